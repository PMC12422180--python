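"""Nonparametric permutation tests.

Four flavours: paired (sign-flipping of within-pair differences),
one-sample sign-flip, independent two-sample (label shuffling), and a
time-resolved cluster permutation test with Welch-t cluster forming.
Monte-Carlo p-values carry the add-one correction ``(b+1)/(n+1)``; when the
permutation group is small enough the null is enumerated exactly and the
p-value is the exact tail fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "PermResult",
    "ClusterResult",
    "paired_permutation_test",
    "independent_permutation_test",
    "signflip_test",
    "cluster_permutation_test",
]

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class PermResult:
    """Result of a two-sided permutation test."""

    statistic: float
    p_value: float
    n_permutations: int
    exact: bool
    seed: int | None = None
    method: str = ""


@dataclass(frozen=True)
class ClusterResult:
    """Result of a cluster permutation test.

    ``clusters`` rows: start, end (inclusive sample indices), sign, mass,
    p_value — maximal contiguous supra-threshold runs of same-signed
    Welch t values, with p-values from the max-cluster-mass null.
    """

    clusters: list[dict]
    n_permutations: int
    alpha: float
    t_values: np.ndarray
    threshold: np.ndarray

    def significant(self, alpha: float | None = None) -> list[dict]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c["p_value"] <= a]


def _two_sided_p(null: np.ndarray, observed: float, exact: bool) -> float:
    thresh = abs(observed) * (1 - _TIE_RTOL) - 1e-300
    b = int(np.sum(np.abs(null) >= thresh))
    if exact:
        return b / null.size
    return (b + 1) / (null.size + 1)


def _signflip_machinery(
    d: np.ndarray, n_perm: int, seed
) -> tuple[float, float, int, bool]:
    observed = float(d.mean())
    n = d.size
    if np.all(d == 0):
        return observed, 1.0, 0, True
    if 2**n <= n_perm:
        # exact enumeration over all sign patterns
        bits = np.arange(2**n, dtype=np.int64)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)) & 1)
        null = (signs * d).mean(axis=1)
        return observed, _two_sided_p(null, observed, exact=True), 2**n, True
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    null = (signs * d).mean(axis=1)
    return observed, _two_sided_p(null, observed, exact=False), n_perm, False


def paired_permutation_test(
    a, b, n_perm: int = 100_000, seed: int | None = None
) -> PermResult:
    """Two-sided paired-sample permutation test on ``mean(a - b)``.

    The null exchanges condition labels within pairs, i.e. randomly flips
    the signs of the paired differences; exact enumeration is used whenever
    ``2**n <= n_perm``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    stat, p, n_used, exact = _signflip_machinery(a - b, n_perm, seed)
    return PermResult(stat, p, n_used, exact, seed, "paired")


def signflip_test(x, n_perm: int = 100_000, seed: int | None = None) -> PermResult:
    """Two-sided sign-flipping test of ``mean(x)`` against zero.

    All-zero input yields p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-D array of length >= 2")
    stat, p, n_used, exact = _signflip_machinery(x, n_perm, seed)
    return PermResult(stat, p, n_used, exact, seed, "signflip")


def independent_permutation_test(
    a, b, n_perm: int = 100_000, seed: int | None = None
) -> PermResult:
    """Two-sided independent-sample permutation test on ``mean(a) - mean(b)``.

    The null shuffles the group assignment of the pooled values; exact
    enumeration over all ``C(na+nb, na)`` assignments is used when feasible.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = float(a.mean() - b.mean())
    if comb(n, na) <= n_perm:
        null = np.array(
            [
                pooled[list(idx)].mean()
                - np.delete(pooled, list(idx)).mean()
                for idx in combinations(range(n), na)
            ]
        )
        p = _two_sided_p(null, observed, exact=True)
        return PermResult(observed, p, null.size, True, seed, "independent")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    null = perms[:, :na].mean(axis=1) - perms[:, na:].mean(axis=1)
    p = _two_sided_p(null, observed, exact=False)
    return PermResult(observed, p, n_perm, False, seed, "independent")


# ---------------------------------------------------------------------------
# cluster statistics
# ---------------------------------------------------------------------------

def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise Welch t statistic and degrees of freedom (columns = time)."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    return t, df


def _clusters_from_t(
    t: np.ndarray, crit: np.ndarray, valid: np.ndarray
) -> list[tuple[int, int, int, float]]:
    """Maximal contiguous same-sign supra-threshold runs: (start, end, sign, mass).

    Runs never bridge invalid (excluded) time points.
    """
    out = []
    n = t.size
    i = 0
    while i < n:
        if not valid[i] or not np.isfinite(t[i]) or abs(t[i]) <= crit[i]:
            i += 1
            continue
        sign = 1 if t[i] > 0 else -1
        j = i
        mass = 0.0
        while (
            j < n
            and valid[j]
            and np.isfinite(t[j])
            and abs(t[j]) > crit[j]
            and (1 if t[j] > 0 else -1) == sign
        ):
            mass += abs(t[j])
            j += 1
        out.append((i, j - 1, sign, mass))
        i = j
    return out


def cluster_permutation_test(
    group_a,
    group_b,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    valid_mask=None,
) -> ClusterResult:
    """Two-sided cluster permutation test on trials x time arrays.

    Pointwise Welch t values are thresholded at the two-sided ``alpha``
    critical value (cluster-forming threshold); cluster mass is the sum of
    |t| over a maximal contiguous same-sign supra-threshold run.  The null
    distribution is the maximum cluster mass under random reassignment of
    trials to groups; each observed cluster's p-value is the add-one
    corrected fraction of null maxima at least as large.  Time points
    flagged invalid in ``valid_mask`` are removed before clustering and
    clusters cannot bridge them.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be trials x time arrays on one time axis")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two trials per group")
    n_time = a.shape[1]
    valid = (
        np.ones(n_time, dtype=bool)
        if valid_mask is None
        else np.asarray(valid_mask, dtype=bool)
    )

    t_obs, df = _welch_t(a, b)
    crit = sp_stats.t.ppf(1 - alpha / 2, np.maximum(df, 1.0))
    obs_clusters = _clusters_from_t(t_obs, crit, valid)

    pooled = np.vstack([a, b])
    na = a.shape[0]
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        pa, pb = pooled[idx[:na]], pooled[idx[na:]]
        t_p, df_p = _welch_t(pa, pb)
        crit_p = sp_stats.t.ppf(1 - alpha / 2, np.maximum(df_p, 1.0))
        cl = _clusters_from_t(t_p, crit_p, valid)
        if cl:
            null_max[i] = max(c[3] for c in cl)

    clusters = [
        {
            "start": s,
            "end": e,
            "sign": sign,
            "mass": mass,
            "p_value": (np.sum(null_max >= mass * (1 - _TIE_RTOL)) + 1) / (n_perm + 1),
        }
        for s, e, sign, mass in obs_clusters
    ]
    return ClusterResult(
        clusters=clusters,
        n_permutations=n_perm,
        alpha=alpha,
        t_values=t_obs,
        threshold=crit,
    )
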