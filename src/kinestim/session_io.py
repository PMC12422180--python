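"""Readers/writers and the top-level pipeline report.

Everything on disk is tab-separated text with a one-line header; units are
encoded in the column names (seconds, pixels, pixels/s).  A session
directory holds ``trace.tsv``, ``movements.tsv``, ``stim_events.tsv``, an
optional ``truth.tsv`` and a ``config.yaml`` snapshot carrying the seed and
a configuration hash.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .closed_loop import SessionRecord
from .config import RunConfig, StimProtocol, config_hash

logger = logging.getLogger("kinestim")

__all__ = ["write_session", "read_session", "validate_session", "report"]

_MOVEMENT_COLUMNS = [
    "block",
    "movement_index",
    "label",
    "stimulated",
    "online_peak_px_s",
    "detection_time_s",
    "detection_latency_s",
]
_STIM_COLUMNS = ["block", "movement_index", "start_time_s", "duration_s"]
_TRACE_COLUMNS = ["time_s", "x_px", "y_px", "trial_index"]


def validate_session(session: SessionRecord) -> None:
    """Enforce structural invariants before a session touches disk."""
    proto = session.protocol
    mv = session.movements
    expected = proto.n_blocks * proto.block_length
    if len(mv) != expected:
        raise ValueError(
            f"session has {len(mv)} movements, protocol demands {expected}"
        )
    bad = session.stim_events.loc[
        ~session.stim_events["block"].isin(proto.stim_blocks)
    ]
    if len(bad):
        raise ValueError(
            f"stimulation events outside stimulation blocks: rows {list(bad.index)}"
        )
    if not np.allclose(session.stim_events["duration_s"], proto.burst_duration):
        raise ValueError("stimulation burst durations deviate from the protocol")


def write_session(session: SessionRecord, path, truth=None, config: RunConfig | None = None) -> Path:
    """Write a validated session (and optional ground truth) to a directory."""
    validate_session(session)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.movements[_MOVEMENT_COLUMNS].to_csv(
        path / "movements.tsv", sep="\t", index=False
    )
    session.stim_events[_STIM_COLUMNS].to_csv(
        path / "stim_events.tsv", sep="\t", index=False
    )
    if session.trace is not None:
        session.trace[_TRACE_COLUMNS].to_csv(path / "trace.tsv", sep="\t", index=False)
    if truth is not None:
        truth.movements.to_csv(path / "truth.tsv", sep="\t", index=False)
    snapshot = {
        "protocol": dataclasses.asdict(session.protocol),
        "meta": dict(session.meta),
        "has_truth": truth is not None,
    }
    if config is not None:
        snapshot["run_config"] = config.to_dict()
        snapshot["config_hash"] = config_hash(config)
    else:
        snapshot["config_hash"] = config_hash(snapshot["protocol"])
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(_listify(snapshot), fh, sort_keys=True)
    logger.info("wrote session to %s", path)
    return path


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:  # noqa: BLE001 - surface the file name
        raise ValueError(f"malformed TSV {path}: {err}") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_session(path) -> SessionRecord:
    """Read and validate a session directory written by :func:`write_session`.

    Extra columns in the tables are preserved.  Schema violations are
    reported with the offending file, column and row.
    """
    path = Path(path)
    movements = _read_tsv(path / "movements.tsv", _MOVEMENT_COLUMNS)
    stim_events = _read_tsv(path / "stim_events.tsv", _STIM_COLUMNS)
    trace = None
    if (path / "trace.tsv").exists():
        trace = _read_tsv(path / "trace.tsv", _TRACE_COLUMNS)
        t = trace["time_s"].to_numpy()
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(
                f"{path / 'trace.tsv'}: non-monotonic time_s at row {int(bad[0]) + 3}"
            )
    protocol = StimProtocol()
    meta: dict = {}
    if (path / "config.yaml").exists():
        with open(path / "config.yaml") as fh:
            snap = yaml.safe_load(fh) or {}
        meta = snap.get("meta", {}) or {}
        meta["config_hash"] = snap.get("config_hash")
        proto_raw = snap.get("protocol")
        if proto_raw:
            proto_raw = {
                k: tuple(v) if isinstance(v, list) else v for k, v in proto_raw.items()
            }
            protocol = StimProtocol(**proto_raw)
    session = SessionRecord(
        movements=movements,
        stim_events=stim_events,
        protocol=protocol,
        trace=trace,
        meta=meta,
    )
    validate_session(session)
    return session


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report(
    out_dir,
    speed_change: pd.DataFrame | None = None,
    shift_table: pd.DataFrame | None = None,
    beta_windows: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> Path:
    """Assemble tabular and plotted summaries of whatever results exist.

    Writes deterministic TSV tables plus a figure with up to three panels:
    block speed-change curves, direction-resolved post-stimulation shift
    bars, and the beta-band time courses of stimulated vs not-stimulated
    trials.  Missing inputs are listed in ``report.txt`` and the partial
    report is still produced.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = []
    stamp = config_hash(config) if config is not None else "unconfigured"

    panels = sum(x is not None for x in (speed_change, shift_table, beta_windows))
    fig, axes = plt.subplots(1, max(panels, 1), figsize=(5 * max(panels, 1), 4))
    axes = np.atleast_1d(axes)
    ax_i = 0

    if speed_change is not None:
        speed_change.to_csv(out_dir / "speed_change.tsv", sep="\t", index=False)
        ax = axes[ax_i]
        for block, grp in speed_change.groupby("block"):
            ax.plot(grp["movement_index"], grp["percent_change"], label=f"block {block}")
        ax.set_xlabel("movement")
        ax.set_ylabel("speed change from block start (%)")
        ax.legend(fontsize=7)
        ax_i += 1
    else:
        missing.append("speed_change")

    if shift_table is not None:
        shift_table.to_csv(out_dir / "poststim_shift.tsv", sep="\t", index=False)
        ax = axes[ax_i]
        lbl = shift_table["condition"] + "/" + shift_table["direction"]
        ax.bar(lbl, shift_table["shift"])
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("post-stimulation speed shift (% points)")
        ax.tick_params(axis="x", rotation=45)
        ax_i += 1
    else:
        missing.append("poststim_shift")

    if beta_windows is not None:
        beta_windows.to_csv(out_dir / "beta_windows.tsv", sep="\t", index=False)
        ax = axes[ax_i]
        stim = beta_windows["stimulated"].to_numpy()
        ax.boxplot(
            [
                beta_windows.loc[stim, "stim_window_beta"].dropna(),
                beta_windows.loc[~stim, "stim_window_beta"].dropna(),
                beta_windows.loc[stim, "post_window_beta"].dropna(),
                beta_windows.loc[~stim, "post_window_beta"].dropna(),
            ],
            tick_labels=["stim/peri", "no-stim/peri", "stim/post", "no-stim/post"],
        )
        ax.set_ylabel("beta power (z)")
        ax.tick_params(axis="x", rotation=45)
    else:
        missing.append("beta_windows")

    fig.suptitle(f"kinestim report [{stamp}]", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_dir / "report.png", dpi=110)
    plt.close(fig)

    with open(out_dir / "report.txt", "w") as fh:
        fh.write(f"config_hash\t{stamp}\n")
        fh.write(f"missing_inputs\t{','.join(missing) if missing else 'none'}\n")
    if missing:
        logger.warning("report assembled without: %s", ", ".join(missing))
    return out_dir
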