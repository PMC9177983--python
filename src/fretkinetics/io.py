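"""On-disk formats: CSV tables for traces, segments, dwells, curves and
key/value text fit reports.

All tables are comma-delimited UTF-8 with a mandatory header row; times are
seconds, frames 0-based.  Writers are deterministic (fixed column order,
shortest-repr float formatting) so that read(write(x)) == x bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dwells import DwellRecord
from .ensemble import BindingSeries, DecayCurve, Spectrum
from .fret import IntensityTrace
from .idealize import IdealizedTrajectory, Segment

__all__ = [
    "SchemaError",
    "TraceValidationError",
    "read_traces",
    "write_traces",
    "read_dwells",
    "write_dwells",
    "read_segments",
    "write_segments",
    "read_decay",
    "write_decay",
    "read_binding",
    "write_binding",
    "read_spectrum",
    "write_spectrum",
    "FitReport",
    "write_report",
    "read_report",
]

TRACE_COLUMNS = ["molecule_id", "frame", "time_s", "donor", "acceptor"]
DWELL_COLUMNS = [
    "molecule_id",
    "state_level",
    "start_s",
    "duration_s",
    "left_censored",
    "right_censored",
]
SEGMENT_COLUMNS = ["molecule_id", "start_frame", "end_frame", "level"]


class SchemaError(ValueError):
    """A table is missing required columns."""


class TraceValidationError(ValueError):
    """A trace table violates the frame-contiguity/uniqueness invariants."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def write_traces(traces: list[IntensityTrace], path, fret=None) -> None:
    """Write intensity traces as a long-format CSV table.

    ``fret`` may map molecule_id -> efficiency array to include the optional
    fret column.
    """
    frames = []
    for tr in traces:
        n = len(tr)
        d = {
            "molecule_id": tr.molecule_id,
            "frame": np.arange(n),
            "time_s": np.arange(n) * tr.frame_interval,
            "donor": tr.donor,
            "acceptor": tr.acceptor,
        }
        if fret is not None and tr.molecule_id in fret:
            d["fret"] = np.asarray(fret[tr.molecule_id], dtype=float)
        frames.append(pd.DataFrame(d))
    cols = TRACE_COLUMNS + (["fret"] if fret else [])
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)
    out.to_csv(path, index=False)


def read_traces(path) -> list[IntensityTrace]:
    """Read a trace table back into per-molecule IntensityTrace objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)
    traces = []
    for mol, g in df.groupby("molecule_id", sort=False):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            raise TraceValidationError(f"{path}: duplicate (molecule_id, frame) for {mol!r}")
        if frames[0] != 0 or np.any(np.diff(frames) != 1):
            raise TraceValidationError(f"{path}: non-contiguous frames for {mol!r}")
        t = g["time_s"].to_numpy()
        if len(t) > 1:
            dt = t[1] - t[0]
            if np.any(np.abs(t - frames * dt) > 1e-9):
                raise TraceValidationError(f"{path}: time_s != frame * interval for {mol!r}")
        else:
            dt = 0.2
        traces.append(
            IntensityTrace(
                molecule_id=str(mol),
                frame_interval=float(dt),
                donor=g["donor"].to_numpy(),
                acceptor=g["acceptor"].to_numpy(),
            )
        )
    return traces


def write_dwells(dwells: list[DwellRecord], path) -> None:
    df = pd.DataFrame(
        {
            "molecule_id": [d.molecule_id for d in dwells],
            "state_level": [d.state_level for d in dwells],
            "start_s": [d.start_s for d in dwells],
            "duration_s": [d.duration_s for d in dwells],
            "left_censored": [d.left_censored for d in dwells],
            "right_censored": [d.right_censored for d in dwells],
        },
        columns=DWELL_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_dwells(path) -> list[DwellRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DWELL_COLUMNS, path)
    return [
        DwellRecord(
            molecule_id=str(r.molecule_id),
            state_level=float(r.state_level),
            start_s=float(r.start_s),
            duration_s=float(r.duration_s),
            left_censored=bool(r.left_censored),
            right_censored=bool(r.right_censored),
        )
        for r in df.itertuples()
    ]


def write_segments(ideals: list[IdealizedTrajectory], path) -> None:
    rows = []
    for ideal in ideals:
        for s in ideal.segments:
            rows.append((ideal.molecule_id, s.start_frame, s.end_frame, s.level))
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, index=False)


def read_segments(path, frame_interval: float = 0.2) -> list[IdealizedTrajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SEGMENT_COLUMNS, path)
    out = []
    for mol, g in df.groupby("molecule_id", sort=False):
        g = g.sort_values("start_frame")
        segs = [
            Segment(int(r.start_frame), int(r.end_frame), float(r.level))
            for r in g.itertuples()
        ]
        out.append(
            IdealizedTrajectory(
                molecule_id=str(mol), frame_interval=frame_interval, segments=segs
            )
        )
    return out


def write_decay(curve: DecayCurve, path) -> None:
    df = pd.DataFrame({"time_s": curve.time_s, "intensity": curve.intensity})
    if curve.uncertainty is not None:
        df["uncertainty"] = curve.uncertainty
    df.to_csv(path, index=False)


def read_decay(path, condition_id: str | None = None) -> DecayCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s", "intensity"], path)
    unc = df["uncertainty"].to_numpy() if "uncertainty" in df.columns else None
    return DecayCurve(
        condition_id=condition_id or Path(path).stem,
        time_s=df["time_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        uncertainty=unc,
    )


def write_binding(series: BindingSeries, path) -> None:
    pd.DataFrame(
        {"concentration_m": series.concentration, "response": series.response}
    ).to_csv(path, index=False)


def read_binding(path, ligand: str = "") -> BindingSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["concentration_m", "response"], path)
    return BindingSeries(
        concentration=df["concentration_m"].to_numpy(),
        response=df["response"].to_numpy(),
        ligand=ligand,
    )


def write_spectrum(s: Spectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": s.wavelength, "intensity": s.intensity}).to_csv(
        path, index=False
    )


def read_spectrum(path) -> Spectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["wavelength_nm", "intensity"], path)
    return Spectrum(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy())


@dataclass
class FitReport:
    """Flat record of one model fit, serializable as key: value text."""

    model: str
    parameters: dict  # name -> value
    stderrs: dict = field(default_factory=dict)  # name -> SE (NaN = undefined)
    goodness: dict = field(default_factory=dict)  # chi_square / log_likelihood / aic / bic
    n_obs: int = 0
    config_digest: str = ""

    def __post_init__(self) -> None:
        for k, v in self.parameters.items():
            if v is not None and not np.isfinite(v):
                raise ValueError(f"parameter {k} is not finite")
        for k, v in self.stderrs.items():
            if v is not None and np.isfinite(v) and v < 0:
                raise ValueError(f"standard error {k} is negative")


def write_report(report: FitReport, path) -> None:
    lines = [f"model: {report.model}", f"n_obs: {report.n_obs}"]
    if report.config_digest:
        lines.append(f"config_digest: {report.config_digest}")
    for k in sorted(report.parameters):
        lines.append(f"param.{k}: {report.parameters[k]!r}")
    for k in sorted(report.stderrs):
        lines.append(f"stderr.{k}: {report.stderrs[k]!r}")
    for k in sorted(report.goodness):
        lines.append(f"gof.{k}: {report.goodness[k]!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_value(text: str):
    if text == "None":
        return None
    try:
        return float(text)
    except ValueError:
        return text


def read_report(path) -> FitReport:
    rep = FitReport(model="", parameters={})
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "model":
            rep.model = value
        elif key == "n_obs":
            rep.n_obs = int(value)
        elif key == "config_digest":
            rep.config_digest = value
        elif key.startswith("param."):
            rep.parameters[key[6:]] = _parse_value(value)
        elif key.startswith("stderr."):
            rep.stderrs[key[7:]] = _parse_value(value)
        elif key.startswith("gof."):
            rep.goodness[key[4:]] = _parse_value(value)
    return rep
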