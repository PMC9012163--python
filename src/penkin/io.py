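"""Reading and writing pen-tablet traces, cohort manifests, and covariate tables.

A trace file is plain CSV preceded by a ``#``-prefixed header block, e.g.::

    # dialect: cm
    # rate_hz: 200
    # subject_id: ctl01
    # group: CTRL
    # bigram: ll
    # trial: 1
    t,x,y,p
    0.000000,1.200000,4.000000,0.000000
    ...

Two dialects are supported: ``cm`` (positions in centimetres, y increasing
upward, pressure already normalised to [0, 1]) and ``raw_counts`` (integer
tablet counts converted through the header-declared ``lpi``, y increasing
downward and flipped using ``active_height_cm``, pressure divided by
``pressure_max``).  All traces come out in a single convention: centimetres,
y up, origin at the active area's bottom-left, time in seconds from trial
start.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

GROUPS = ("CTRL", "SCZ")
BIGRAMS = ("ll", "ln")

#: Wacom Pro Pen 2 reports 8192 pressure levels (0..8191).
DEFAULT_PRESSURE_MAX = 8191

COVARIATE_COLUMNS = [
    "subject_id", "panss_p", "panss_n", "panss_g", "sas", "cpze",
    "illness_years", "education_years",
    "purdue_dom", "purdue_nondom", "purdue_both", "purdue_asm",
]


class TraceFormatError(ValueError):
    """Malformed trace file (header, cell, ordering, or range problems)."""


class PenSample(NamedTuple):
    t: float   # seconds from trial start
    x: float   # cm
    y: float   # cm, increasing upward
    p: float   # normalised pressure in [0, 1]


@dataclass
class PenTrace:
    """One trial's pen recording plus trial metadata.

    Samples are stored as parallel numpy arrays; ``samples()`` yields
    :class:`PenSample` tuples for element-wise access.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    p: np.ndarray
    subject_id: str = ""
    group: str = ""
    bigram: str = ""
    trial: int = 1
    nominal_rate: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.p = np.asarray(self.p, dtype=float)

    def __len__(self) -> int:
        return self.t.size

    def samples(self):
        for row in zip(self.t, self.x, self.y, self.p):
            yield PenSample(*row)

    def validate(self) -> "PenTrace":
        """Check the trace invariants, raising :class:`TraceFormatError`."""
        n = len(self)
        if not (self.x.size == self.y.size == self.p.size == n):
            raise TraceFormatError("t, x, y, p must have equal length")
        if n == 0:
            raise TraceFormatError("trace has no samples")
        if not np.all(np.isfinite(self.t)) or self.t[0] < 0:
            raise TraceFormatError("times must be finite and non-negative")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            i = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise TraceFormatError(
                f"sample times must be strictly increasing (violated at row {i})"
            )
        if np.any((self.p < 0) | (self.p > 1)):
            raise TraceFormatError("pressure outside [0, 1] after normalisation")
        if self.group and self.group not in GROUPS:
            raise TraceFormatError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.bigram and self.bigram not in BIGRAMS:
            raise TraceFormatError(f"bigram must be one of {BIGRAMS}, got {self.bigram!r}")
        return self

    def copy(self) -> "PenTrace":
        return replace(
            self, t=self.t.copy(), x=self.x.copy(), y=self.y.copy(), p=self.p.copy()
        )


def counts_to_cm(raw, lpi: float):
    """Convert raw tablet counts to centimetres given the resolution in lines
    per inch (1 inch = 2.54 cm)."""
    if lpi <= 0:
        raise ValueError(f"lpi must be positive, got {lpi}")
    return np.asarray(raw, dtype=float) / lpi * 2.54


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if not body:
            continue
        if ":" not in body:
            raise TraceFormatError(f"malformed header line: {ln.strip()!r}")
        key, _, val = body.partition(":")
        meta[key.strip()] = val.strip()
    return meta


def read_trace(path, dialect: str | None = None) -> PenTrace:
    """Read one trace file, returning a :class:`PenTrace` in cm / y-up / [0,1]
    pressure.  ``dialect`` overrides the header-declared dialect if given."""
    path = Path(path)
    text = path.read_text()
    header_lines, data_lines = [], []
    n_header = 0
    for ln in text.splitlines():
        if ln.startswith("#"):
            header_lines.append(ln)
            n_header += 1
        else:
            data_lines.append(ln)
    meta = _parse_header(header_lines)
    dialect = dialect or meta.get("dialect", "cm")
    if dialect not in ("cm", "raw_counts"):
        raise TraceFormatError(f"unknown dialect {dialect!r} in {path}")

    try:
        df = pd.read_csv(_io.StringIO("\n".join(data_lines)))
    except Exception as exc:  # noqa: BLE001 - re-raise with location
        raise TraceFormatError(f"{path}: cannot parse CSV body: {exc}") from exc
    for col in ("t", "x", "y", "p"):
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing column {col!r}")
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + n_header + 2 if len(bad) else "?"
            raise TraceFormatError(f"{path}: non-numeric cell in column {col!r} at line {line}")

    t = df["t"].to_numpy(float)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    p = df["p"].to_numpy(float)

    if dialect == "raw_counts":
        lpi = float(meta.get("lpi", 5080))
        height = float(meta.get("active_height_cm", 10.0))
        pmax = float(meta.get("pressure_max", DEFAULT_PRESSURE_MAX))
        if np.any((p < 0) | (p > pmax)):
            raise TraceFormatError(f"{path}: raw pressure outside [0, {pmax}]")
        x = counts_to_cm(x, lpi)
        # Raw tablet streams are y-down; flip into the y-up convention.
        y = height - counts_to_cm(y, lpi)
        p = p / pmax
    else:
        if np.any((p < 0) | (p > 1)):
            raise TraceFormatError(f"{path}: pressure outside declared range [0, 1]")

    rate = meta.get("rate_hz")
    if rate is None and len(t) > 1:
        dt = np.diff(t)
        if np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            rate = 1.0 / dt[0]
    trace = PenTrace(
        t=t, x=x, y=y, p=p,
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group", ""),
        bigram=meta.get("bigram", ""),
        trial=int(meta.get("trial", 1)),
        nominal_rate=float(rate) if rate is not None else None,
    )
    return trace.validate()


def write_trace(trace: PenTrace, path) -> Path:
    """Write a trace in the ``cm`` dialect with 6-decimal precision.

    Round-trip guarantee: ``read_trace(write_trace(x))`` reproduces samples
    within 1e-6.  Pen-up rows (p = 0) are data and are preserved.
    """
    trace.validate()
    path = Path(path)
    lines = ["# dialect: cm"]
    if trace.nominal_rate is not None:
        lines.append(f"# rate_hz: {trace.nominal_rate:g}")
    for key in ("subject_id", "group", "bigram"):
        val = getattr(trace, key)
        if val:
            lines.append(f"# {key}: {val}")
    lines.append(f"# trial: {trace.trial}")
    lines.append("t,x,y,p")
    for ti, xi, yi, pi in zip(trace.t, trace.x, trace.y, trace.p):
        lines.append(f"{ti:.6f},{xi:.6f},{yi:.6f},{pi:.6f}")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class CohortManifest:
    """Trial index of a cohort: one row per recorded trial, plus an optional
    clinical covariate table keyed by subject_id."""

    trials: pd.DataFrame  # columns: subject_id, group, bigram, trial, path
    covariates: pd.DataFrame | None = None

    def validate(self, check_paths: bool = True) -> "CohortManifest":
        required = ["subject_id", "group", "bigram", "trial", "path"]
        missing = [c for c in required if c not in self.trials.columns]
        if missing:
            raise TraceFormatError(f"manifest missing columns {missing}")
        dup = self.trials.duplicated(subset=["subject_id", "bigram", "trial"])
        if dup.any():
            raise TraceFormatError(
                f"duplicate (subject_id, bigram, trial) rows: {self.trials[dup].head()}"
            )
        bad_group = ~self.trials["group"].isin(GROUPS)
        if bad_group.any():
            raise TraceFormatError(f"unknown group values {set(self.trials.loc[bad_group, 'group'])}")
        bad_big = ~self.trials["bigram"].isin(BIGRAMS)
        if bad_big.any():
            raise TraceFormatError(f"unknown bigram values {set(self.trials.loc[bad_big, 'bigram'])}")
        if check_paths:
            for p in self.trials["path"]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing trace file {p}")
        return self


def read_manifest(path, covariates_path=None, check_paths: bool = True) -> CohortManifest:
    trials = pd.read_csv(path, comment="#")
    # Trace paths are stored relative to the manifest's directory.
    base = Path(path).parent
    trials = trials.assign(path=[str((base / p)) if not Path(p).is_absolute() else p
                                 for p in trials["path"]])
    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, comment="#")
    return CohortManifest(trials=trials, covariates=cov).validate(check_paths=check_paths)


def write_manifest(manifest: CohortManifest, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.trials.to_csv(path, index=False)
    return path
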