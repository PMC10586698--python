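"""Tabular I/O, mixed-type attribute encoding, run configuration and seeding.

Time-series files are delimited text with a header row: one ``time`` column
(days relative to transplant, negative = pre-transplant) followed by one
column per physiological parameter.  Patient and cohort identifiers live in
a separate manifest (YAML or JSON) so each time-series file stays a single
matrix.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("vodscore")

__all__ = [
    "PatientTimeSeries",
    "PreTransplantTable",
    "RunConfig",
    "read_time_series",
    "write_time_series",
    "read_manifest",
    "encode_pretransplant",
    "child_rng",
    "configure_logging",
]


def configure_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Send structured logs to stderr and optionally to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = "%(asctime)s %(levelname)s %(name)s: %(message)s"
    logging.basicConfig(level=level, format=fmt, handlers=handlers, force=True)


def child_rng(master_seed: int, *tags: object) -> np.random.Generator:
    """Derive a reproducible, stream-independent generator.

    Child streams are keyed on ``(master_seed, *tags)`` (purpose tag,
    patient id, ...) via a stable hash, so per-patient streams are
    reproducible and mutually independent.
    """
    digest = hashlib.sha256("\x1f".join(str(t) for t in tags).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *words]))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PatientTimeSeries:
    """One patient's n_t x m physiological record.

    ``times`` are strictly increasing day offsets relative to transplant;
    ``values`` holds one row per time point and one column per parameter.
    """

    patient_id: str
    cohort_id: str
    times: np.ndarray
    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"patient {self.patient_id}: values must be 2-D")
        if self.n_t < 3:
            raise ValueError(
                f"patient {self.patient_id}: insufficient rows "
                f"({self.n_t} < 3); cannot support a correlation estimate"
            )
        if len(self.times) != self.n_t:
            raise ValueError(f"patient {self.patient_id}: times/values length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"patient {self.patient_id}: times must be strictly increasing")
        if len(self.column_names) != self.m:
            raise ValueError(f"patient {self.patient_id}: column_names/values width mismatch")

    @property
    def n_t(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class PreTransplantTable:
    """Encoded pre-transplant attributes for a cohort.

    ``encoded`` is the d x N_p real matrix after dummy encoding (rows are
    attributes, columns are patients).  ``level_maps`` records, per
    categorical attribute, the level list with the baseline first, so the
    same encoder can be applied to a prospective patient.
    """

    patient_ids: list[str]
    raw_attributes: pd.DataFrame
    encoded: np.ndarray
    attribute_names: list[str]
    level_maps: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.encoded = np.asarray(self.encoded, dtype=float)
        if self.encoded.shape != (len(self.attribute_names), len(self.patient_ids)):
            raise ValueError("encoded must be d x N_p")
        if not np.all(np.isfinite(self.encoded)):
            raise ValueError("encoded pre-transplant matrix contains missing entries")

    @property
    def d(self) -> int:
        return self.encoded.shape[0]

    @property
    def n_patients(self) -> int:
        return self.encoded.shape[1]

    def encode_row(self, raw_row: Mapping[str, object]) -> np.ndarray:
        """Encode a single new patient's raw record with the fitted encoder."""
        return _encode_frame(
            pd.DataFrame([dict(raw_row)]), self.level_maps, self.attribute_names
        )[:, 0]

    def drop_variable(self, index: int) -> "PreTransplantTable":
        keep = [i for i in range(self.d) if i != index]
        return PreTransplantTable(
            patient_ids=list(self.patient_ids),
            raw_attributes=self.raw_attributes,
            encoded=self.encoded[keep, :],
            attribute_names=[self.attribute_names[i] for i in keep],
            level_maps=dict(self.level_maps),
        )


@dataclass
class RunConfig:
    """All tunables for one end-to-end run."""

    tau: float = 0.6
    n_iter: int = 10_000
    ridge: float = 1e-6
    # score MCMC
    n_sweeps: int = 20_000
    burn_in: int = 5_000
    proposal_sd: float = 0.05
    likelihood_sd: float = 0.1
    prior_sd: float = 0.1
    # GP MCMC
    gp_n_iter: int = 30_000
    gp_burn_in: int = 10_000
    # classification thresholds
    mean_cutoff: float = 0.11
    upper_cutoff: float = 0.31
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        for name in ("proposal_sd", "likelihood_sd", "prior_sd", "ridge"):
            if getattr(self, name) < 0 or (name != "ridge" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**(raw or {}))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_time_series(
    path: str | Path,
    patient_id: str | None = None,
    cohort_id: str = "",
    time_column: str = "time",
    sep: str = ",",
) -> PatientTimeSeries:
    """Read one patient's delimited time-series file.

    Rows containing any missing value are dropped with a logged warning;
    fewer than 3 complete rows is a hard error.
    """
    path = Path(path)
    pid = patient_id if patient_id is not None else path.stem
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if time_column not in frame.columns:
        raise ValueError(f"patient {pid}: no '{time_column}' column in {path}")
    n_raw = len(frame)
    frame = frame.dropna(axis=0, how="any")
    n_dropped = n_raw - len(frame)
    if n_dropped:
        logger.warning("patient %s: dropped %d incomplete row(s) of %d", pid, n_dropped, n_raw)
    if len(frame) < 3:
        raise ValueError(f"patient {pid}: insufficient rows ({len(frame)} complete rows < 3)")
    value_cols = [c for c in frame.columns if c != time_column]
    return PatientTimeSeries(
        patient_id=pid,
        cohort_id=cohort_id,
        times=frame[time_column].to_numpy(dtype=float),
        values=frame[value_cols].to_numpy(dtype=float),
        column_names=value_cols,
    )


def write_time_series(ts: PatientTimeSeries, path: str | Path, sep: str = ",") -> None:
    frame = pd.DataFrame(ts.values, columns=ts.column_names)
    frame.insert(0, "time", ts.times)
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_manifest(path: str | Path) -> dict:
    """Read a cohort manifest (YAML or JSON by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# mixed-type encoding
# ---------------------------------------------------------------------------


def _encode_frame(
    raw: pd.DataFrame,
    level_maps: Mapping[str, Sequence[str]],
    expected_names: Sequence[str] | None = None,
) -> np.ndarray:
    columns: dict[str, np.ndarray] = {}
    for col in raw.columns:
        if col in level_maps:
            levels = list(level_maps[col])
            seen = raw[col].astype(str)
            unknown = sorted(set(seen) - set(levels))
            if unknown:
                raise ValueError(
                    f"attribute '{col}': unseen level(s) {unknown}; known levels: {levels}"
                )
            for lev in levels[1:]:  # baseline (first level) -> all-zero indicators
                columns[f"{col}={lev}"] = (seen == lev).to_numpy(dtype=float)
        else:
            columns[col] = raw[col].to_numpy(dtype=float)
    names = list(columns)
    if expected_names is not None:
        if set(names) != set(expected_names):
            raise ValueError("record attributes do not match the fitted encoder")
        names = list(expected_names)
    return np.vstack([columns[n] for n in names]) if names else np.empty((0, len(raw)))


def encode_pretransplant(
    raw: pd.DataFrame,
    categorical_levels: Mapping[str, Sequence[str]] | None = None,
    patient_ids: Sequence[str] | None = None,
) -> PreTransplantTable:
    """Dummy-encode a raw per-patient attribute table.

    Each categorical attribute with k enumerated levels (first level =
    baseline) contributes k-1 indicator columns; the baseline maps to
    all-zero indicators.  Numeric and binary attributes pass through.
    """
    categorical_levels = dict(categorical_levels or {})
    if patient_ids is None:
        patient_ids = [str(i) for i in raw.index]
    encoded = _encode_frame(raw, categorical_levels)
    names: list[str] = []
    for col in raw.columns:
        if col in categorical_levels:
            names.extend(f"{col}={lev}" for lev in list(categorical_levels[col])[1:])
        else:
            names.append(col)
    return PreTransplantTable(
        patient_ids=list(patient_ids),
        raw_attributes=raw.reset_index(drop=True),
        encoded=encoded,
        attribute_names=names,
        level_maps={k: list(v) for k, v in categorical_levels.items()},
    )
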