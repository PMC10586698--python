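"""Synthetic cohorts with a latent severity driving correlation structure.

Each patient j carries a latent severity z_j in [0, 1].  Their time-series
rows are i.i.d. draws from a zero-mean Gaussian whose correlation matrix is
the convex mixture

    Sigma(z) = (1 - w(z)) * C_healthy + w(z) * C_sick,

and their pre-transplant attributes are linked to z through linear (numeric)
and logistic (binary) links, with distractor attributes independent of z.
This reproduces the statistical structure the scoring method assumes, so
every downstream stage is testable without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import json
import numpy as np
import pandas as pd
import yaml

from .io_config import PatientTimeSeries, PreTransplantTable, child_rng, encode_pretransplant, write_time_series

__all__ = ["SeverityScenario", "simulate_cohort", "simulate_test_patient", "write_cohort"]


def _ar1_correlation(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _equicorrelation(m: int, rho: float) -> np.ndarray:
    return np.full((m, m), rho) + (1.0 - rho) * np.eye(m)


@dataclass
class NumericAttribute:
    name: str
    intercept: float
    slope: float  # 0 for distractors
    noise_sd: float


@dataclass
class BinaryAttribute:
    name: str
    intercept: float  # logit scale
    slope: float
    reserved_novel: bool = False  # always 0 in training; 1 for a flagged test patient


@dataclass
class CategoricalAttribute:
    name: str
    levels: list[str]  # baseline first; contributes len-1 encoded columns


def _default_attributes() -> tuple[list[NumericAttribute], list[BinaryAttribute], list[CategoricalAttribute]]:
    numeric = [
        NumericAttribute("Age", 35.0, 25.0, 4.0),
        NumericAttribute("FerritinPre", 800.0, 1500.0, 150.0),
        NumericAttribute("CRPPre", 5.0, 30.0, 3.0),
        NumericAttribute("BilirubinPre", 0.5, 1.2, 0.15),
        NumericAttribute("Weight", 70.0, 0.0, 8.0),
        NumericAttribute("Height", 168.0, 0.0, 7.0),
    ]
    binary = [
        BinaryAttribute("LiverDisHist", -3.0, 5.0),
        BinaryAttribute("HepaticDysfun", -3.5, 5.5),
        BinaryAttribute("PulmonaryDysf", -2.5, 4.0),
        BinaryAttribute("CMVPositive", -2.0, 3.5),
        BinaryAttribute("DisRelapsed", -2.5, 4.5),
        BinaryAttribute("Diabetes", -2.0, 3.0),
        BinaryAttribute("Hypertension", -1.0, 0.0),
        BinaryAttribute("Gender", 0.0, 0.0),
        BinaryAttribute("ABOMismatch", -0.5, 0.0),
        BinaryAttribute("HLAMatch", 1.0, 0.0),
        BinaryAttribute("CardiacDis", -1.5, 0.0),
        BinaryAttribute("Thromboembolism", -30.0, 0.0, reserved_novel=True),
    ]
    categorical = [
        CategoricalAttribute(
            "CancerType", ["Other", "ALL", "AML", "Aplastic", "CML", "Myelofibrosis"]
        ),
        CategoricalAttribute("GenderMismatch", ["NoMismatch", "M:F", "F:M", "F:F", "M:M"]),
        CategoricalAttribute("Conditioning", ["Standard", "Reduced", "Myeloablative", "Sequential"]),
    ]
    return numeric, binary, categorical


@dataclass
class SeverityScenario:
    """Full generative specification of one synthetic multi-cohort study."""

    cohort_sizes: tuple[int, ...] = (5, 8, 12)
    m: int = 11
    c_healthy: np.ndarray | None = None
    c_sick: np.ndarray | None = None
    severities: np.ndarray | None = None  # per patient; default stratified over [0, 1]
    length_range: tuple[int, int] = (400, 600)  # monitor-resolution sampling over ~26 days
    mixing: Callable[[float], float] | None = None  # w(z); default identity
    noise_scale: float = 1.0  # multiplies attribute noise; 0 gives the noise-free links
    ar_coefficient: float = 0.0  # optional AR(1) row process for robustness checks
    numeric_attributes: list[NumericAttribute] = field(default_factory=list)
    binary_attributes: list[BinaryAttribute] = field(default_factory=list)
    categorical_attributes: list[CategoricalAttribute] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        # defaults need strong *partial* correlations in the sick structure:
        # an AR(1) band gives neighbour partials ~ rho/(1+rho^2), whereas an
        # equicorrelation matrix has near-zero partials at m = 11
        if self.c_healthy is None:
            self.c_healthy = _ar1_correlation(self.m, 0.15)
        if self.c_sick is None:
            self.c_sick = _ar1_correlation(self.m, 0.9)
        self.c_healthy = np.asarray(self.c_healthy, dtype=float)
        self.c_sick = np.asarray(self.c_sick, dtype=float)
        for name, c in (("c_healthy", self.c_healthy), ("c_sick", self.c_sick)):
            if c.shape != (self.m, self.m):
                raise ValueError(f"{name} must be {self.m} x {self.m}")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError(f"{name} must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        if self.severities is None:
            n = self.n_patients
            rng = child_rng(self.seed, "severities")
            self.severities = (np.arange(n) + rng.uniform(size=n)) / n
            rng.shuffle(self.severities)
        self.severities = np.asarray(self.severities, dtype=float)
        if len(self.severities) != self.n_patients:
            raise ValueError("severities must have one entry per patient")
        if np.any((self.severities < 0) | (self.severities > 1)):
            raise ValueError("severities must lie in [0, 1]")
        if not self.numeric_attributes and not self.binary_attributes and not self.categorical_attributes:
            num, binr, cat = _default_attributes()
            self.numeric_attributes = num
            self.binary_attributes = binr
            self.categorical_attributes = cat

    @property
    def n_patients(self) -> int:
        return int(sum(self.cohort_sizes))

    @property
    def column_names(self) -> list[str]:
        defaults = [
            "SysBP", "DiaBP", "Pulse", "RespRate", "Temp", "CapSat",
            "Weight", "FluidBal", "Bilirubin", "Creatinine", "WBC",
        ]
        if self.m <= len(defaults):
            return defaults[: self.m]
        return defaults + [f"Param{i}" for i in range(len(defaults), self.m)]

    def w(self, z: float) -> float:
        return float(z) if self.mixing is None else float(self.mixing(z))

    def mixture_correlation(self, z: float) -> np.ndarray:
        wz = self.w(z)
        if not 0.0 <= wz <= 1.0:
            raise ValueError("mixing weight must lie in [0, 1]")
        sigma = (1.0 - wz) * self.c_healthy + wz * self.c_sick
        # convex mixture of unit-diagonal PD matrices stays unit-diagonal PD
        assert np.allclose(np.diag(sigma), 1.0)
        assert np.linalg.eigvalsh(sigma).min() > 0
        return sigma

    def patient_ids(self) -> list[str]:
        ids = []
        for c, size in enumerate(self.cohort_sizes):
            ids.extend(f"C{c + 1}-P{j + 1}" for j in range(size))
        return ids

    def cohort_ids(self) -> list[str]:
        out = []
        for c, size in enumerate(self.cohort_sizes):
            out.extend([f"C{c + 1}"] * size)
        return out


def _sample_rows(scenario: SeverityScenario, z: float, n_t: int, rng: np.random.Generator) -> np.ndarray:
    sigma = scenario.mixture_correlation(z)
    chol = np.linalg.cholesky(sigma)
    eps = rng.standard_normal((n_t, scenario.m))
    phi = scenario.ar_coefficient
    if phi:
        innov_scale = np.sqrt(1.0 - phi**2)
        for t in range(1, n_t):
            eps[t] = phi * eps[t - 1] + innov_scale * eps[t]
    return eps @ chol.T


def _raw_attribute_record(
    scenario: SeverityScenario, z: float, rng: np.random.Generator, novel: bool = False
) -> dict[str, object]:
    rec: dict[str, object] = {}
    ns = scenario.noise_scale
    for att in scenario.numeric_attributes:
        noise = att.noise_sd * ns * rng.standard_normal() if ns > 0 else 0.0
        rec[att.name] = att.intercept + att.slope * z + noise
    for att in scenario.binary_attributes:
        if att.reserved_novel:
            rec[att.name] = 1.0 if novel else 0.0
            continue
        p = 1.0 / (1.0 + np.exp(-(att.intercept + att.slope * z)))
        rec[att.name] = float(rng.uniform() < p) if ns > 0 else float(p > 0.5)
    for att in scenario.categorical_attributes:
        rec[att.name] = att.levels[0] if ns == 0 else att.levels[rng.integers(len(att.levels))]
    return rec


def simulate_cohort(
    scenario: SeverityScenario,
) -> tuple[list[PatientTimeSeries], PreTransplantTable, dict[str, float]]:
    """Draw a full multi-cohort study from the scenario.

    Returns the per-patient time series, the encoded pre-transplant table
    and the truth record mapping patient id to latent severity.
    """
    ids = scenario.patient_ids()
    cohorts = scenario.cohort_ids()
    n_min, n_max = scenario.length_range
    series: list[PatientTimeSeries] = []
    records: list[dict[str, object]] = []
    for pid, cid, z in zip(ids, cohorts, scenario.severities):
        rng = child_rng(scenario.seed, "patient", pid)
        n_t = int(rng.integers(n_min, n_max + 1))
        values = _sample_rows(scenario, z, n_t, rng)
        # n_t readings from 8 days pre-transplant to a patient-specific
        # truncation time at most 18 days post-transplant
        t_max = float(rng.uniform(2.0, 18.0))
        times = np.linspace(-8.0, t_max, n_t)
        series.append(
            PatientTimeSeries(
                patient_id=pid, cohort_id=cid, times=times,
                values=values, column_names=scenario.column_names,
            )
        )
        records.append(_raw_attribute_record(scenario, z, rng))
    raw = pd.DataFrame(records)
    table = encode_pretransplant(
        raw,
        categorical_levels={a.name: a.levels for a in scenario.categorical_attributes},
        patient_ids=ids,
    )
    truth = {pid: float(z) for pid, z in zip(ids, scenario.severities)}
    return series, table, truth


def simulate_test_patient(
    scenario: SeverityScenario,
    z_test: float,
    include_novel_flag: bool = False,
    seed_tag: object = "test-patient",
) -> dict[str, object]:
    """Generate a single prospective patient's raw pre-transplant record.

    When ``include_novel_flag`` is set, the reserved novel binary attribute
    is 1 for this patient while it is 0 for every training patient.
    """
    rng = child_rng(scenario.seed, seed_tag, z_test)
    return _raw_attribute_record(scenario, z_test, rng, novel=include_novel_flag)


def write_cohort(
    out_dir: str | Path,
    series: Sequence[PatientTimeSeries],
    table: PreTransplantTable,
    truth: dict[str, float],
) -> None:
    """Write a simulated cohort as CSV files + manifest + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": []}
    for ts in series:
        fname = f"{ts.patient_id}.csv"
        write_time_series(ts, out / fname)
        manifest["patients"].append(
            {"id": ts.patient_id, "cohort": ts.cohort_id, "file": fname}
        )
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    raw = table.raw_attributes.copy()
    raw.insert(0, "patient_id", table.patient_ids)
    raw.to_csv(out / "pretransplant.csv", index=False)
    (out / "levels.json").write_text(json.dumps(table.level_maps, indent=1))
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
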