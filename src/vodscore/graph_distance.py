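"""Discretised Hellinger distances between patients' graph posteriors.

Each patient's chain contributes a trace of log graph posteriors; all traces
are scaled by the single cohort-wide maximum B, and the distance between two
patients is the root-mean-square difference of their scaled traces, paired
by iteration.  Computed this way, delta is symmetric, nonnegative, obeys the
triangle inequality, and is exactly zero for identical chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .graphical_model import GraphChain

__all__ = ["LogPosteriorTraces", "DistanceMatrix", "scale_traces", "hellinger_distance", "distance_matrix"]


@dataclass
class LogPosteriorTraces:
    """B-scaled log-posterior traces, one row per patient."""

    u: np.ndarray  # (n_patients, n_iter), all entries <= 0
    scale_b: float

    @property
    def n_iter(self) -> int:
        return self.u.shape[1]


@dataclass
class DistanceMatrix:
    """Symmetric N_p x N_p matrix of inter-patient graph distances."""

    delta: np.ndarray
    patient_ids: list[str] | None = None

    @property
    def n_patients(self) -> int:
        return self.delta.shape[0]

    def index_of(self, patient_id: str) -> int:
        if self.patient_ids is None:
            raise ValueError("distance matrix carries no patient ids")
        return self.patient_ids.index(patient_id)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"patient_ids": self.patient_ids, "delta": self.delta.tolist()}, indent=1
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DistanceMatrix":
        raw = json.loads(Path(path).read_text())
        return cls(delta=np.asarray(raw["delta"], dtype=float), patient_ids=raw["patient_ids"])


def scale_traces(chains: Sequence[GraphChain]) -> LogPosteriorTraces:
    """Scale all log-posterior traces by the cohort-wide maximum B."""
    if not chains:
        raise ValueError("no chains supplied")
    n_iter = chains[0].n_iter
    if any(c.n_iter != n_iter for c in chains):
        raise ValueError("all chains must share a common n_iter")
    logs = np.vstack([c.log_post for c in chains])
    b = float(logs.max())
    return LogPosteriorTraces(u=logs - b, scale_b=b)


def hellinger_distance(trace_i: np.ndarray, trace_j: np.ndarray) -> float:
    """RMS difference of two iteration-paired scaled traces."""
    trace_i = np.asarray(trace_i, dtype=float)
    trace_j = np.asarray(trace_j, dtype=float)
    if trace_i.shape != trace_j.shape:
        raise ValueError("trace length mismatch")
    return float(np.sqrt(np.mean((trace_i - trace_j) ** 2)))


def distance_matrix(
    chains: Sequence[GraphChain],
    patient_ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Assemble the full cohort distance matrix from iteration-paired traces."""
    traces = scale_traces(chains)
    # delta_ij = ||u_i - u_j||_2 / sqrt(N_iter): a plain Euclidean distance
    delta = squareform(pdist(traces.u, metric="euclidean")) / np.sqrt(traces.n_iter)
    return DistanceMatrix(delta=delta, patient_ids=list(patient_ids) if patient_ids else None)
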