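"""Relative score learning from the distance matrix by Metropolis-Hastings.

The reference patient is pinned at score 1.  The observable distance of
patient j to the reference is modelled as Normal about |s_j - 1|, and
pairwise case-based priors keep the full score configuration internally
consistent with all inter-patient distances.  Scores for cohorts anchored
to different references are aligned by shifting with the inter-reference
distance, signed by the clinician severity ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .graph_distance import DistanceMatrix
from .io_config import child_rng

__all__ = [
    "ScoreMcmcConfig",
    "ScorePosterior",
    "CohortAlignment",
    "hpd_interval",
    "case_prior_mean",
    "log_score_target",
    "learn_scores",
    "align_cohorts",
    "classify_status",
    "status_thresholds",
    "load_benchmark_scores",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class ScoreMcmcConfig:
    n_sweeps: int = 20_000
    burn_in: int = 5_000
    proposal_sd: float = 0.05
    likelihood_sd: float = 0.1
    prior_sd: float = 0.1
    side_prior_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.likelihood_sd <= 0 or self.prior_sd <= 0 or self.proposal_sd <= 0:
            raise ValueError("all MCMC standard deviations must be positive")
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("burn_in must lie in [0, n_sweeps)")


@dataclass
class ScorePosterior:
    """Per-patient retained draws, posterior means and 95% HPD intervals.

    ``hpd_lower``/``hpd_upper`` are NaN for patients whose score is assigned
    rather than learnt (reference patients), reported as "N.A." in tables.
    """

    patient_ids: list[str]
    means: np.ndarray
    hpd_lower: np.ndarray
    hpd_upper: np.ndarray
    reference_index: int
    draws: np.ndarray | None = None  # (n_kept, n_patients)
    cohort_ids: list[str] | None = None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "mean_score": self.means,
                "hpd_lower": self.hpd_lower,
                "hpd_upper": self.hpd_upper,
            }
        )


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


# ---------------------------------------------------------------------------
# case-based prior
# ---------------------------------------------------------------------------


def case_prior_mean(s_j_prop, s_i_prop, delta_1j, delta_1i, delta_ij):
    """Case-consistent prior mean for S_j given comparator S_i.

    With |s - 1| matching the distance to the reference and
    delta_ij = |delta_1j - delta_1i|, each combination of the sides of
    s_j, s_i relative to 1 and of the ordering of delta_1i vs delta_1j
    determines s_j from s_i and delta_ij; the mixed-side cases follow from
    the same |s - 1| algebra.
    """
    s_j = np.asarray(s_j_prop, dtype=float)
    s_i = np.asarray(s_i_prop, dtype=float)
    d1j = np.asarray(delta_1j, dtype=float)
    d1i = np.asarray(delta_1i, dtype=float)
    dij = np.asarray(delta_ij, dtype=float)
    s_j, s_i, d1j, d1i, dij = np.broadcast_arrays(s_j, s_i, d1j, d1i, dij)
    above_j = s_j >= 1.0
    above_i = s_i >= 1.0
    i_farther = d1i > d1j
    signed = np.where(i_farther, dij, -dij)
    mean = np.where(above_j == above_i,
                    np.where(above_j, s_i - signed, s_i + signed),
                    np.where(above_j, 2.0 - s_i - signed, 2.0 - s_i + signed))
    return mean if mean.ndim else float(mean)


def _log_normal(x, mean, sd) -> np.ndarray:
    z = (np.asarray(x, dtype=float) - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def log_score_target(
    s: np.ndarray,
    dist: np.ndarray,
    reference: int,
    config: ScoreMcmcConfig,
    side: dict[int, int] | None = None,
) -> float:
    """Log of the unnormalised pseudo-posterior over the full score vector.

    Sum of the per-patient Normal likelihoods of the reference distances,
    the pairwise case-based priors over all ordered non-reference pairs,
    and optional one-sided severity priors.
    """
    s = np.asarray(s, dtype=float)
    n = len(s)
    others = np.array([j for j in range(n) if j != reference])
    d1 = dist[reference]
    total = float(np.sum(_log_normal(d1[others], np.abs(s[others] - 1.0), config.likelihood_sd)))
    for j in others:
        comp = others[others != j]
        if comp.size:
            means = case_prior_mean(s[j], s[comp], d1[j], d1[comp], dist[j, comp])
            total += float(np.sum(_log_normal(s[j], means, config.prior_sd)))
    if side:
        for j, sgn in side.items():
            anchor = 1.0 + sgn * d1[j]
            total += float(_log_normal(s[j], anchor, config.side_prior_sd))
    return total


# ---------------------------------------------------------------------------
# Metropolis-Hastings sampler
# ---------------------------------------------------------------------------


def learn_scores(
    dist: DistanceMatrix | np.ndarray,
    reference: int = 0,
    config: ScoreMcmcConfig | None = None,
    side: dict[int, int] | None = None,
    init: str | np.ndarray = "above",
    patient_ids: list[str] | None = None,
) -> ScorePosterior:
    """Component-wise random-walk MH over all non-reference scores.

    ``init`` places the chain at 1 + delta ("above"), 1 - delta ("below")
    or a user-supplied configuration; the branch of each score relative to
    1 remains free to move during sampling.  ``side`` optionally adds a
    Normal severity prior anchored at 1 + sign*delta for selected patients
    (clinician-style ordering information).
    """
    if isinstance(dist, DistanceMatrix):
        patient_ids = patient_ids or dist.patient_ids
        dmat = dist.delta
    else:
        dmat = np.asarray(dist, dtype=float)
    config = config or ScoreMcmcConfig()
    n = dmat.shape[0]
    if patient_ids is None:
        patient_ids = [str(i) for i in range(n)]
    others = np.array([j for j in range(n) if j != reference])
    d1 = dmat[reference]
    rng = child_rng(config.seed, "score-mcmc", reference)

    if isinstance(init, str):
        if init == "above":
            s = 1.0 + d1.copy()
        elif init == "below":
            s = 1.0 - d1.copy()
        else:
            raise ValueError(f"unknown init '{init}'")
    else:
        s = np.asarray(init, dtype=float).copy()
    s[reference] = 1.0

    v = config.prior_sd
    sig = config.likelihood_sd
    side = side or {}

    def delta_log_target(j: int, s_new: float) -> float:
        s_old = s[j]
        out = (
            _log_normal(d1[j], abs(s_new - 1.0), sig)
            - _log_normal(d1[j], abs(s_old - 1.0), sig)
        )
        comp = others[others != j]
        if comp.size:
            m_new = case_prior_mean(s_new, s[comp], d1[j], d1[comp], dmat[j, comp])
            m_old = case_prior_mean(s_old, s[comp], d1[j], d1[comp], dmat[j, comp])
            out += np.sum(_log_normal(s_new, m_new, v) - _log_normal(s_old, m_old, v))
            # terms where j is the comparator of the other scores
            r_new = case_prior_mean(s[comp], s_new, d1[comp], d1[j], dmat[comp, j])
            r_old = case_prior_mean(s[comp], s_old, d1[comp], d1[j], dmat[comp, j])
            out += np.sum(_log_normal(s[comp], r_new, v) - _log_normal(s[comp], r_old, v))
        if j in side:
            anchor = 1.0 + side[j] * d1[j]
            out += _log_normal(s_new, anchor, config.side_prior_sd) - _log_normal(
                s_old, anchor, config.side_prior_sd
            )
        return float(out)

    n_kept = config.n_sweeps - config.burn_in
    draws = np.empty((n_kept, n))
    prop = rng.normal(scale=config.proposal_sd, size=(config.n_sweeps, len(others)))
    logu = np.log(rng.uniform(size=(config.n_sweeps, len(others))))
    for t in range(config.n_sweeps):
        for jj, j in enumerate(others):
            s_new = s[j] + prop[t, jj]
            if logu[t, jj] < delta_log_target(j, s_new):
                s[j] = s_new
        if t >= config.burn_in:
            draws[t - config.burn_in] = s

    means = draws.mean(axis=0)
    lower = np.empty(n)
    upper = np.empty(n)
    for j in range(n):
        lower[j], upper[j] = hpd_interval(draws[:, j])
    means[reference] = 1.0
    lower[reference] = np.nan
    upper[reference] = np.nan
    return ScorePosterior(
        patient_ids=list(patient_ids),
        means=means,
        hpd_lower=lower,
        hpd_upper=upper,
        reference_index=reference,
        draws=draws,
    )


# ---------------------------------------------------------------------------
# multi-cohort alignment and classification
# ---------------------------------------------------------------------------


@dataclass
class CohortAlignment:
    """Alignment of one cohort's reference to the universal reference."""

    cohort_id: str
    reference_patient_id: str
    distance_to_universal: float
    reference_more_severe: bool  # True: this cohort's reference more severe

    @property
    def shift(self) -> float:
        if self.distance_to_universal < 0:
            raise ValueError("inter-reference distance must be nonnegative")
        return self.distance_to_universal if self.reference_more_severe else -self.distance_to_universal


def align_cohorts(
    universal_cohort_id: str,
    alignments: list[CohortAlignment],
    cohort_posteriors: dict[str, ScorePosterior],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Shift every cohort's scores onto the universal reference scale.

    Every score (means, HPD bounds, draws) in a non-universal cohort is
    shifted by +d (its reference more severe than the universal reference)
    or -d; shifted cohort references keep no uncertainty ("N.A.").  Returns
    the combined per-patient table and the per-cohort shifts.
    """
    shifts: dict[str, float] = {universal_cohort_id: 0.0}
    by_cohort = {a.cohort_id: a for a in alignments}
    for cid in cohort_posteriors:
        if cid != universal_cohort_id and cid not in by_cohort:
            raise ValueError(f"no severity ordering supplied for cohort '{cid}'")
    rows = []
    for cid, post in cohort_posteriors.items():
        if cid == universal_cohort_id:
            shift = 0.0
        else:
            shift = by_cohort[cid].shift
            shifts[cid] = shift
        for idx, pid in enumerate(post.patient_ids):
            is_ref = idx == post.reference_index
            mean = post.means[idx] + shift
            if is_ref:
                lo = hi = np.nan  # reference scores carry no uncertainty
            else:
                lo = post.hpd_lower[idx] + shift
                hi = post.hpd_upper[idx] + shift
            rows.append(
                {
                    "cohort_id": cid,
                    "patient_id": pid,
                    "mean_score": mean,
                    "hpd_lower": lo,
                    "hpd_upper": hi,
                    "is_reference": is_ref,
                }
            )
    return pd.DataFrame(rows), shifts


def classify_status(
    mean_score: float,
    upper_hpd: float | None = None,
    mean_cutoff: float = 0.11,
    upper_cutoff: float = 0.31,
    use_uncertainty: bool = False,
) -> str:
    """Map a learnt score to a predicted status label ("Y"/"N").

    A mean score above the cutoff predicts onset; in uncertainty-aware mode
    the upper 95% HPD bound is compared against its own (higher) cutoff.
    """
    if use_uncertainty and upper_hpd is not None and np.isfinite(upper_hpd):
        return "N" if upper_hpd <= upper_cutoff else "Y"
    return "Y" if mean_score > mean_cutoff else "N"


def status_thresholds(table: pd.DataFrame) -> tuple[float, float]:
    """Largest mean score and largest upper HPD bound among status-N rows.

    These are the boundaries consistent with every negative patient in a
    scored cohort table (columns: mean_score, hpd_upper, status).
    """
    neg = table[table["status"] == "N"]
    mean_cutoff = float(neg["mean_score"].max())
    upper_cutoff = float(neg["hpd_upper"].dropna().max())
    return mean_cutoff, upper_cutoff


def load_benchmark_scores() -> pd.DataFrame:
    """Load the packaged 25-patient benchmark score table.

    Columns: mean_score, hpd_lower, hpd_upper (NaN where not available)
    and observed post-transplant status ("Y"/"N").
    """
    with resources.files("vodscore.data").joinpath("benchmark_scores.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
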