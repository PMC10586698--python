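"""Convenience orchestration of the per-cohort stages.

Glues together correlation estimation, graph-chain sampling, distance
assembly and score learning so the CLI, tests and experiments share one
code path.
"""

from __future__ import annotations

from typing import Sequence

from .graph_distance import DistanceMatrix, distance_matrix
from .graphical_model import GraphChain, correlation_matrix, sample_cohort_chains
from .io_config import PatientTimeSeries, RunConfig
from .score_inference import ScoreMcmcConfig, ScorePosterior, learn_scores

__all__ = ["cohort_distances", "score_cohort"]


def cohort_distances(
    series: Sequence[PatientTimeSeries],
    config: RunConfig | None = None,
    stream_policy: str = "common",
) -> tuple[list[GraphChain], DistanceMatrix]:
    """Time series -> graph chains -> inter-patient distance matrix."""
    config = config or RunConfig()
    corrs = [correlation_matrix(ts, ridge=config.ridge) for ts in series]
    chains = sample_cohort_chains(corrs, config.n_iter, seed=config.seed, stream_policy=stream_policy)
    return chains, distance_matrix(chains, patient_ids=[ts.patient_id for ts in series])


def score_cohort(
    series: Sequence[PatientTimeSeries],
    reference_id: str,
    config: RunConfig | None = None,
    side: dict[str, int] | None = None,
    init: str = "above",
) -> tuple[DistanceMatrix, ScorePosterior]:
    """Full within-cohort run: distances then MCMC score learning."""
    config = config or RunConfig()
    _, dist = cohort_distances(series, config)
    ref_index = dist.index_of(reference_id)
    side_idx = {dist.index_of(pid): sgn for pid, sgn in (side or {}).items()}
    mcmc = ScoreMcmcConfig(
        n_sweeps=config.n_sweeps,
        burn_in=config.burn_in,
        proposal_sd=config.proposal_sd,
        likelihood_sd=config.likelihood_sd,
        prior_sd=config.prior_sd,
        seed=config.seed,
    )
    posterior = learn_scores(dist, reference=ref_index, config=mcmc, side=side_idx, init=init)
    return dist, posterior
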