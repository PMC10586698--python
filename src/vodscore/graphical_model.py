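"""Soft-graph posterior over partial-correlation networks of one patient.

For each pair of physiological parameters the absolute partial correlation
|r| is treated as a noisy observation of the binary edge variable G, with
Normal observation density N(g, v), a U[0,1] prior on the variance v and a
Bernoulli(0.5) prior on G.  Marginalising v gives a closed-form two-point
edge posterior; sampling all pairs independently yields a chain of graphs
whose log posteriors drive the inter-patient distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .io_config import PatientTimeSeries

logger = logging.getLogger("vodscore")

__all__ = [
    "CorrelationStructures",
    "EdgeMarginals",
    "GraphChain",
    "GraphicalModel",
    "correlation_matrix",
    "separation_density",
    "edge_marginal_probability",
    "edge_marginals",
    "sample_graph_chain",
    "sample_cohort_chains",
    "extract_graphical_model",
]

_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)


@dataclass
class CorrelationStructures:
    """Inter-column correlation Sigma, its precision and partial correlations."""

    sigma: np.ndarray
    psi: np.ndarray
    r: np.ndarray
    column_names: list[str] | None = None

    @property
    def m(self) -> int:
        return self.r.shape[0]


@dataclass
class EdgeMarginals:
    """Symmetric matrix of closed-form edge-inclusion probabilities."""

    p: np.ndarray


@dataclass
class GraphChain:
    """Sampled binary graphs over the m(m-1)/2 nodal pairs with log posteriors.

    ``samples[q, e]`` is the edge indicator of pair ``pairs[e]`` in the q-th
    sampled graph; ``log_post[q]`` is the log joint edge posterior of that
    graph, recomputable exactly from ``samples`` and ``edge_probs``.
    """

    samples: np.ndarray  # (n_iter, n_pairs) bool
    log_post: np.ndarray  # (n_iter,)
    edge_probs: np.ndarray  # (n_pairs,) closed-form Bernoulli parameters
    pairs: np.ndarray  # (n_pairs, 2) upper-triangle index pairs
    m: int

    @property
    def n_iter(self) -> int:
        return self.samples.shape[0]

    def empirical_edge_probabilities(self) -> np.ndarray:
        """Relative frequency of each edge being present across the chain."""
        return self.samples.mean(axis=0)

    def recompute_log_post(self) -> np.ndarray:
        g = self.samples
        logp = np.log(self.edge_probs)
        log1mp = np.log1p(-self.edge_probs)
        return g @ logp + (~g) @ log1mp


@dataclass
class GraphicalModel:
    """tau-thresholded graphical model of one patient."""

    vertex_labels: list[str]
    adjacency: np.ndarray
    edge_probabilities: np.ndarray  # probabilities used for thresholding
    tau: float

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        m = len(self.vertex_labels)
        for k in range(m):
            for l in range(k + 1, m):
                if self.adjacency[k, l]:
                    out.append((self.vertex_labels[k], self.vertex_labels[l],
                                float(self.edge_probabilities[k, l])))
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.vertex_labels)
        for a, b, p in self.edges():
            g.add_edge(a, b, probability=p)
        return g


# ---------------------------------------------------------------------------
# correlation structures
# ---------------------------------------------------------------------------


def correlation_matrix(
    ts: PatientTimeSeries | np.ndarray,
    ridge: float = 1e-6,
    method: str = "pearson",
) -> CorrelationStructures:
    """Correlation, precision and partial-correlation matrices of one record.

    If the smallest eigenvalue of the sample correlation falls below 1e-8
    the matrix is shrunk as (Sigma + ridge*I)/(1 + ridge) before inversion
    (this preserves the unit diagonal); the shrinkage is logged.
    """
    if isinstance(ts, PatientTimeSeries):
        values = ts.values
        names = ts.column_names
        pid = ts.patient_id
    else:
        values = np.asarray(ts, dtype=float)
        names = None
        pid = "<array>"
    if values.shape[0] < 3:
        raise ValueError(f"patient {pid}: need at least 3 rows")
    stds = values.std(axis=0)
    if np.any(stds == 0):
        bad = [i for i in np.flatnonzero(stds == 0)]
        labels = [names[i] if names else str(i) for i in bad]
        raise ValueError(f"patient {pid}: constant column(s) {labels}")
    if method == "spearman":
        from scipy.stats import rankdata

        values = rankdata(values, axis=0)
    sigma = np.corrcoef(values, rowvar=False)
    if np.linalg.eigvalsh(sigma).min() < 1e-8:
        logger.info("patient %s: applying ridge %g to near-singular correlation", pid, ridge)
        sigma = (sigma + ridge * np.eye(sigma.shape[0])) / (1.0 + ridge)
    try:
        psi = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by ridge
        raise ValueError(f"patient {pid}: correlation inversion failed after ridge") from exc
    denom = np.sqrt(np.outer(np.diag(psi), np.diag(psi)))
    r = -psi / denom
    np.fill_diagonal(r, 1.0)
    return CorrelationStructures(sigma=sigma, psi=psi, r=r, column_names=list(names) if names else None)


# ---------------------------------------------------------------------------
# closed-form edge marginal
# ---------------------------------------------------------------------------


def separation_density(s: np.ndarray | float) -> np.ndarray | float:
    """Unnormalised edge-posterior weight at separation S = |g - |r||.

    This is the U[0,1]-marginalised Normal density
    integral_0^1 (2 pi v)^{-1/2} exp(-S^2 / (2 v)) dv
            = sqrt(2/pi) exp(-S^2/2) - S erfc(S / sqrt(2)).
    """
    s = np.asarray(s, dtype=float)
    out = _SQRT_2_OVER_PI * np.exp(-0.5 * s**2) - s * erfc(s / np.sqrt(2.0))
    return out if out.ndim else float(out)


def edge_marginal_probability(r_abs: np.ndarray | float) -> np.ndarray | float:
    """P(G = 1 | |r|): normalised over the two-point support of G."""
    r = np.asarray(r_abs, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("absolute partial correlation must lie in [0, 1]")
    f1 = np.asarray(separation_density(1.0 - r))  # separation when G = 1
    f0 = np.asarray(separation_density(r))  # separation when G = 0
    out = f1 / (f0 + f1)
    return out if out.ndim else float(out)


def edge_marginals(corr: CorrelationStructures) -> EdgeMarginals:
    p = edge_marginal_probability(np.clip(np.abs(corr.r), 0.0, 1.0))
    np.fill_diagonal(p, 0.0)
    return EdgeMarginals(p=p)


# ---------------------------------------------------------------------------
# graph sampling
# ---------------------------------------------------------------------------


def _upper_pairs(m: int) -> np.ndarray:
    return np.column_stack(np.triu_indices(m, k=1))


def sample_graph_chain(
    corr: CorrelationStructures,
    n_iter: int,
    rng: np.random.Generator | None = None,
    uniforms: np.ndarray | None = None,
    mode: str = "inverse_cdf",
) -> GraphChain:
    """Sample ``n_iter`` graphs from the per-pair edge posteriors.

    Each edge is an independent two-point draw with the closed-form marginal
    probability; ``uniforms`` (shape n_iter x n_pairs) may be supplied to
    share one underlying stream across patients (common random numbers).
    ``mode='rejection'`` runs a literal accept/reject sampler against the
    Bernoulli(0.5) prior instead; it is distributionally identical.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    m = corr.m
    pairs = _upper_pairs(m)
    r_abs = np.clip(np.abs(corr.r[pairs[:, 0], pairs[:, 1]]), 0.0, 1.0)
    p = np.asarray(edge_marginal_probability(r_abs))
    if mode == "inverse_cdf":
        if uniforms is None:
            if rng is None:
                rng = np.random.default_rng()
            uniforms = rng.uniform(size=(n_iter, len(pairs)))
        if uniforms.shape != (n_iter, len(pairs)):
            raise ValueError("uniforms must have shape (n_iter, n_pairs)")
        samples = uniforms < p
    elif mode == "rejection":
        if rng is None:
            rng = np.random.default_rng()
        samples = np.empty((n_iter, len(pairs)), dtype=bool)
        pmax = np.maximum(p, 1.0 - p)
        for e in range(len(pairs)):
            weights = np.array([1.0 - p[e], p[e]])
            accepted = np.empty(0, dtype=bool)
            while accepted.size < n_iter:
                chunk = max(64, 4 * (n_iter - accepted.size))
                cand = rng.integers(0, 2, size=chunk).astype(bool)
                u = rng.uniform(size=chunk)
                keep = u < weights[cand.astype(int)] / pmax[e]
                accepted = np.concatenate([accepted, cand[keep]])
            samples[:, e] = accepted[:n_iter]
    else:
        raise ValueError(f"unknown sampling mode '{mode}'")
    logp = np.log(p)
    log1mp = np.log1p(-p)
    log_post = samples @ logp + (~samples) @ log1mp
    return GraphChain(samples=samples, log_post=log_post, edge_probs=p, pairs=pairs, m=m)


def sample_cohort_chains(
    corrs: list[CorrelationStructures],
    n_iter: int,
    seed: int,
    stream_policy: str = "common",
) -> list[GraphChain]:
    """Sample chains for a whole cohort under a shared or independent streams.

    Under ``stream_policy='common'`` the uniform draw for iteration q and
    pair (k, l) is identical across patients, so two patients with identical
    partial correlations yield identical chains (and zero distance).
    """
    from .io_config import child_rng

    if not corrs:
        return []
    m = corrs[0].m
    if any(c.m != m for c in corrs):
        raise ValueError("all patients must share the same number of parameters")
    n_pairs = m * (m - 1) // 2
    if stream_policy == "common":
        uniforms = child_rng(seed, "graph-chain-common").uniform(size=(n_iter, n_pairs))
        return [sample_graph_chain(c, n_iter, uniforms=uniforms) for c in corrs]
    if stream_policy == "independent":
        return [
            sample_graph_chain(c, n_iter, rng=child_rng(seed, "graph-chain", i))
            for i, c in enumerate(corrs)
        ]
    raise ValueError(f"unknown stream_policy '{stream_policy}'")


def extract_graphical_model(
    chain: GraphChain,
    corr: CorrelationStructures,
    tau: float,
    use_closed_form: bool = False,
) -> GraphicalModel:
    """Threshold edge probabilities at tau to obtain the final model.

    The default thresholds the empirical chain frequencies; the closed-form
    probabilities can be used instead via ``use_closed_form``.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    m = chain.m
    probs = np.zeros((m, m))
    values = chain.edge_probs if use_closed_form else chain.empirical_edge_probabilities()
    probs[chain.pairs[:, 0], chain.pairs[:, 1]] = values
    probs = probs + probs.T
    adjacency = (probs >= tau).astype(int)
    np.fill_diagonal(adjacency, 0)
    labels = corr.column_names or [f"V{i}" for i in range(m)]
    return GraphicalModel(
        vertex_labels=list(labels), adjacency=adjacency, edge_probabilities=probs, tau=tau
    )
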