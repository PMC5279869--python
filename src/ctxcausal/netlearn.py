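"""Context-specific network learning with interventional DBNs.

Each context's replicate-averaged, imputed 7-point time courses are
turned into lag-1 regression problems: for every child node, the
response stacks the child's values at time index t+1 over all regimes,
and the predictors are all node values at time index t (no rows span a
regime boundary).  Interventions are encoded in the design: under the
default ``fix_baseline`` mode, the predictor column of an inhibited node
is pinned to the context's DMSO t = 0 value for that regime's rows
(blocked activity); ``drop_edges`` instead removes rows from regimes
inhibiting any member of the scored parent set.

Parent sets up to size ``d_max`` are scored in closed form with a
Gaussian linear model and a unit-information g-prior (g = n) on the
coefficients, flat priors on intercept and noise variance; the intercept
and the child's own lag are always included and self-edges are never
reported.  Exact Bayesian model averaging over parent sets yields edge
marginals.  Contexts are coupled two ways: a prior-network energy
``eta * |parent set (symmetric difference) prior parents|`` and an
inter-context agreement energy ``lambda/(C-1) * expected edge
disagreement`` with the other contexts' current marginals, solved by
cyclic mean-field iteration to a fixed point of the edge marginals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb, lgamma, log, pi

import numpy as np
import pandas as pd

from .rppa_io import ANALYSIS_TIMES, Context, InhibitorRegime, PriorNetwork, RppaDataset

__all__ = [
    "LearningConfig",
    "DesignSet",
    "EdgeProbabilityNetwork",
    "build_design",
    "log_marginal_likelihood",
    "enumerate_parent_sets",
    "score_parent_sets",
    "joint_edge_posteriors",
    "learn_networks",
    "summarize_cell_line_network",
    "permute_time_order",
]

MAX_PARENT_SETS = 500_000


@dataclass
class LearningConfig:
    """Tunable parameters of the network-learning stage.

    ``lambda_joint`` (inter-context agreement) and ``eta_prior`` (prior
    network agreement) follow the study's settings of 3 and 15; the
    ``kappa`` scale constants let users re-scale either energy if
    matching a different parametrization.
    """

    lambda_joint: float = 3.0
    eta_prior: float = 15.0
    d_max: int = 3
    score: str = "g_prior"  # or "bic"
    g: float | None = None  # None -> unit information, g = n
    intervention_mode: str = "fix_baseline"  # or "drop_edges", "off"
    tol: float = 1e-4
    max_iter: int = 100
    seed: int = 0
    kappa_eta: float = 1.0
    kappa_lambda: float = 1.0

    def __post_init__(self) -> None:
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class DesignSet:
    """Stacked lag-1 transitions for one context."""

    context: Context
    nodes: list[str]
    X: np.ndarray  # n_rows x P lagged predictors (masking applied)
    Y: np.ndarray  # n_rows x P responses
    row_regime: list[str]  # regime id per row
    masked_nodes: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class EdgeProbabilityNetwork:
    """Posterior edge marginals for one context; prob[child, parent]."""

    context: Context
    prob: pd.DataFrame

    def edge_probability(self, parent: str, child: str) -> float:
        return float(self.prob.loc[child, parent])


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _context_series(
    data: RppaDataset, context: Context, regime_id: str, times: tuple[float, ...]
) -> np.ndarray | None:
    sub = data.select_context(context)
    mask = (sub.meta["inhibitor"] == regime_id).to_numpy()
    block = sub.meta.loc[mask].join(sub.values.loc[mask])
    if not mask.any():
        return None
    block = block.set_index("time_min")
    if not all(t in block.index for t in times):
        return None
    return block.loc[list(times), data.antibody_names].to_numpy(dtype=float)


def build_design(
    data: RppaDataset,
    regimes: list[InhibitorRegime],
    context: Context,
    mode: str = "fix_baseline",
    time_points: tuple[float, ...] = ANALYSIS_TIMES,
) -> DesignSet:
    """Stack lag-1 transitions for one context over the given regimes.

    Requires replicate-averaged, imputed data with a complete series per
    regime.  Regimes targeting nodes absent from the panel contribute
    data without masking (with a warning), mirroring inhibitors whose
    target carries no antibody.
    """
    nodes = data.antibody_names
    node_idx = {n: i for i, n in enumerate(nodes)}
    dmso = _context_series(data, context, "DMSO", time_points)
    if dmso is None:
        raise ValueError(f"no complete DMSO series for {context}")
    xs, ys, row_regime = [], [], []
    masked: dict[str, frozenset[str]] = {}
    for reg in regimes:
        series = dmso if reg.is_control else _context_series(
            data, context, reg.regime_id, time_points
        )
        if series is None:
            warnings.warn(f"{context}: no complete series for {reg.regime_id}; skipped")
            continue
        lagged = series[:-1].copy()
        response = series[1:]
        present = frozenset(t for t in reg.target_nodes if t in node_idx)
        absent = reg.target_nodes - present
        if absent and not reg.is_control:
            warnings.warn(
                f"regime {reg.regime_id} targets {sorted(absent)} not in panel; no masking"
            )
        if mode == "fix_baseline" and present and not reg.is_control:
            for t in present:
                lagged[:, node_idx[t]] = dmso[0, node_idx[t]]
        masked[reg.regime_id] = present if (mode != "off" and not reg.is_control) else frozenset()
        xs.append(lagged)
        ys.append(response)
        row_regime.extend([reg.regime_id] * lagged.shape[0])
    if not xs:
        raise ValueError(f"no usable regimes for {context}")
    return DesignSet(
        context=context,
        nodes=list(nodes),
        X=np.vstack(xs),
        Y=np.vstack(ys),
        row_regime=row_regime,
        masked_nodes=masked,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def enumerate_parent_sets(candidates: list, d_max: int) -> list[tuple]:
    """All candidate-parent subsets of size 0..d_max, ordered by size then
    lexicographically (deterministic)."""
    n = len(candidates)
    total = sum(comb(n, k) for k in range(min(d_max, n) + 1))
    if total > MAX_PARENT_SETS:
        raise ValueError(
            f"{total} parent sets exceeds the tractability bound; reduce d_max"
        )
    out: list[tuple] = []
    for k in range(min(d_max, n) + 1):
        out.extend(itertools.combinations(candidates, k))
    return out


def _gprior_score(
    n: int, k: int, tss: float, rss: float, g: float
) -> float:
    """Closed-form log marginal likelihood, Zellner g-prior on slopes,
    flat priors on intercept and noise variance."""
    if tss <= 0.0:
        return 0.0  # constant response: all models tie
    r2 = max(0.0, 1.0 - rss / tss)
    return (
        lgamma((n - 1) / 2.0)
        - ((n - 1) / 2.0) * log(pi)
        - 0.5 * log(n)
        - ((n - 1) / 2.0) * log(tss)
        + ((n - 1 - k) / 2.0) * log(1.0 + g)
        - ((n - 1) / 2.0) * log(1.0 + g * (1.0 - r2))
    )


def log_marginal_likelihood(
    response: np.ndarray,
    predictors: np.ndarray,
    g: float | None = None,
    score: str = "g_prior",
) -> float:
    """Score one parent set's Gaussian linear model.

    ``predictors`` holds the non-intercept columns (self-lag plus parent
    lags); an intercept is added internally.  ``k`` is the effective
    rank of the centered predictor block, so duplicated or collinear
    columns do not change the score.  ``g`` defaults to the
    unit-information choice g = n.  ``score="bic"`` returns -BIC/2.
    """
    y = np.asarray(response, dtype=float)
    x = np.atleast_2d(np.asarray(predictors, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    n = len(y)
    if n <= x.shape[1] + 2:
        raise ValueError("too few rows for the parent-set size")
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    tss = float(yc @ yc)
    beta, _, rank, _ = np.linalg.lstsq(xc, yc, rcond=None)
    rss = float(yc @ yc - yc @ (xc @ beta))
    rss = max(rss, 0.0)
    k = int(rank)
    if score == "bic":
        if tss <= 0:
            return 0.0
        sigma2 = max(rss, 1e-300) / n
        ll = -0.5 * n * (log(2 * pi * sigma2) + 1.0)
        return ll - 0.5 * (k + 2) * log(n)
    return _gprior_score(n, k, tss, rss, g if g is not None else float(n))


def score_parent_sets(
    design: DesignSet,
    child: str,
    config: LearningConfig,
    candidates: list[str] | None = None,
) -> tuple[list[frozenset[str]], np.ndarray]:
    """Log marginal likelihood of every parent set for one child.

    The self-lag is always included and is not part of the parent set.
    Under ``drop_edges`` masking, rows from regimes inhibiting a member
    of the scored set are excluded from that set's regression.
    """
    nodes = design.nodes
    node_idx = {n: i for i, n in enumerate(nodes)}
    ci = node_idx[child]
    if candidates is None:
        candidates = [n for n in nodes if n != child]
    sets = enumerate_parent_sets(sorted(candidates), config.d_max)
    y_all = design.Y[:, ci]
    drop_mode = config.intervention_mode == "drop_edges"
    row_masked: list[frozenset[str]] = [
        design.masked_nodes.get(r, frozenset()) for r in design.row_regime
    ]
    scores = np.empty(len(sets))
    for s_i, parents in enumerate(sets):
        cols = [node_idx[child]] + [node_idx[p] for p in parents]
        if drop_mode and parents:
            pset = set(parents)
            keep = np.array([not (m & pset) for m in row_masked])
        else:
            keep = slice(None)
        x = design.X[keep][:, cols]
        y = y_all[keep]
        scores[s_i] = log_marginal_likelihood(y, x, g=config.g, score=config.score)
    return [frozenset(s) for s in sets], scores


# ---------------------------------------------------------------------------
# joint posterior over contexts
# ---------------------------------------------------------------------------

def _membership(sets: list[frozenset[str]], candidates: list[str]) -> np.ndarray:
    m = np.zeros((len(sets), len(candidates)), dtype=float)
    cidx = {c: j for j, c in enumerate(candidates)}
    for i, s in enumerate(sets):
        for p in s:
            m[i, cidx[p]] = 1.0
    return m


def _softmax(logw: np.ndarray) -> np.ndarray:
    w = np.exp(logw - logw.max())
    return w / w.sum()


def joint_edge_posteriors(
    scores: dict[tuple[Context, str], tuple[list[frozenset[str]], np.ndarray]],
    prior: PriorNetwork | None,
    config: LearningConfig,
    contexts: list[Context],
    nodes: list[str],
) -> dict[Context, EdgeProbabilityNetwork]:
    """Mean-field joint posterior over the context-specific structures.

    Per child and context, parent-set posteriors are proportional to
    ``exp(logML - eta_n * |S (symm diff) prior parents|
    - lambda_n * sum_{c' != c} E[edge disagreement with c'])`` where the
    expectation uses the other contexts' current edge marginals,
    ``eta_n = eta * kappa_eta`` and
    ``lambda_n = lambda/(C-1) * kappa_lambda``.  Initialized from the
    eta-only posterior and iterated cyclically (contexts, then children,
    in declared order) until the largest edge-marginal change is below
    ``tol``.  Returns converged marginals; warns if ``max_iter`` is hit.
    """
    C = len(contexts)
    # no prior network -> no prior energy (eta only meaningful with a prior)
    eta_n = config.eta_prior * config.kappa_eta if prior is not None else 0.0
    lam_n = (config.lambda_joint / (C - 1)) * config.kappa_lambda if C > 1 else 0.0

    cand: dict[str, list[str]] = {c: [n for n in nodes if n != c] for c in nodes}
    memb: dict[str, np.ndarray] = {}
    prior_vec: dict[str, np.ndarray] = {}
    prior_energy: dict[str, np.ndarray] = {}
    for child in nodes:
        sets, _ = scores[(contexts[0], child)]
        m = _membership(sets, cand[child])
        memb[child] = m
        pv = np.zeros(len(cand[child]))
        if prior is not None:
            parents = prior.parents_of(child)
            for j, c in enumerate(cand[child]):
                pv[j] = 1.0 if c in parents else 0.0
        prior_vec[child] = pv
        # |S symm-diff prior| = sum_j [ m_ij (1-pv_j) + (1-m_ij) pv_j ]
        prior_energy[child] = m @ (1.0 - pv) + (1.0 - m) @ pv

    # marginals[context][child] -> vector over candidates
    marg: dict[Context, dict[str, np.ndarray]] = {}
    post: dict[tuple[Context, str], np.ndarray] = {}
    for ctx in contexts:
        marg[ctx] = {}
        for child in nodes:
            _, logml = scores[(ctx, child)]
            w = _softmax(logml - eta_n * prior_energy[child])
            post[(ctx, child)] = w
            marg[ctx][child] = w @ memb[child]

    if lam_n > 0.0 and C > 1:
        delta = np.inf
        for it in range(config.max_iter):
            delta = 0.0
            for ctx in contexts:
                for child in nodes:
                    _, logml = scores[(ctx, child)]
                    m = memb[child]
                    others = [marg[c2][child] for c2 in contexts if c2 != ctx]
                    s_in = np.sum([1.0 - o for o in others], axis=0)
                    s_out = np.sum(others, axis=0)
                    couple = m @ s_in + (1.0 - m) @ s_out
                    w = _softmax(logml - eta_n * prior_energy[child] - lam_n * couple)
                    new_m = w @ m
                    delta = max(delta, float(np.max(np.abs(new_m - marg[ctx][child]))))
                    post[(ctx, child)] = w
                    marg[ctx][child] = new_m
            if delta < config.tol:
                break
        else:
            warnings.warn(
                f"mean-field iteration did not converge (last delta {delta:.2e})"
            )

    out: dict[Context, EdgeProbabilityNetwork] = {}
    for ctx in contexts:
        prob = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for child in nodes:
            for j, parent in enumerate(cand[child]):
                prob.loc[child, parent] = marg[ctx][child][j]
        out[ctx] = EdgeProbabilityNetwork(context=ctx, prob=prob)
    return out


def learn_networks(
    data: RppaDataset,
    prior: PriorNetwork | None,
    regimes: list[InhibitorRegime],
    config: LearningConfig | None = None,
    contexts: list[Context] | None = None,
    time_points: tuple[float, ...] = ANALYSIS_TIMES,
) -> dict[Context, EdgeProbabilityNetwork]:
    """End-to-end learning: designs -> parent-set scores -> joint posterior.

    Deterministic given the configuration (fixed context and node order).
    """
    config = config or LearningConfig()
    contexts = contexts or data.contexts()
    nodes = data.antibody_names
    scores: dict[tuple[Context, str], tuple[list[frozenset[str]], np.ndarray]] = {}
    for ctx in contexts:
        design = build_design(
            data, regimes, ctx, mode=config.intervention_mode, time_points=time_points
        )
        for child in nodes:
            scores[(ctx, child)] = score_parent_sets(design, child, config)
    return joint_edge_posteriors(scores, prior, config, contexts, nodes)


# ---------------------------------------------------------------------------
# summaries and controls
# ---------------------------------------------------------------------------

def summarize_cell_line_network(
    networks: list[EdgeProbabilityNetwork],
    threshold: float = 0.2,
    prior: PriorNetwork | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average edge probabilities across one cell line's stimulus networks.

    Returns the element-wise mean matrix and the edge list with mean
    probability strictly greater than ``threshold``, flagged for prior
    membership.  Averages over the available networks if fewer than
    eight are given (count recorded in the table attrs).
    """
    if not networks:
        raise ValueError("no networks to summarize")
    ref = networks[0].prob
    mats = []
    for net in networks:
        if list(net.prob.index) != list(ref.index):
            raise ValueError("networks must share node order")
        mats.append(net.prob.to_numpy())
    mean = pd.DataFrame(np.mean(mats, axis=0), index=ref.index, columns=ref.columns)
    rows = []
    for child in mean.index:
        for parent in mean.columns:
            p = float(mean.loc[child, parent])
            if parent != child and p > threshold:
                in_prior = bool(prior and (parent, child) in prior.edges)
                rows.append((parent, child, p, in_prior))
    edges = pd.DataFrame(rows, columns=["parent", "child", "mean_probability", "in_prior"])
    edges = edges.sort_values("mean_probability", ascending=False).reset_index(drop=True)
    edges.attrs["n_networks"] = len(networks)
    return mean, edges


def permute_time_order(data: RppaDataset, seed: int = 0) -> RppaDataset:
    """Negative control: shuffle the time order within every
    (context, regime, replicate) series, destroying lag-1 structure while
    preserving the marginal distribution of values."""
    rng = np.random.default_rng(seed)
    out = data.copy()
    keys = ["cell_line", "stimulus", "inhibitor", "replicate"]
    for _, idx in out.meta.groupby(keys, sort=False).groups.items():
        idx = list(idx)
        perm = rng.permutation(len(idx))
        out.values.loc[idx] = out.values.loc[[idx[k] for k in perm]].to_numpy()
    return out
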