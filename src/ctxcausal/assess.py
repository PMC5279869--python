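"""Held-out-inhibitor assessment of causal network learning.

Networks are learned on training data that excludes one inhibitor
regime; the held-out (test) regime's salient-change calls define a
context-specific gold-standard descendant set.  Sweeping a threshold
over the learned edge probabilities yields, per threshold, the
graph-reachable descendants of the test inhibitor's target nodes; the
true/false positive rates against the gold set trace an ROC curve whose
area (AUROC) is the assessment metric.  Significance comes from an
empirical null: AUROCs of uniformly random edge-probability matrices.

A split is valid only when the test regime's targets are network nodes
and every training regime's targets are disjoint from them (training is
always maximal).  By default the ROC universe excludes the test
targets themselves, since a target trivially responds to its own
inhibitor.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rppa_io import Context, InhibitorRegime, PriorNetwork, RppaDataset
from .descendancy import build_descendancy_matrix, call_salient_changes
from .netlearn import EdgeProbabilityNetwork, LearningConfig, learn_networks

__all__ = [
    "TrainTestSplit",
    "AssessmentResult",
    "make_train_test_splits",
    "reach_capacities",
    "descendants_at_threshold",
    "descendant_roc_auroc",
    "empirical_null_pvalue",
    "run_full_assessment",
    "results_to_frame",
]


@dataclass
class TrainTestSplit:
    test_regime: InhibitorRegime
    train_regimes: list[InhibitorRegime]
    valid: bool
    reason: str = ""


@dataclass
class AssessmentResult:
    context: Context
    test_regime_id: str
    auroc: float
    p_empirical: float
    n_gold: int
    null_aurocs: np.ndarray | None = field(default=None, repr=False)


def make_train_test_splits(
    regimes: list[InhibitorRegime], network_nodes: set[str]
) -> list[TrainTestSplit]:
    """Enumerate candidate test regimes with maximal training sets.

    Valid iff the test targets are all network nodes and at least one
    non-control regime with disjoint targets remains for training; the
    control regime always joins the training set.
    """
    controls = [r for r in regimes if r.is_control]
    candidates = [r for r in regimes if not r.is_control]
    splits = []
    for test in candidates:
        if not test.target_nodes:
            splits.append(TrainTestSplit(test, [], False, "no annotated targets"))
            continue
        if not test.target_nodes <= network_nodes:
            missing = sorted(test.target_nodes - network_nodes)
            splits.append(
                TrainTestSplit(test, [], False, f"target(s) not in network: {missing}")
            )
            continue
        train = [r for r in candidates if r is not test and not (r.target_nodes & test.target_nodes)]
        if not train:
            splits.append(TrainTestSplit(test, [], False, "empty training set"))
            continue
        splits.append(TrainTestSplit(test, controls + train, True))
    return splits


# ---------------------------------------------------------------------------
# descendant prediction
# ---------------------------------------------------------------------------

def _capacities(w: np.ndarray, target_idx: list[int]) -> np.ndarray:
    """Widest-path capacities from a target index set on w[child, parent]."""
    n = w.shape[0]
    cap = np.full(n, -np.inf)
    for j in target_idx:
        out = w[:, j].copy()
        out[j] = -np.inf
        cap = np.maximum(cap, out)
    heap = [(-cap[i], i) for i in range(n) if cap[i] > -np.inf]
    heapq.heapify(heap)
    done = np.zeros(n, dtype=bool)
    while heap:
        negc, j = heapq.heappop(heap)
        if done[j]:
            continue
        done[j] = True
        relax = np.minimum(-negc, w[:, j])
        relax[j] = -np.inf
        better = relax > cap
        if better.any():
            cap = np.where(better, relax, cap)
            for i in np.flatnonzero(better):
                heapq.heappush(heap, (-cap[i], i))
    return cap


def reach_capacities(prob: pd.DataFrame, targets: set[str]) -> pd.Series:
    """Widest-path reachability capacity from the target set.

    ``cap[v]`` is the maximum over directed paths (>= 1 edge) from any
    target to ``v`` of the minimum edge probability along the path, and
    -inf for unreachable nodes.  Then, for any threshold t, the
    descendant set is exactly ``{v : cap[v] >= t}``.
    """
    nodes = list(prob.index)
    idx = {n: i for i, n in enumerate(nodes)}
    for t in targets:
        if t not in idx:
            raise ValueError(f"target {t!r} not a network node")
    cap = _capacities(prob.to_numpy(), [idx[t] for t in targets])
    return pd.Series(cap, index=nodes)


def descendants_at_threshold(
    network: EdgeProbabilityNetwork | pd.DataFrame,
    targets: set[str],
    threshold: float,
) -> set[str]:
    """Nodes reachable from the targets via edges with probability >=
    threshold (targets included only if reachable through >= 1 edge)."""
    prob = network.prob if isinstance(network, EdgeProbabilityNetwork) else network
    cap = reach_capacities(prob, targets)
    return set(cap.index[cap >= threshold])


def descendant_roc_auroc(
    network: EdgeProbabilityNetwork | pd.DataFrame,
    targets: set[str],
    gold: set[str],
    universe: set[str],
) -> tuple[np.ndarray, float]:
    """Threshold-sweep descendant ROC curve and its area.

    Thresholds run over the sorted unique edge probabilities
    (descending, preceded by a supra-maximal value); at each, TPR and
    FPR are computed from the thresholded descendant set against the
    gold positives P = gold and negatives N = universe - gold - targets.
    The curve is anchored at (0,0) and (1,1), sorted by FPR with ties
    resolved by the maximal TPR, monotonized, and integrated by
    trapezoid.  Returns (curve points as an (m, 2) FPR/TPR array, auroc).
    """
    prob = network.prob if isinstance(network, EdgeProbabilityNetwork) else network
    positives = set(gold) & set(universe)
    negatives = set(universe) - set(gold) - set(targets)
    if not positives or not negatives:
        raise ValueError("ROC undefined: positives and negatives must be non-empty")
    nodes = list(prob.index)
    idx = {n: i for i, n in enumerate(nodes)}
    return _roc_core(
        prob.to_numpy(),
        [idx[t] for t in targets],
        [idx[n] for n in positives],
        [idx[n] for n in negatives],
    )


def _roc_core(
    w: np.ndarray, target_idx: list[int], pos_idx: list[int], neg_idx: list[int]
) -> tuple[np.ndarray, float]:
    cap = _capacities(w, target_idx)
    off_diag = w[~np.eye(w.shape[0], dtype=bool)]
    thresholds = np.concatenate(([off_diag.max() + 1.0], np.unique(off_diag)[::-1]))
    tpr = (cap[pos_idx][None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (cap[neg_idx][None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = np.concatenate(([0.0], fpr, [1.0]))
    tpr = np.concatenate(([0.0], tpr, [1.0]))
    # sort by FPR, resolve ties by the maximal TPR, monotonize
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    keep = np.r_[fpr[1:] != fpr[:-1], True]  # last point of each FPR tie group
    curve = np.column_stack((fpr[keep], np.maximum.accumulate(tpr[keep])))
    auroc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return curve, auroc


def empirical_null_pvalue(
    observed_auroc: float,
    targets: set[str],
    gold: set[str],
    universe: set[str],
    nodes: list[str],
    n_null: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Empirical p-value from uniformly random edge-probability matrices.

    Draws ``n_null`` matrices of independent U(0,1) edge probabilities
    over the same node set, scores each with the descendant ROC, and
    returns ``p = (1 + #{null >= observed}) / (1 + n_null)`` with the
    null sample.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_null)
    p = len(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    target_idx = [idx[t] for t in targets]
    pos_idx = [idx[n] for n in (set(gold) & set(universe))]
    neg_idx = [idx[n] for n in (set(universe) - set(gold) - set(targets))]
    for b in range(n_null):
        mat = rng.uniform(size=(p, p))
        np.fill_diagonal(mat, 0.0)
        _, nulls[b] = _roc_core(mat, target_idx, pos_idx, neg_idx)
    p_emp = (1.0 + int((nulls >= observed_auroc).sum())) / (1.0 + n_null)
    return float(p_emp), nulls


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_full_assessment(
    data: RppaDataset,
    prior: PriorNetwork | None,
    regimes: list[InhibitorRegime],
    averaged: RppaDataset,
    config: LearningConfig | None = None,
    contexts: list[Context] | None = None,
    n_null: int = 1000,
    q: float = 0.05,
    tau: float = 1.0,
    include_targets_in_universe: bool = False,
    seed: int = 0,
) -> list[AssessmentResult]:
    """Train-and-test assessment over all valid held-out-inhibitor splits.

    ``data`` is the replicate-level QC-passed dataset (for gold-standard
    change calls under the test regime); ``averaged`` is the
    replicate-averaged imputed dataset used for network learning.  For
    each valid split, networks are retrained on the training regimes
    only, and each context's predicted descendants of the test targets
    are scored against that context's gold-standard descendant set.
    """
    config = config or LearningConfig()
    contexts = contexts or averaged.contexts()
    nodes = averaged.antibody_names
    splits = [s for s in make_train_test_splits(regimes, set(nodes)) if s.valid]
    results: list[AssessmentResult] = []
    for s_i, split in enumerate(splits):
        test_id = split.test_regime.regime_id
        calls = []
        for ctx in contexts:
            calls.extend(call_salient_changes(data, test_id, ctx, q=q, tau=tau))
        if not calls:
            warnings.warn(f"no calls available for test regime {test_id}")
            continue
        cdm = build_descendancy_matrix(calls, proteins=nodes, contexts=contexts)
        networks = learn_networks(averaged, prior, split.train_regimes, config, contexts)
        targets = set(split.test_regime.target_nodes)
        universe = set(nodes) if include_targets_in_universe else set(nodes) - targets
        for c_i, ctx in enumerate(contexts):
            col = cdm.entries[str(ctx)]
            gold = set(col.index[(col.notna()) & (col != 0)]) - targets
            if not gold:
                warnings.warn(f"{ctx}/{test_id}: empty gold set; excluded")
                continue
            if not (universe - gold - targets):
                warnings.warn(f"{ctx}/{test_id}: no negatives; excluded")
                continue
            _, auroc = descendant_roc_auroc(networks[ctx], targets, gold, universe)
            p_emp, nulls = empirical_null_pvalue(
                auroc,
                targets,
                gold,
                universe,
                nodes,
                n_null=n_null,
                seed=seed + 1000 * s_i + c_i,
            )
            results.append(
                AssessmentResult(
                    context=ctx,
                    test_regime_id=test_id,
                    auroc=auroc,
                    p_empirical=p_emp,
                    n_gold=len(gold),
                    null_aurocs=nulls,
                )
            )
    return results


def results_to_frame(results: list[AssessmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_line": [r.context.cell_line for r in results],
            "stimulus": [r.context.stimulus for r in results],
            "test_regime": [r.test_regime_id for r in results],
            "auroc": [r.auroc for r in results],
            "p_empirical": [r.p_empirical for r in results],
            "n_gold": [r.n_gold for r in results],
        }
    )
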