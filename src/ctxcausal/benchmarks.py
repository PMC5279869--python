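"""Synthetic evaluation studies for the full pipeline.

Each function sets up a simulated study under stated conditions, runs the
relevant pipeline stage(s) end to end, and returns summary numbers:
normalization contract checks, null calibration of the salient-change
caller, its power against planted effects, directed-edge recovery of the
network learner (with time-shuffled and unmasked controls), the
descendant-AUROC null, and held-out-inhibitor assessment significance.

Problem sizes follow the package's standard synthetic study: 10-node
networks, 4 contexts, the 7-point design with 16 replicates at t = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rppa_io import Context, InhibitorRegime, RppaDataset
from .synthetic_data import (
    SimulationDesign,
    default_regimes,
    hub_regimes,
    sample_context_networks,
    simulate_change_panel,
    simulate_rppa_dataset,
    strong_signal_model,
)
from .preprocess import (
    average_replicates,
    batch_normalize,
    compute_snr,
    impute_time_course,
    median_center_loading,
    _dmso_stats,
)
from .descendancy import (
    build_descendancy_matrix,
    call_salient_changes,
    context_difference_stats,
)
from .netlearn import LearningConfig, learn_networks, permute_time_order
from .assess import descendant_roc_auroc, run_full_assessment, results_to_frame

DEFAULT_CONTEXTS = [Context(cl, st) for cl in ("CL1", "CL2") for st in ("S1", "S2")]


# ---------------------------------------------------------------------------
# normalization contracts
# ---------------------------------------------------------------------------

def batch_normalization_contract(seed: int = 0) -> dict:
    """Two-batch study with a planted affine batch effect.

    Batch 2 (its own replicates, DMSO controls included) is shifted and
    scaled per antibody; after loading normalization and batch
    normalization, the batch-2 DMSO mean/SD must equal batch 1's.
    Returns the maximum absolute deviations.
    """
    rng = np.random.default_rng(seed)
    ctx = [Context("UACC812", "EGF"), Context("UACC812", "FGF1")]
    model = sample_context_networks(8, ctx, seed=seed)

    def run(regimes, batch_id, rep_offset):
        data = simulate_rppa_dataset(
            model, SimulationDesign(regimes=regimes, n_rep_t0=8)
        )
        data.meta["batch"] = batch_id
        data.meta["replicate"] += rep_offset
        return data

    regs = default_regimes(model.nodes, 2)
    b1 = run((regs[0], regs[1]), "B1", 0)
    b2 = run((regs[0], regs[2]), "B2", 100)
    shift = rng.uniform(-2.0, 2.0, size=len(model.nodes))
    scale = rng.uniform(0.5, 2.0, size=len(model.nodes))
    b2.values.loc[:, :] = shift + scale * b2.values

    b1n, _ = median_center_loading(b1)
    b2n, _ = median_center_loading(b2)
    combined, stats = batch_normalize(b1n, b2n)
    sub2 = combined.subset((combined.meta["batch"] == "B2").to_numpy())
    mu, sd = _dmso_stats(sub2, combined.antibody_names)
    return {
        "max_mean_deviation": float((mu - stats.table["mu1"]).abs().max()),
        "max_sd_deviation": float((sd - stats.table["sigma1"]).abs().max()),
    }


def loading_normalization_checks(seed: int = 0, n_random: int = 100) -> dict:
    """Worked 3x3 matrix plus the per-sample median invariant on random data."""
    from .preprocess import median_center_loading as mcl
    from .rppa_io import META_COLUMNS

    def dataset(mat):
        n = len(mat)
        meta = pd.DataFrame(
            {
                "cell_line": ["MCF7"] * n,
                "stimulus": ["EGF"] * n,
                "inhibitor": ["DMSO"] * n,
                "time_min": [0.0] * n,
                "replicate": range(1, n + 1),
                "batch": ["B1"] * n,
            }
        )[META_COLUMNS]
        vals = pd.DataFrame(np.asarray(mat, dtype=float),
                            columns=[f"AB{j}" for j in range(mat.shape[1])])
        return RppaDataset(meta, vals, scale="log2")

    worked = np.array([[0.0, 1, 2], [1, 2, 3], [2, 3, 4]])
    out, cf = mcl(dataset(worked))
    worked_cf_ok = np.allclose(cf.cf_log2, [-1, 0, 1]) and np.allclose(
        out.values.to_numpy(), [[1, 2, 3]] * 3
    )
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_random):
        mat = rng.normal(10, 2, size=(6, 9))
        data = dataset(mat)
        out, _ = mcl(data)
        centered = out.values - data.values.median(axis=0)
        worst = max(worst, float(centered.median(axis=1).abs().max()))
    return {"worked_example_ok": worked_cf_ok, "max_median_invariant_violation": worst}


# ---------------------------------------------------------------------------
# change-caller calibration and power
# ---------------------------------------------------------------------------

def null_change_call_rate(
    n_panels: int = 2000, n_proteins: int = 35, noise_sd: float = 0.05, seed: int = 0
) -> dict:
    """Fraction of all-null panels with at least one salient call.

    Each panel is one (context, regime) family of ``n_proteins``
    phosphoproteins with no true effects; the caller's family-wise rate
    should not exceed the FDR level q = 0.05 (any call on a null panel
    is a false discovery).
    """
    ctx = Context("MCF7", "EGF")
    hits = 0
    for b in range(n_panels):
        panel = simulate_change_panel(
            n_proteins, None, noise_sd=noise_sd, seed=seed * 1_000_003 + b
        )
        calls = call_salient_changes(panel, "INH", ctx)
        hits += any(c.salient for c in calls)
    rate = hits / n_panels
    return {
        "rate": rate,
        "mc_se": float(np.sqrt(max(rate, 1 / n_panels) * (1 - rate) / n_panels)),
        "n": n_panels,
    }


def change_call_power(
    n_contexts: int = 200,
    n_proteins: int = 35,
    n_effect: int = 5,
    effect_x_noise: float = 5.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> dict:
    """Sensitivity and null false-call rate with planted 5x-noise effects."""
    ctx = Context("MCF7", "EGF")
    rng = np.random.default_rng(seed)
    tp = fn = fp = tn = sign_ok = sign_n = 0
    for b in range(n_contexts):
        effects = np.zeros(n_proteins)
        idx = rng.choice(n_proteins, size=n_effect, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_effect)
        effects[idx] = effect_x_noise * noise_sd * signs
        panel = simulate_change_panel(
            n_proteins, effects, noise_sd=noise_sd, seed=seed * 999_983 + b
        )
        calls = {c.phosphoprotein: c for c in call_salient_changes(panel, "INH", ctx)}
        for j, name in enumerate(panel.antibody_names):
            call = calls[name]
            if effects[j] != 0:
                tp += call.salient
                fn += not call.salient
                if call.salient:
                    sign_n += 1
                    sign_ok += call.sign == -int(np.sign(effects[j]))
            else:
                fp += call.salient
                tn += not call.salient
    return {
        "sensitivity": tp / (tp + fn),
        "false_call_rate": fp / (fp + tn),
        "sign_accuracy": sign_ok / sign_n if sign_n else np.nan,
        "n": n_contexts,
    }


# ---------------------------------------------------------------------------
# network recovery
# ---------------------------------------------------------------------------

def _edge_recovery_auroc(model, networks) -> float:
    from sklearn.metrics import roc_auc_score

    p = len(model.nodes)
    mask = ~np.eye(p, dtype=bool)
    scores = []
    for ctx in model.contexts:
        truth = model.W[ctx].copy()
        np.fill_diagonal(truth, 0.0)
        scores.append(
            roc_auc_score((truth != 0)[mask], networks[ctx].prob.to_numpy()[mask])
        )
    return float(np.mean(scores))


def network_recovery_study(
    n_seeds: int = 20, p_nodes: int = 10, n_inhibitors: int = 3, seed: int = 0
) -> dict:
    """Directed-edge recovery under strong dynamic signal, over seeds.

    For each seed: simulate a 4-context study (tonic activity disabled so
    the information is purely dynamic and the time-shuffled control is a
    clean null), learn networks with interventional masking, without
    masking, and on time-shuffled data, and score edge recovery AUROC
    against the generator's edge sets.  Reports means, the per-seed
    masking advantage, and a sign-test p-value for it.
    """
    rows = []
    for s in range(n_seeds):
        model = strong_signal_model(
            p_nodes, DEFAULT_CONTEXTS, seed=seed * 7919 + s, tonic_range=(0.0, 0.0)
        )
        regs = list(default_regimes(model.nodes, n_inhibitors))
        data = simulate_rppa_dataset(model, SimulationDesign(regimes=tuple(regs)))
        avg, _ = average_replicates(data)
        comp, _ = impute_time_course(avg)
        shuffled, _ = impute_time_course(permute_time_order(avg, seed=seed * 7919 + s))
        out = {}
        for label, mode, dset in [
            ("fix_baseline", "fix_baseline", comp),
            ("unmasked", "off", comp),
            ("shuffled", "fix_baseline", shuffled),
        ]:
            cfg = LearningConfig(
                lambda_joint=3.0, eta_prior=0.0, d_max=3, intervention_mode=mode
            )
            nets = learn_networks(dset, None, regs, cfg)
            out[label] = _edge_recovery_auroc(model, nets)
        rows.append(out)
    table = pd.DataFrame(rows)
    wins = int((table["fix_baseline"] > table["unmasked"]).sum())
    sign_p = float(sps.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue)
    return {
        "auroc_fix_baseline": float(table["fix_baseline"].mean()),
        "auroc_unmasked": float(table["unmasked"].mean()),
        "auroc_shuffled": float(table["shuffled"].mean()),
        "masking_wins": wins,
        "masking_sign_test_p": sign_p,
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# assessment machinery
# ---------------------------------------------------------------------------

def null_descendant_auroc(
    n_draws: int = 1000, n_nodes: int = 35, gold_size: int = 10, seed: int = 0
) -> dict:
    """Mean descendant AUROC of uniformly random edge-probability matrices
    against a fixed gold set (should sit at chance, 0.5)."""
    rng = np.random.default_rng(seed)
    nodes = [f"P{i:02d}" for i in range(n_nodes)]
    targets = {nodes[0]}
    gold = set(nodes[1 : 1 + gold_size])
    universe = set(nodes) - targets
    vals = np.empty(n_draws)
    for b in range(n_draws):
        mat = rng.uniform(size=(n_nodes, n_nodes))
        np.fill_diagonal(mat, 0.0)
        prob = pd.DataFrame(mat, index=nodes, columns=nodes)
        _, vals[b] = descendant_roc_auroc(prob, targets, gold, universe)
    return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)), "n": n_draws}


def assessment_study(
    p_nodes: int = 35,
    edge_density: float = 0.05,
    n_inhibitors: int = 4,
    n_null: int = 1000,
    seed: int = 0,
) -> dict:
    """Held-out-inhibitor assessment on a strong-signal synthetic study.

    Emulates the study's geometry: a 35-node panel, a sparse base
    network serving as the prior, inhibitors aimed at hub nodes (as
    kinase inhibitors are), tonic activity on (so inhibitions produce
    salient descendant changes), learning with the study's lambda = 3
    and eta = 15.  Reports the fraction of (context, test regime)
    assessments with empirical p < 0.05, plus the mean AUROC.
    """
    model = strong_signal_model(p_nodes, DEFAULT_CONTEXTS, seed=seed,
                                tonic_range=(0.5, 1.5), edge_density=edge_density,
                                n_entry=5, topology="layered")
    regs = list(hub_regimes(model, n_inhibitors))
    data = simulate_rppa_dataset(model, SimulationDesign(regimes=tuple(regs)))
    avg, _ = average_replicates(data)
    comp, _ = impute_time_course(avg)
    cfg = LearningConfig(lambda_joint=3.0, eta_prior=15.0, d_max=2)
    results = run_full_assessment(
        data, model.prior_network(), regs, comp, config=cfg, n_null=n_null, seed=seed
    )
    frame = results_to_frame(results)
    return {
        "fraction_significant": float((frame.p_empirical < 0.05).mean()),
        "mean_auroc": float(frame.auroc.mean()),
        "n": len(frame),
        "table": frame,
    }


# ---------------------------------------------------------------------------
# descendancy summary on a full synthetic study
# ---------------------------------------------------------------------------

def descendancy_study(p_nodes: int = 35, n_inhibitors: int = 4, seed: int = 0) -> dict:
    """CDMs and context-difference statistics for one synthetic study."""
    model = strong_signal_model(p_nodes, DEFAULT_CONTEXTS, seed=seed,
                                tonic_range=(0.5, 1.5), rewire_frac=0.3,
                                edge_density=0.05, n_entry=5, topology="layered")
    regs = list(hub_regimes(model, n_inhibitors))
    data = simulate_rppa_dataset(model, SimulationDesign(regimes=tuple(regs)))
    cdms = {}
    for reg in regs:
        if reg.is_control:
            continue
        calls = []
        for ctx in model.contexts:
            calls.extend(call_salient_changes(data, reg.regime_id, ctx))
        cdms[reg.regime_id] = build_descendancy_matrix(
            calls, proteins=model.nodes, contexts=model.contexts
        )
    stats = context_difference_stats(cdms)
    snr_table, snr_summary = compute_snr(data)
    stats["mean_replicate_snr"] = snr_summary["grand_mean"]
    stats["n_contexts"] = len(model.contexts)
    return stats
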