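"""Identification of changes under kinase inhibition.

For each (phosphoprotein, context, inhibitor regime) a paired t test
compares the replicate-averaged DMSO and inhibitor time courses over the
seven analysis time points.  Phosphoproteins whose DMSO time course is
stimulus-responsive with a peak shape are retested restricted to the
intermediate time points within the peak, and the smaller p-value is
retained.  P-values are corrected per (context, regime) across the
phosphoprotein panel with the two-stage adaptive linear step-up FDR
procedure.  A change is *salient* when the FDR value is below 5% and the
effect size (mean log2 DMSO/inhibitor ratio) is large relative to the
averaged pooled replicate SD.  Salient calls are collected into causal
descendancy matrices (CDMs): phosphoprotein x context sign matrices per
regime (+1 increase under inhibition, -1 decrease, 0 no salient change).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rppa_io import ANALYSIS_TIMES, Context, RppaDataset
from .preprocess import impute_series

__all__ = [
    "PairedTestResult",
    "ChangeCall",
    "DescendancyMatrix",
    "paired_mean_test",
    "detect_peak_window",
    "adaptive_fdr",
    "pooled_replicate_sd",
    "call_salient_changes",
    "calls_to_frame",
    "build_descendancy_matrix",
    "context_difference_stats",
]


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    effect: float  # mean(dmso - inhib), log2 ratio DMSO/inhibitor
    degenerate: bool = False


@dataclass
class ChangeCall:
    phosphoprotein: str
    context: Context
    regime_id: str
    p_full: float
    p_peak: float | None
    p_final: float
    q_fdr: float
    effect: float
    rep_sd: float
    salient: bool
    sign: int


@dataclass
class DescendancyMatrix:
    """Per-regime phosphoprotein x context sign matrix in {-1, 0, +1}.

    Missing (context, protein) cells are NaN, not 0."""

    regime_id: str
    entries: pd.DataFrame


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def paired_mean_test(dmso: np.ndarray, inhib: np.ndarray) -> PairedTestResult:
    """Paired t test on per-time-point differences ``d_t = dmso_t - inhib_t``.

    ``t = mean(d) / (SD(d)/sqrt(n))`` with a two-sided p from the t
    distribution on n-1 df.  Degenerate series (SD(d) = 0) give p = 0
    for a nonzero mean difference and p = 1 otherwise.
    """
    d = np.asarray(dmso, dtype=float) - np.asarray(inhib, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 paired time points")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, 1.0, 0.0, degenerate=True)
        return PairedTestResult(np.sign(mean) * np.inf, 0.0, mean, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), float(p), mean)


def detect_peak_window(
    dmso_series: np.ndarray,
    rep_sd: float,
    k_peak: float = 1.0,
    min_width: int = 2,
) -> np.ndarray | None:
    """Detect a stimulus-response peak in a DMSO time course.

    Fires iff the series maximum sits at an intermediate index and
    exceeds both the first and last values by more than
    ``k_peak * rep_sd``.  The window is the maximal contiguous run of
    intermediate indices (containing the maximum) whose values exceed
    the half height ``(max + min(first, last)) / 2``; windows narrower
    than ``min_width`` are discarded.  Returns the index array or None.
    """
    y = np.asarray(dmso_series, dtype=float)
    n = len(y)
    if n < 3:
        return None
    k = int(np.argmax(y))
    if k == 0 or k == n - 1:
        return None
    peak = y[k]
    if not (peak > y[0] + k_peak * rep_sd and peak > y[-1] + k_peak * rep_sd):
        return None
    half = (peak + min(y[0], y[-1])) / 2.0
    lo = k
    while lo - 1 >= 1 and y[lo - 1] > half:
        lo -= 1
    hi = k
    while hi + 1 <= n - 2 and y[hi + 1] > half:
        hi += 1
    window = np.arange(lo, hi + 1)
    return window if len(window) >= min_width else None


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (linear step-up)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def adaptive_fdr(
    pvalues: np.ndarray, q: float = 0.05, method: str = "two_stage"
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive two-stage linear step-up FDR control.

    Stage 1 runs the linear step-up procedure at ``q' = q/(1+q)`` giving
    r1 rejections; r1 = 0 rejects nothing, r1 = m rejects everything;
    otherwise the number of true nulls is estimated as ``m0 = m - r1``
    and stage 2 reruns the step-up at level ``q' * m / m0``.  Returns
    rejection flags and the implied adjusted values
    (stage-2 BH-adjusted p scaled by ``m0/m``; reject iff <= q').
    ``method="bh"`` gives the plain one-stage procedure.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, bool), np.zeros(0)
    if method == "bh":
        adj = _bh_adjust(p)
        return adj <= q, adj
    if method != "two_stage":
        raise ValueError(f"unknown method {method!r}")
    q1 = q / (1.0 + q)
    bh = _bh_adjust(p)
    r1 = int((bh <= q1).sum())
    if r1 == 0:
        return np.zeros(m, bool), bh
    if r1 == m:
        return np.ones(m, bool), bh / m
    m0 = m - r1
    adjusted = np.minimum(bh * m0 / m, 1.0)
    return adjusted <= q1, adjusted


def pooled_replicate_sd(
    dmso_reps: list[np.ndarray],
    inhib_reps: list[np.ndarray],
    fallback: float | None = None,
) -> tuple[float, bool]:
    """Averaged pooled replicate SD over time points.

    Per time point, the replicate variances of the DMSO and inhibitor
    arms are pooled with df weights and square-rooted; time points with
    no replication (no arm with >= 2 replicates) are skipped.  The mean
    over contributing time points is returned.  With no replicated time
    point at all, the ``fallback`` value is returned with a flag.
    """
    sds = []
    for arms in itertools.zip_longest(dmso_reps, inhib_reps, fillvalue=np.array([])):
        num = 0.0
        df = 0
        for reps in arms:
            reps = np.asarray(reps, dtype=float)
            reps = reps[~np.isnan(reps)]
            if len(reps) >= 2:
                num += (len(reps) - 1) * reps.var(ddof=1)
                df += len(reps) - 1
        if df > 0:
            sds.append(np.sqrt(num / df))
    if not sds:
        if fallback is None:
            raise ValueError("no replicated time points and no fallback provided")
        return float(fallback), True
    return float(np.mean(sds)), False


# ---------------------------------------------------------------------------
# salient-change calling
# ---------------------------------------------------------------------------

def _arm_blocks(
    sub: RppaDataset, regime_id: str, times: tuple[float, ...]
) -> list[np.ndarray]:
    """Per-time replicate blocks (n_rep x n_antibodies) for one arm."""
    mask = (sub.meta["inhibitor"] == regime_id).to_numpy()
    tvals = sub.meta.loc[mask, "time_min"].to_numpy()
    vals = sub.values.loc[mask].to_numpy(dtype=float)
    return [vals[tvals == t] for t in times]


def _series_from_blocks(
    blocks: list[np.ndarray], j: int, times: tuple[float, ...]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Replicate-averaged series and per-time replicate sets for antibody j."""
    reps = []
    means = np.full(len(times), np.nan)
    for k, block in enumerate(blocks):
        r = block[:, j] if block.size else np.empty(0)
        r = r[~np.isnan(r)]
        reps.append(r)
        if len(r):
            means[k] = r.mean()
    if np.isnan(means).any():
        obs = ~np.isnan(means)
        if obs.sum() >= 2:
            means, _ = impute_series(np.asarray(times), means)
    return means, reps


def call_salient_changes(
    data: RppaDataset,
    regime_id: str,
    context: Context,
    q: float = 0.05,
    tau: float = 1.0,
    k_peak: float = 1.0,
    peak_retest: bool = True,
    time_points: tuple[float, ...] = ANALYSIS_TIMES,
    fallback_rep_sd: float | None = None,
    fdr_method: str = "two_stage",
) -> list[ChangeCall]:
    """Call salient changes under one inhibitor regime in one context.

    ``data`` is the replicate-level, QC-passed log2 dataset; replicate
    averaging happens internally so the pooled replicate SD can be
    computed from the same series the tests use.  A phosphoprotein is
    salient iff the adaptive-FDR value is below ``q`` and the absolute
    effect over the tested window is at least ``tau`` times the averaged
    pooled replicate SD.  Sign convention: a positive effect
    (DMSO > inhibitor) is a decrease under inhibition, sign -1.
    """
    sub = data.select_context(context)
    regimes_present = set(sub.meta["inhibitor"])
    if "DMSO" not in regimes_present or regime_id not in regimes_present:
        warnings.warn(f"missing arm for {context}: need DMSO and {regime_id}; skipped")
        return []
    if fallback_rep_sd is None:
        fallback_rep_sd = _dataset_median_rep_sd(data)

    dmso_blocks = _arm_blocks(sub, "DMSO", time_points)
    inhib_blocks = _arm_blocks(sub, regime_id, time_points)
    records = []
    for j, ab in enumerate(sub.antibody_names):
        dmso_mean, dmso_reps = _series_from_blocks(dmso_blocks, j, time_points)
        inhib_mean, inhib_reps = _series_from_blocks(inhib_blocks, j, time_points)
        if np.isnan(dmso_mean).any() or np.isnan(inhib_mean).any():
            continue
        rep_sd, fb = pooled_replicate_sd(dmso_reps, inhib_reps, fallback=fallback_rep_sd)
        full = paired_mean_test(dmso_mean, inhib_mean)
        p_peak = None
        effect, sd_used = full.effect, rep_sd
        p_final = full.p
        if peak_retest:
            window = detect_peak_window(dmso_mean, rep_sd, k_peak=k_peak)
            if window is not None:
                peak = paired_mean_test(dmso_mean[window], inhib_mean[window])
                p_peak = peak.p
                if peak.p < full.p:
                    p_final = peak.p
                    effect = peak.effect
                    sd_used, _ = pooled_replicate_sd(
                        [dmso_reps[k] for k in window],
                        [inhib_reps[k] for k in window],
                        fallback=fallback_rep_sd,
                    )
        records.append((ab, full.p, p_peak, p_final, effect, sd_used))

    if not records:
        return []
    p_final = np.array([r[3] for r in records])
    reject, q_fdr = adaptive_fdr(p_final, q=q, method=fdr_method)
    calls = []
    for (ab, pf, pp, pfin, effect, sd_used), rej, qv in zip(records, reject, q_fdr):
        salient = bool(rej) and abs(effect) >= tau * sd_used
        sign = int(-np.sign(effect)) if salient else 0
        calls.append(
            ChangeCall(
                phosphoprotein=ab,
                context=context,
                regime_id=regime_id,
                p_full=pf,
                p_peak=pp,
                p_final=pfin,
                q_fdr=float(qv),
                effect=float(effect),
                rep_sd=float(sd_used),
                salient=salient,
                sign=sign,
            )
        )
    return calls


def _dataset_median_rep_sd(data: RppaDataset) -> float:
    """Median replicate SD across all replicated (condition, antibody) groups."""
    keys = ["cell_line", "stimulus", "inhibitor", "time_min"]
    grouped = data.meta.join(data.values).groupby(keys, sort=False)[data.antibody_names]
    sds = grouped.std(ddof=1).to_numpy().ravel()
    sds = sds[~np.isnan(sds)]
    return float(np.median(sds)) if len(sds) else 0.0


def calls_to_frame(calls: list[ChangeCall]) -> pd.DataFrame:
    rows = [
        {
            "phosphoprotein": c.phosphoprotein,
            "cell_line": c.context.cell_line,
            "stimulus": c.context.stimulus,
            "regime": c.regime_id,
            "p_full": c.p_full,
            "p_peak": c.p_peak,
            "p_final": c.p_final,
            "q_fdr": c.q_fdr,
            "effect": c.effect,
            "rep_sd": c.rep_sd,
            "salient": c.salient,
            "sign": c.sign,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# causal descendancy matrices
# ---------------------------------------------------------------------------

def build_descendancy_matrix(
    calls: list[ChangeCall],
    proteins: list[str] | None = None,
    contexts: list[Context] | None = None,
) -> DescendancyMatrix:
    """Assemble one regime's calls into a sign matrix.

    Cells without a corresponding call stay NaN (missing, not "no
    change").  All calls must share one regime.
    """
    if not calls:
        raise ValueError("no calls provided")
    regimes = {c.regime_id for c in calls}
    if len(regimes) > 1:
        raise ValueError(f"calls span multiple regimes: {sorted(regimes)}")
    proteins = proteins or sorted({c.phosphoprotein for c in calls})
    contexts = contexts or sorted({c.context for c in calls})
    entries = pd.DataFrame(
        np.nan, index=proteins, columns=[str(ctx) for ctx in contexts]
    )
    for c in calls:
        entries.loc[c.phosphoprotein, str(c.context)] = c.sign
    return DescendancyMatrix(regime_id=regimes.pop(), entries=entries)


def context_difference_stats(
    cdms: dict[str, DescendancyMatrix] | dict[str, pd.DataFrame],
) -> dict[str, float]:
    """Mean number of phosphoproteins salient in exactly one context of a pair.

    Counts presence/absence (nonzero entries, ignoring sign) over all
    unordered context pairs within each regime; proteins missing in
    either context of a pair are skipped.  Returns the grand mean over
    all regimes x pairs, the mean over pairs of cell lines sharing a
    stimulus, and the mean over pairs of stimuli sharing a cell line.
    """
    all_counts, cl_counts, stim_counts = [], [], []
    for regime_id, cdm in cdms.items():
        entries = cdm.entries if isinstance(cdm, DescendancyMatrix) else cdm
        cols = list(entries.columns)
        for a, b in itertools.combinations(cols, 2):
            ca, cb = Context.parse(a), Context.parse(b)
            va, vb = entries[a], entries[b]
            ok = va.notna() & vb.notna()
            count = int(((va[ok] != 0) != (vb[ok] != 0)).sum())
            all_counts.append(count)
            if ca.stimulus == cb.stimulus and ca.cell_line != cb.cell_line:
                cl_counts.append(count)
            if ca.cell_line == cb.cell_line and ca.stimulus != cb.stimulus:
                stim_counts.append(count)
    return {
        "grand_mean": float(np.mean(all_counts)) if all_counts else np.nan,
        "cell_line_pairs_mean": float(np.mean(cl_counts)) if cl_counts else np.nan,
        "stimulus_pairs_mean": float(np.mean(stim_counts)) if stim_counts else np.nan,
    }
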