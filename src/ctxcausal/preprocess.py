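"""Quality control and preprocessing of RPPA abundance data.

The chain, in order: log2 transform, per-batch loading normalization
(median centering across antibodies), two-batch normalization against
DMSO controls, sample QC/exclusion, replicate averaging, correlated
antibody-panel selection, and linear-interpolation imputation of missing
time points.

Loading normalization computes, per sample, a correction factor (CF): the
median across antibodies of antibody-centered log2 values.  Extreme CFs
(linear scale > 2.5 or < 0.25) flag outlier samples, as does a per-sample
log2 variance across antibodies above 40.  Signal-to-noise ratios
(mean / SD of t = 0 replicates, linear scale) below 1 flag replicate
groups for review without automatic exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rppa_io import ANALYSIS_TIMES, RppaDataset

__all__ = [
    "LoadingCorrection",
    "BatchStats",
    "QcReport",
    "median_center_loading",
    "batch_normalize",
    "compute_snr",
    "qc_flag_samples",
    "select_phospho_panel",
    "average_replicates",
    "impute_series",
    "impute_time_course",
    "preprocess_pipeline",
]

CF_UPPER = 2.5
CF_LOWER = 0.25
VARIANCE_LIMIT = 40.0
SNR_LIMIT = 1.0


@dataclass
class LoadingCorrection:
    """Per-sample loading correction factors (log2 offset and linear factor)."""

    table: pd.DataFrame  # columns: cf_log2, cf_linear

    @property
    def cf_log2(self) -> pd.Series:
        return self.table["cf_log2"]

    @property
    def cf_linear(self) -> pd.Series:
        return self.table["cf_linear"]


@dataclass
class BatchStats:
    """Per-antibody DMSO mean/SD for two batches (log2 scale)."""

    table: pd.DataFrame  # columns: mu1, sigma1, mu2, sigma2, sigma2_zero


@dataclass
class QcReport:
    cf: pd.DataFrame | None = None
    variance: pd.Series | None = None
    snr: pd.DataFrame | None = None
    excluded: dict[int, str] = field(default_factory=dict)
    snr_flagged_groups: list[tuple] = field(default_factory=list)
    dropped_antibodies: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# loading normalization
# ---------------------------------------------------------------------------

def median_center_loading(
    data: RppaDataset, batch_scope: str = "batch"
) -> tuple[RppaDataset, LoadingCorrection]:
    """Normalize for protein loading by median centering across antibodies.

    Within each batch: (1) center each antibody at its cross-sample
    median; (2) per sample, take the median across antibodies of the
    centered values as the correction factor CF; (3) subtract CF from the
    original log2 values.  Samples with no observed values are excluded
    with reason ``manual``.
    """
    if data.scale != "log2":
        raise ValueError("loading normalization operates on log2 data")
    out = data.copy()
    cf_log2 = pd.Series(np.nan, index=data.values.index, dtype=float)
    groups = (
        data.meta.groupby(batch_scope, sort=False).groups
        if batch_scope
        else {"all": data.meta.index}
    )
    for _, idx in groups.items():
        block = data.values.loc[idx]
        centered = block - block.median(axis=0, skipna=True)
        cf = centered.median(axis=1, skipna=True)
        cf_log2.loc[idx] = cf
        out.values.loc[idx] = block.sub(cf, axis=0)
    all_missing = data.values.isna().all(axis=1)
    for i in data.values.index[all_missing]:
        out.excluded[i] = "manual"
    table = pd.DataFrame({"cf_log2": cf_log2, "cf_linear": np.power(2.0, cf_log2)})
    return out, LoadingCorrection(table)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def _dmso_stats(data: RppaDataset, antibodies: list[str]) -> tuple[pd.Series, pd.Series]:
    """Per-antibody mean/SD of DMSO samples, with t = 0 replicates averaged
    to a single value per (stimulus) condition before the calculation."""
    dmso = data.subset((data.meta["inhibitor"] == "DMSO").to_numpy())
    joined = dmso.meta.join(dmso.values[antibodies])
    t0 = joined[joined["time_min"] == 0]
    later = joined[joined["time_min"] > 0]
    t0_avg = t0.groupby(["cell_line", "stimulus"], sort=False)[antibodies].mean()
    stacked = pd.concat([t0_avg.reset_index(drop=True), later[antibodies].reset_index(drop=True)])
    return stacked.mean(axis=0), stacked.std(axis=0, ddof=1)


def batch_normalize(batch1: RppaDataset, batch2: RppaDataset) -> tuple[RppaDataset, BatchStats]:
    """Map batch 2 onto batch 1 via the DMSO controls, per antibody.

    Antibodies absent from either batch are removed.  For each antibody
    the DMSO mean/SD (mu, sigma) are computed per batch -- with t = 0
    replicates averaged before the calculation -- and every individual
    batch-2 value x becomes ``mu1 + sigma1 * (x - mu2) / sigma2``.
    Antibodies with ``sigma2 = 0`` are centered only (``x - mu2 + mu1``)
    with a warning.  Returns the concatenated dataset and the stats used.
    """
    if batch1.scale != "log2" or batch2.scale != "log2":
        raise ValueError("batch normalization operates on log2 data")
    common = [a for a in batch1.antibody_names if a in set(batch2.antibody_names)]
    if not common:
        raise ValueError("no antibodies common to both batches")
    mu1, s1 = _dmso_stats(batch1, common)
    mu2, s2 = _dmso_stats(batch2, common)
    sigma2_zero = (s2 == 0) | s2.isna()
    if sigma2_zero.any():
        warnings.warn(
            f"sigma2 = 0 for {int(sigma2_zero.sum())} antibody(ies); center-only transform"
        )
    v2 = batch2.values[common].copy()
    scale = (s1 / s2).where(~sigma2_zero, 1.0)
    v2 = mu1 + scale * (v2 - mu2)
    meta = pd.concat([batch1.meta, batch2.meta], ignore_index=True)
    values = pd.concat(
        [batch1.values[common].reset_index(drop=True), v2.reset_index(drop=True)],
        ignore_index=True,
    )
    combined = RppaDataset(meta, values, scale="log2", antibodies=dict(batch1.antibodies))
    stats = pd.DataFrame(
        {"mu1": mu1, "sigma1": s1, "mu2": mu2, "sigma2": s2, "sigma2_zero": sigma2_zero}
    )
    return combined, BatchStats(stats)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def compute_snr(data: RppaDataset, use_linear: bool = True) -> tuple[pd.DataFrame, dict]:
    """Signal-to-noise ratio of the t = 0 replicates.

    SNR = mean / SD of the t = 0 replicate values per
    (cell line, antibody, regime), computed on linear-scale abundances by
    default.  Groups with a single replicate are skipped with a warning;
    SD = 0 yields an infinite-SNR flag.  Returns the table and a summary
    with the grand mean and SD of all finite SNRs.
    """
    vals = data.values
    if use_linear and data.scale == "log2":
        vals = np.power(2.0, vals)
    elif not use_linear and data.scale == "linear":
        vals = np.log2(vals.where(vals > 0))
    phospho = [
        a
        for a in data.antibody_names
        if not data.antibodies or data.antibodies[a].is_phospho
    ]
    t0 = data.meta["time_min"] == 0
    rows = []
    n_single = 0
    grouped = data.meta.loc[t0].groupby(["cell_line", "inhibitor"], sort=False).groups
    for (cl, reg), idx in grouped.items():
        block = vals.loc[idx, phospho]
        for ab in phospho:
            reps = block[ab].dropna()
            if len(reps) < 2:
                n_single += 1
                continue
            sd = reps.std(ddof=1)
            snr = np.inf if sd == 0 else reps.mean() / sd
            rows.append((cl, ab, reg, float(snr), len(reps), bool(sd == 0)))
    if n_single:
        warnings.warn(f"{n_single} replicate group(s) skipped (single replicate)")
    table = pd.DataFrame(
        rows, columns=["cell_line", "antibody", "inhibitor", "snr", "n_rep", "sd_zero"]
    )
    table["snr"] = table["snr"].astype(float)
    finite = table.loc[np.isfinite(table["snr"]), "snr"]
    summary = {
        "grand_mean": float(finite.mean()) if len(finite) else np.nan,
        "grand_sd": float(finite.std(ddof=1)) if len(finite) > 1 else np.nan,
    }
    return table, summary


def qc_flag_samples(
    data: RppaDataset,
    cf: LoadingCorrection,
    snr_table: pd.DataFrame | None = None,
    manual_exclusions: dict[int, str] | None = None,
) -> QcReport:
    """Flag outlier samples and low-SNR replicate groups.

    Exclusion reasons (one primary reason per sample, in priority order):
    ``manual`` (caller-provided list), ``cf_bounds`` (linear CF > 2.5 or
    < 0.25, strict), ``variance`` (log2 variance across antibodies > 40).
    SNR < 1 flags mark *replicate groups* for review and do not exclude.
    """
    report = QcReport(cf=cf.table)
    variance = data.values.var(axis=1, ddof=1)
    report.variance = variance
    excluded: dict[int, str] = {}
    for i, reason in (manual_exclusions or {}).items():
        excluded[i] = reason or "manual"
    cf_lin = cf.cf_linear
    cf_bad = (cf_lin > CF_UPPER) | (cf_lin < CF_LOWER)
    for i in data.values.index[cf_bad.reindex(data.values.index, fill_value=False)]:
        excluded.setdefault(i, "cf_bounds")
    var_bad = variance > VARIANCE_LIMIT
    for i in data.values.index[var_bad]:
        excluded.setdefault(i, "variance")
    report.excluded = excluded
    if snr_table is not None:
        report.snr = snr_table
        low = snr_table[snr_table["snr"] < SNR_LIMIT]
        report.snr_flagged_groups = [
            (r.cell_line, r.antibody, r.inhibitor) for r in low.itertuples()
        ]
    return report


# ---------------------------------------------------------------------------
# panel selection
# ---------------------------------------------------------------------------

def select_phospho_panel(
    data: RppaDataset,
    r_threshold: float = 0.9,
    priority: list[str] | None = None,
) -> tuple[RppaDataset, list[tuple[str, str]]]:
    """Restrict to phospho antibodies common to all cell lines and drop
    one of each highly correlated same-target pair.

    A pair of antibodies against the same target protein is collapsed iff
    their Pearson r exceeds ``r_threshold`` in *every* cell line.  The
    antibody later in the priority order (default lexicographic) is
    dropped.  Returns the reduced dataset and the (kept, dropped) pairs.
    """
    cell_lines = sorted(data.meta["cell_line"].unique())
    if data.antibodies:
        panel = [a for a in data.antibody_names if data.antibodies[a].is_phospho]
    else:
        panel = list(data.antibody_names)
    # keep antibodies observed in every cell line
    present = []
    for ab in panel:
        ok = all(
            data.values.loc[(data.meta["cell_line"] == cl).to_numpy(), ab].notna().any()
            for cl in cell_lines
        )
        if ok:
            present.append(ab)
    panel = present

    order = {a: k for k, a in enumerate(priority)} if priority else None

    def rank(a: str) -> tuple:
        return (order.get(a, len(order)), a) if order else (a,)

    by_target: dict[str, list[str]] = {}
    for ab in panel:
        target = data.antibodies[ab].target_node if data.antibodies else ab.split("_p")[0]
        by_target.setdefault(target, []).append(ab)

    dropped: list[tuple[str, str]] = []
    drop_set: set[str] = set()
    for target, abs_ in by_target.items():
        if len(abs_) < 2:
            continue
        for i in range(len(abs_)):
            for j in range(i + 1, len(abs_)):
                a, b = abs_[i], abs_[j]
                if a in drop_set or b in drop_set:
                    continue
                high_everywhere = True
                for cl in cell_lines:
                    mask = (data.meta["cell_line"] == cl).to_numpy()
                    x = data.values.loc[mask, a]
                    y = data.values.loc[mask, b]
                    ok = x.notna() & y.notna()
                    r = x[ok].corr(y[ok]) if ok.sum() >= 3 else np.nan
                    if not (r > r_threshold):
                        high_everywhere = False
                        break
                if high_everywhere:
                    keep, drop = sorted((a, b), key=rank)
                    drop_set.add(drop)
                    dropped.append((keep, drop))
    kept = [a for a in panel if a not in drop_set]
    out = RppaDataset(
        data.meta.copy(),
        data.values[kept].copy(),
        scale=data.scale,
        antibodies={a: v for a, v in data.antibodies.items() if a in kept},
    )
    return out, dropped


# ---------------------------------------------------------------------------
# replicate averaging and imputation
# ---------------------------------------------------------------------------

def average_replicates(data: RppaDataset) -> tuple[RppaDataset, pd.DataFrame]:
    """Average replicates on the log2 scale: one row per
    (cell line, stimulus, regime, time).  Returns the averaged dataset and
    the per-cell replicate counts (for pooled-SD computations downstream)."""
    if data.scale != "log2":
        raise ValueError("replicates are averaged on the log2 scale")
    keys = ["cell_line", "stimulus", "inhibitor", "time_min"]
    joined = data.meta.join(data.values)
    grouped = joined.groupby(keys, sort=False)
    mean = grouped[data.antibody_names].mean()
    counts = grouped[data.antibody_names].count()
    meta = mean.index.to_frame(index=False)
    meta["replicate"] = 1
    batch = data.meta.groupby(keys, sort=False)["batch"].first()
    meta["batch"] = batch.loc[pd.MultiIndex.from_frame(meta[keys])].to_numpy()
    values = mean.reset_index(drop=True)
    counts = counts.reset_index(drop=True)
    return (
        RppaDataset(
            meta[["cell_line", "stimulus", "inhibitor", "time_min", "replicate", "batch"]],
            values,
            scale="log2",
            antibodies=dict(data.antibodies),
        ),
        counts,
    )


def impute_series(
    times: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing values by linear interpolation in real time (minutes).

    Interior gaps are interpolated between adjacent observed time points;
    leading/trailing gaps take the nearest observed value.  Returns the
    completed series and a boolean imputation mask.  Raises if fewer than
    two points are observed.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed time points to impute")
    filled = np.interp(times, times[obs], values[obs])
    return filled, ~obs


def impute_time_course(
    data: RppaDataset, time_points: tuple[float, ...] = ANALYSIS_TIMES
) -> tuple[RppaDataset, pd.DataFrame]:
    """Complete every (context, regime) series over the analysis time grid.

    Operates on replicate-averaged data.  Series with fewer than two
    observed time points are left missing with a warning.  Returns the
    completed dataset and a long table flagging imputed entries.
    """
    keys = ["cell_line", "stimulus", "inhibitor"]
    joined = data.meta.join(data.values)
    out_rows, out_vals, flags = [], [], []
    n_excluded = 0
    for key, grp in joined.groupby(keys, sort=False):
        grp = grp.set_index("time_min").reindex(list(time_points))
        batch = grp["batch"].dropna().iloc[0] if grp["batch"].notna().any() else "B1"
        block = grp[data.antibody_names]
        t = np.asarray(time_points, dtype=float)
        filled = block.to_numpy(copy=True)
        for j, ab in enumerate(data.antibody_names):
            col = filled[:, j]
            if np.isnan(col).any():
                if (~np.isnan(col)).sum() < 2:
                    n_excluded += 1
                    continue
                filled[:, j], mask = impute_series(t, col)
                for k in np.flatnonzero(mask):
                    flags.append((*key, t[k], ab))
        for k, tv in enumerate(time_points):
            out_rows.append([*key, tv, 1, batch])
            out_vals.append(filled[k])
    if n_excluded:
        warnings.warn(f"{n_excluded} series left incomplete (<2 observed time points)")
    meta = pd.DataFrame(
        out_rows, columns=["cell_line", "stimulus", "inhibitor", "time_min", "replicate", "batch"]
    )
    values = pd.DataFrame(np.asarray(out_vals), columns=data.antibody_names)
    flag_table = pd.DataFrame(
        flags, columns=["cell_line", "stimulus", "inhibitor", "time_min", "antibody"]
    )
    return (
        RppaDataset(meta, values, scale="log2", antibodies=dict(data.antibodies)),
        flag_table,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def preprocess_pipeline(
    data: RppaDataset,
    r_threshold: float = 0.9,
    manual_exclusions: dict[int, str] | None = None,
    select_panel: bool = True,
) -> tuple[RppaDataset, RppaDataset, QcReport]:
    """Run the full preprocessing chain.

    Order: log2 transform -> per-batch loading normalization -> two-batch
    normalization for any cell line whose samples span two batches ->
    QC exclusions -> replicate averaging -> panel selection ->
    imputation.  Returns the replicate-level QC-passed dataset (needed
    for replicate-SD statistics), the averaged/imputed dataset, and the
    QC report.
    """
    log2 = data.to_log2()
    normalized, cf = median_center_loading(log2)

    # batch normalization per cell line spanning exactly two batches
    pieces = []
    for cl, idx in normalized.meta.groupby("cell_line", sort=False).groups.items():
        sub = normalized.subset(normalized.meta.index.isin(idx))
        batches = sorted(sub.meta["batch"].unique())
        if len(batches) == 2:
            b1 = sub.subset((sub.meta["batch"] == batches[0]).to_numpy())
            b2 = sub.subset((sub.meta["batch"] == batches[1]).to_numpy())
            merged, _ = batch_normalize(b1, b2)
            pieces.append(merged)
        else:
            pieces.append(sub)
    normalized = RppaDataset(
        pd.concat([p.meta for p in pieces], ignore_index=True),
        pd.concat([p.values for p in pieces], ignore_index=True),
        scale="log2",
        antibodies=dict(normalized.antibodies),
    )
    cf_table = LoadingCorrection(cf.table.reset_index(drop=True))

    snr_table, _ = compute_snr(normalized)
    report = qc_flag_samples(normalized, cf_table, snr_table, manual_exclusions)
    keep = ~normalized.values.index.isin(list(report.excluded))
    passed = normalized.subset(keep)

    averaged, _counts = average_replicates(passed)
    if select_panel:
        averaged, dropped = select_phospho_panel(averaged, r_threshold=r_threshold)
        report.dropped_antibodies = dropped
        passed = RppaDataset(
            passed.meta.copy(),
            passed.values[averaged.antibody_names].copy(),
            scale="log2",
            antibodies=dict(averaged.antibodies),
        )
    completed, _flags = impute_time_course(averaged)
    return passed, completed, report
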