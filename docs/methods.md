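# Methods

`ctxcausal` implements an end-to-end analysis of interventional
reverse-phase protein array (RPPA) time courses: preprocessing and
quality control, identification of salient phosphoprotein changes under
kinase inhibition (causal descendancy matrices), joint learning of
context-specific networks with interventional dynamic Bayesian networks
(iDBNs), and empirical assessment of causal network learning against
held-out inhibitors.  A synthetic-data generator provides ground truth
for every stage.  This note records the models, the tunable parameters,
and the design choices made where the procedure was genuinely open.

## Data model

A study measures abundances for a panel of (phospho)protein antibodies
across samples indexed by *cell line*, *stimulus*, *inhibitor regime*,
*time* (minutes; the analysis grid is 0, 5, 15, 30, 60, 120, 240),
*replicate*, and *batch*.  A **context** is a (cell line, stimulus)
pair; inhibitors are interventions applied within a context.  The
canonical on-disk layout is a long CSV (one row per sample × antibody);
time is stored in minutes; antibody names map to network node names as
`PROTEIN_pSITE` (e.g. `AKT_pS473`).

## Preprocessing

Order of operations: log2 transform → per-batch loading normalization →
two-batch normalization (for a cell line whose samples span two
batches) → sample QC/exclusion → replicate averaging → correlated-panel
reduction → time-course imputation.

**Loading normalization** centers each antibody at its cross-sample
median, takes the per-sample median across antibodies as a correction
factor (CF), and subtracts the CF from the original log2 values.  The
CF is the loading offset; on a large, mostly stable antibody panel it is
insensitive to real signal.  On small simulated panels (10 antibodies,
most of which carry signal) the CF confounds with biology, so the
synthetic network-learning studies in `benchmarks` consume
replicate-averaged data directly and the normalization is exercised on
datasets with planted loading and batch artifacts.

**Batch normalization** maps batch 2 onto batch 1 per antibody via the
DMSO controls: with (μ₁, σ₁) and (μ₂, σ₂) the DMSO mean/SD of the two
batches (t = 0 replicates averaged before the calculation), every
individual batch-2 value x becomes μ₁ + σ₁(x − μ₂)/σ₂.  Antibodies with
σ₂ = 0 are centered only, with a warning.

**QC rules.**  Samples with linear-scale CF > 2.5 or < 0.25 (strict
inequalities) or log2 variance across antibodies > 40 are excluded,
each with a single primary reason code.  The CF bounds are interpreted
on the linear scale (2.5 and 0.25 are near-reciprocal multiplicative
bounds; log2 CFs straddle 0 and could not reach 2.5 for sane data).
Signal-to-noise ratios (mean/SD of the t = 0 replicates, computed on
linear-scale abundances) below 1 flag replicate *groups* for review but
do not auto-exclude; both scale choices are configurable.

**Panel reduction** keeps phospho antibodies observed in every cell
line and collapses same-target antibody pairs whose Pearson r exceeds
0.9 in *every* cell line, dropping the lexicographically later one
(priority order configurable).

**Imputation** is linear interpolation in real time (minutes), with
nearest-value fill at the boundaries; series with fewer than two
observed points are left incomplete with a warning.

## Salient changes and causal descendancy matrices

For each (phosphoprotein, context, regime), a paired t test compares
the replicate-averaged DMSO and inhibitor series over the 7 analysis
time points (t = mean(d)/(SD(d)/√n), d = DMSO − inhibitor, two-sided,
n−1 df).  If the DMSO series is peak-shaped — maximum at an interior
time point exceeding both endpoints by more than `k_peak` (default 1.0)
× the replicate SD — the test is repeated on the peak window (the
maximal contiguous run of interior points above the half height
(max + min(first, last))/2, minimum width 2) and the smaller p-value is
retained.  The peak heuristic's constants are surrogates (the published
rule is deferred to supplementary material) and are all configurable.

P-values are corrected per (context, regime) across the phosphoprotein
panel with the two-stage adaptive linear step-up FDR procedure: stage 1
is the linear step-up at q′ = q/(1+q); with r₁ rejections the null
count is estimated as m̂₀ = m − r₁ and stage 2 reruns the step-up at
q′·m/m̂₀ (r₁ = 0 rejects none, r₁ = m all).  Plain one-stage
Benjamini–Hochberg is available behind a flag.

A change is **salient** iff the FDR value is below q = 0.05 *and* the
absolute effect (mean log2 DMSO/inhibitor ratio over the tested window)
is at least τ (default 1.0) times the averaged pooled replicate SD —
the df-weighted pooled SD of the two arms' replicates per time point,
averaged over time points with any replication; when the peak retest is
retained, both the effect and the SD are recomputed over the same
window so the two salience conditions stay aligned.  Sign convention:
positive effect (DMSO > inhibitor) is a decrease under inhibition,
entered as −1 in the causal descendancy matrix (CDM); +1 is an
increase; cells without calls stay missing, not 0.

**Context differences** count, per regime and unordered context pair,
the phosphoproteins salient in exactly one of the two contexts
(presence/absence, sign ignored; proteins missing in either context are
skipped), summarized as a grand mean, a mean over same-stimulus
(cell-line) pairs, and a mean over same-cell-line (stimulus) pairs.

## Network learning

Each context's replicate-averaged, imputed series are stacked into
lag-1 transitions per regime (6 per regime time course; no row spans a
regime boundary).  For a child node, candidate parent sets up to
`d_max` (default 3) are scored in closed form under a Gaussian linear
model with intercept and the child's own lag always included:
a Zellner g-prior on the slopes with the unit-information choice g = n,
flat priors on intercept and noise variance, giving

log ML = lgamma((n−1)/2) − ((n−1)/2)·log π − ½·log n − ((n−1)/2)·log TSS
       + ((n−1−k)/2)·log(1+g) − ((n−1)/2)·log(1 + g(1−R²)),

where k is the effective (rank-based) number of centered non-intercept
columns, so collinear or duplicated parents do not change the score.
BIC scoring is available as an alternative.  Self-edges are never
reported.  The DBN is discrete-step over the 7 observation indices; the
uneven real spacing is ignored.

**Interventions.**  Default `fix_baseline`: for transitions from a
regime inhibiting node j, j's predictor values are pinned to the
context's DMSO t = 0 value (activity blocked from before stimulus);
the node's own response rows are retained.  Alternative `drop_edges`:
rows from regimes inhibiting any member of the scored parent set are
excluded from that set's regression.  Regimes targeting nodes absent
from the panel contribute data without masking, with a warning (as for
an FGFR inhibitor when FGFR carries no antibody).

**Joint coupling and prior.**  Parent-set posteriors are
∝ exp(log ML − η_n·|S Δ prior parents| − λ_n·Σ_{c′≠c} E[edge
disagreement with c′]), with the expectation under the other contexts'
current edge marginals; η_n = η·κ_η (0 when no prior network is given)
and λ_n = λ/(C−1)·κ_λ, so the coupling pressure is scale-free in the
number of contexts C.  The study values λ = 3 and η = 15 are the
defaults; the κ scale constants (default 1) absorb differences against
other parametrizations.  The coupled posterior is solved by cyclic
mean-field iteration (contexts, then children, in declared order),
initialized from the η-only posteriors, until the largest edge-marginal
change falls below `tol` = 1e-4 (max 100 sweeps; non-convergence
returns the last iterate with a warning).  With λ = 0 and a single
context this reduces exactly to independent Bayesian model averaging.
Cell-line summary networks average edge probabilities over the eight
stimulus networks and list edges strictly above 0.2, flagged for prior
membership.

## Assessment

A train/test split holds out one inhibitor regime; it is valid iff the
test regime's annotated targets are all network nodes and at least one
non-control regime with disjoint targets remains (training is always
maximal and keeps the control).  With the study's regime panel this
yields exactly three valid splits — the FGFR inhibitor fails the
node-presence rule and the dual PI3K/mTOR inhibitor's PI3K target has
no panel node.

Gold-standard descendant sets are the nonzero CDM entries of the test
regime per context.  Predicted descendants at a threshold are the nodes
reachable from the test targets through edges with probability ≥ the
threshold (≥ 1 edge; targets count only if reachable, e.g. on a cycle).
Sweeping the threshold over the unique edge probabilities traces an ROC
curve (TPR/FPR against the gold set; anchored at (0,0) and (1,1), FPR
ties resolved by maximal TPR, monotonized) whose trapezoid area is the
AUROC.  Internally, per-threshold reachability is computed via
widest-path (maximin edge probability) capacities from the target set —
a node is a descendant at threshold t iff its capacity is ≥ t — which
is mathematically identical to per-threshold graph search and makes the
1,000-draw empirical null cheap.  The ROC universe excludes the test
regime's own targets by default (a target trivially changes under its
own inhibitor); a switch restores them.

Significance uses an empirical null — AUROCs of matrices of independent
U(0,1) edge probabilities over the same node set — with the add-one
estimator p = (1 + #{null ≥ observed})/(1 + n_null), n_null = 1000 by
default (the published count is unstated).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the biochemistry:

- **Networks.**  A base directed network at configurable density with
  random-sign weights (magnitudes 0.4–0.8 by default), independently
  rewired per context (delete a fraction of base edges, add the same
  number outside the base set), each context matrix rescaled to
  spectral radius ≤ 0.9 and self-persistence 0.3.  Two topologies:
  `random` (uniform ordered pairs) and `layered` (nodes in ranks,
  edges strictly downward — a signaling-cascade shape whose descendant
  cones stay moderate instead of percolating).  The base network also
  serves as the "canonical" prior for learning experiments, exactly as
  a curated pathway prior relates to context-specific truths.
- **Dynamics.**  Lag-1 linear-Gaussian recursion
  x(t+1) = b + W_eff(x(t) − b) + k + u(t+1) + process noise over the 7
  observation indices, plus i.i.d. measurement noise per readout.
  Stimulus input u enters at per-context entry nodes (first-layer nodes
  under the layered topology) with a peak shape (difference of
  exponentials, 10-min rise / 60-min decay, unit maximum) or a
  sustained step.
- **Interventions.**  An inhibitor blocks its target's *outgoing
  influence* (catalytic inhibition): the target's off-diagonal weight
  column is scaled by a blockade efficiency α (default 0, complete).
  Each node additionally carries a tonic (constitutive) activity τ;
  blocking node j removes (1−α)·W[:, j]·τ_j from its children's inputs
  (the constant k above), so descendants shift even at rest — the
  behaviour seen for mTOR-pathway readouts in serum-starved cells.
  Inhibited trajectories start at the inhibition-adjusted steady state
  (cells are pre-treated before stimulus).  Under the control regime
  k = 0 and the recursion is the plain lag-1 model.
- **Replication** follows the study design: 16 replicates at t = 0,
  2 replicates for DMSO at t > 0, singletons elsewhere; batch
  location/scale shifts and per-sample outlier multipliers can be
  injected to exercise the QC stages.
- **Defaults.**  Process and measurement noise 0.05 log2 units; the
  `strong_signal_model` preset (process 0.1, measurement 0.02, gains
  1.0–1.5) makes every effect channel at least five times the
  measurement noise.

What the generator does *not* emulate: mass-action kinetics,
saturation, single-cell heterogeneity, spatial effects, antibody
cross-reactivity, or inhibitor off-target activity.  Passing recovery
tests therefore show the pipeline is correct under its own modelling
assumptions, not that those assumptions hold for any particular real
dataset.

## Benchmark study designs

The `benchmarks` module fixes the evaluation conditions:

- Change-caller calibration and power use single-context panels of 35
  proteins with the study's replication; planted effects are 5× the
  replicate noise.
- Edge recovery runs at 10 nodes and 4 contexts (parent-set
  enumeration exact and fast), strong signal, with tonic activity
  disabled: recovery there should come from dynamics alone, which is
  also the condition under which the time-shuffled negative control is
  a clean null (tonic blockade creates regime-level mean shifts that
  survive time shuffling and would contaminate the "null").
- The held-out-inhibitor assessment runs at the study's panel scale —
  35 nodes, layered topology at density 0.05, inhibitors aimed at hub
  (highest out-degree) nodes as kinase inhibitors are, tonic activity
  on, learning with the canonical prior at η = 15 and λ = 3, parent
  sets to d_max = 2 for tractability.  These sizes keep gold-standard
  descendant sets at a realistic 3–20 of 34 and the whole study within
  a couple of minutes on one core.

## Limitations

- All quantitative guarantees are under the generator's linear-Gaussian
  assumptions; the published statistics from the deposited dataset are
  reproduction targets only where that dataset is locally available.
- The exact likelihood, intervention encoding, and joint-prior
  parametrization of the methods the study built on are not restated in
  its text; the g-prior score, the fix-baseline encoding, and the
  mean-field coupling here are this package's own fully specified
  choices, with κ constants to re-scale λ and η against other
  parametrizations.
- The peak heuristic and effect-size rule are declared surrogates for
  unpublished supplementary definitions; every constant is exposed.
- FDR values from the two-stage procedure are used as a ranking
  heuristic, as in the source analysis, and should not be interpreted
  as formal error rates.
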