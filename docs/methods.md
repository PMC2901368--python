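# Methods

This note documents the statistical models implemented in `probeanova`,
the conventions frozen where more than one reasonable choice existed, and
what the built-in simulator does and does not emulate.

## The nested factorial model

For one gene with L probes observed on N = n₁ + n₂ arrays split between
two treatment levels, the log2 probe intensity is modelled as

    Y_ijl = μ + T_i + S_j(i) + P_l + (TP)_il + (SP)_jl(i)

- `T_i` — fixed treatment effect (g = 2 levels),
- `S_j(i)` — random subject/array effect, nested within treatment,
  variance σ²_S,
- `P_l` — probe (affinity) effect,
- `(TP)_il` — treatment × probe interaction,
- `(SP)_jl(i)` — subject × probe stratum, used as the error term,
  variance σ².

Because arrays are nested in treatment and probes cross both, the correct
error stratum for the treatment test is subject-within-treatment, not the
residual:

    F = MS(treatment) / MS(subject within treatment)

with df (g − 1, Σnᵢ − g). The strata degrees of freedom are: treatment
g − 1; subject-within-treatment Σ(nᵢ − 1); probe L − 1; treatment × probe
(g − 1)(L − 1); residual (L − 1)·Σ(nᵢ − 1).

**Engines.** For a complete probe × array block the layout is balanced and
the expected-mean-square closed form is exact; it is the default engine
and involves no iteration, hence no convergence concerns. The `reml`
engine fits the same mixed model by numerically maximizing the restricted
likelihood over (σ²_S, σ²) and forms the treatment F as the squared Wald
statistic of the probe-averaged treatment contrast; it exists for blocks
with missing cells. Intensities are rounded half-to-even to 5 decimals
before iterative fitting (`stabilize_rounding`): trivial rounding of
log-scale data removes occasional non-convergence of iterative REML while
changing the closed-form F by well under 1e-3. The closed-form/REML
equivalence holds when the REML optimum is interior (the ANOVA estimate of
σ²_S is positive); when MS(subject) < MS(residual) the REML fit truncates
at the boundary and the two legitimately differ — the test suite's
equivalence checks therefore use generative settings with a clearly
positive subject variance.

**Degenerate genes.** MS(subject) = 0 with MS(treatment) = 0 gives F = 0;
MS(subject) = 0 with MS(treatment) > 0 gives a +∞ sentinel that ranks
above every finite statistic. Both are flagged `degenerate`. This keeps a
total order over genes, which permutation ranking requires. Zero-ness is
judged against a relative tolerance (1e-12 × squared data range) so pure
location shifts of constant data remain degenerate. Single-probe
probesets collapse to the one-way ANOVA F on that probe with the same
(g − 1, Σnᵢ − g) df; they are annotated (`single_probe`) but not
degenerate. Negative variance-component estimates are clipped to 0 for
reporting; the F itself always uses raw mean squares.

## Theoretical-F diagnostic

Under the null with Gaussian components the F statistic follows
F(g − 1, Σnᵢ − g) exactly (verified by simulation in the test suite
against the alternative residual-df candidate, which is firmly rejected).
`f_quantile_diagnostic` pairs empirical quantiles at probabilities
(i − 0.5)/n with theoretical F quantiles; near-identity supports using
the theoretical reference, systematic curvature (as real arrays often
show) motivates the permutation null below.

## Pooled permutation inference

All `C(N, n₁)` treatment labelings with group sizes fixed are enumerated;
for equal group sizes a sign-free statistic is invariant to swapping the
level names, so by default one representative per swap pair is kept (the
member assigning the first array its original label), halving K. The
identity labeling is always included and listed first.

The null distribution is the flat pool of all G × K statistics. Per gene,

    p = #{pool ≥ observed} / (G·K)

with ties counting as extreme (exceedance is ≥, statistics compared
exactly as computed, no tolerance). Because the observed statistic is in
the pool, p ≥ 1/(G·K) > 0. Degenerate +∞ sentinels participate in the
pool and in exceedance counting, so results are reproducible and
conservative for the affected genes. Enumeration is exhaustive by design;
a cap (10,000 labelings) errors out rather than silently subsampling —
the intended designs (≤ 5 vs 5 or so) sit far below it.

A per-gene permutation utility (`per_gene_pvalues`) is provided only to
demonstrate the floor p ≥ 1/K that makes the per-gene approach useless at
these sample sizes.

**q-values.** `storey_qvalues` computes
q_i = π̂₀ · min_{p_(j) ≥ p_i} (p_(j)·m/j). With `pi0_mode="fixed_one"`
this is exactly Benjamini–Hochberg (cross-checked against statsmodels).
The default estimates π₀ from the λ-grid 0.05…0.95:
π₀(λ) = #{p > λ}/(m(1 − λ)), smoothed by a least-squares cubic polynomial
in λ and evaluated at λ = 0.95, clipped to (1/m, 1]. The reference
implementation of this estimator smooths with a df-3 smoothing spline; the
global cubic is the closest closed-form analogue available here and agrees
in the regimes that matter (π₀ near 1 under sparse signal). Estimated
π₀ ≤ 1 means the default is never more conservative than BH.

## Comparator statistics

All comparators expose the same interface (larger |statistic| = more
evidence) and plug into the pooled permutation machinery via
`block_statistic`.

- **FC** — log2 fold change c'·ŷ with c = (+1/n₁ … , −1/n₂ …); reported
  as control minus treatment (a `direction` flag flips it; ranking uses
  |FC| so the convention never affects ROC results).
- **RMANOVA1/2** — treating each array's probe vector as an observation,
  robust level centres μ̂₍ᵢ₎ and overall centre μ̂ are component-wise
  medians; W = Σᵢ Σⱼ (y − μ̂₍ᵢ₎)(y − μ̂₍ᵢ₎)′ and
  B = Σᵢ nᵢ(μ̂₍ᵢ₎ − μ̂)(μ̂₍ᵢ₎ − μ̂)′ are the within/between error
  matrices; the statistics are tr(B)/tr(W) and the component-wise median
  of diag(B)/diag(W). Both are scale-free ratios of between- to
  within-treatment error in the spirit of a one-way F on the whole probe
  vector. Zero within-spread uses the same 0/+∞ sentinel convention as
  the F. Singleton levels (nᵢ = 1) are allowed — the median degenerates
  to the single observation — but flagged by the caller's design checks.
- **FIRSTP** — per probe, a one-way ANOVA p-value p_l for equal treatment
  means; probes constant on all arrays are reset to p_l = 1 (no
  evidence); zero residual variance with unequal means gives p_l = 0
  (maximal evidence — the natural extension of the constant-probe rule to
  the other degenerate case). The gene statistic is the median over
  probes of 1 − p_l, always in [0, 1].
- **Moderated t** — per gene, least squares with a treatment dummy gives
  β̂₁, unscaled variance v = 1/n₁ + 1/n₂, residual variance s² on
  d = N − 2 df. With a scaled-inverse-χ² prior (d₀, s₀²) on the
  variances, the posterior variance is
  s̃² = (d₀s₀² + d·s²)/(d₀ + d) and t̃ = β̂₁/√(v·s̃²) has d₀ + d df
  under the null. (d₀, s₀²) are estimated by the standard moment method
  on log s² (digamma/trigamma matching, Newton inverse trigamma);
  d₀ = ∞ (no excess dispersion) pins s̃² at the common variance, here
  the arithmetic mean of the s², and the null reference becomes normal.
  The estimator is cross-checked against the R reference implementation
  in the test suite, and fixed (d₀, s₀²) can be supplied for exact
  reproducibility — required when the statistic is used inside the
  permutation loop, where hyperparameters must not be re-estimated per
  labeling.

## Evaluation

`tpr_fpr_curve` implements the iterative-removal ROC: sort |statistics|
increasing, repeatedly drop the smallest (ties broken by stable input
order), and record (FPR, TPR) of each retained set, from all n genes down
to one, then append (0, 0) for the empty set — n + 1 points, starting at
(1, 1). AUC integrates the staircase path traced by the points sorted by
(FPR, TPR): vertical runs contribute zero width, horizontal runs their
rectangle. This makes perfect separation integrate to exactly 1 and, in
the absence of ties, reproduces the rank-based (Mann–Whitney) AUC to
1e-9 — the two invariants that pinned down the integration rule.
Averaging over sub-design comparisons is pointwise by removal-step index
(all subsets share the gene universe, so curves align); AUC is recomputed
on the averaged points. Per-fold-change ROC curves are obtained by
restricting the truth table to one fold-change level plus all non-spiked
genes. `method_rank_distances` compares methods by Manhattan distance
between their rank vectors over the union of top-n genes — a scale-free
summary of ranking agreement (the downstream clustering/biplot is out of
scope).

## Simulator

`simulate_probe_dataset` draws data from the generative form of the
nested factorial model: per gene, μ_g ~ U(4, 12) log2 units, probe count
uniform on 11–20, S ~ N(0, σ_S²) per array, P ~ N(0, σ_P²) per probe,
optional (TP) ~ N(0, σ_TP²), residual N(0, σ²). Spiked genes (a
configurable fraction) receive a treatment shift of ±δ/2 per level —
symmetric so both fold-change signs are exercised — or 0/+δ with
`all_up=True`, mimicking spike-in designs where everything is
up-regulated in one group. Defaults (3 vs 3 arrays, σ_S = 0.3,
σ_P = 1.0, σ_TP = 0, σ = 0.3, 10% spiked at δ = 1.5) represent a small
two-group GeneChip comparison: array-to-array and residual spreads of
~0.3 log2 units, probe affinities as the dominant nuisance at ~1 log2
unit, and a 2.8-fold spike a plausible mid-strength signal. All draws
come from one seeded PCG64 generator; identical configs reproduce
byte-identical TSV outputs. Statistical properties, not bit streams, are
the cross-language contract.

What the simulator does **not** emulate: sequence-dependent probe
affinity (and hence background-correction artifacts), mismatch probes,
spatial array defects, intensity-dependent variance, and correlated
probe overlap. Passing tests therefore show correctness of the
statistical machinery under the model's own assumptions, not robustness
to the full messiness of physical arrays.

## Preprocessing conventions

- **Quantile normalization**: columns are mapped rank-wise onto the
  vector of per-rank means of the sorted columns; ties within a column
  receive the mean of the reference values at their tied ranks (this
  makes the map idempotent). Requires ≥ 2 arrays.
- **Probeset summarization** is the per-probeset mean of log2 probe
  intensities — an explicit, simple stand-in for model-based summaries,
  sufficient for the probeset-level statistics here and exact when probe
  effects average out.
- **Non-specific filter**: keep probesets with expression above a floor
  (default 20) on at least `min_arrays` arrays (default 2). The floor is
  compared on the anti-log scale by default, since log2 summaries rarely
  exceed ~14 and a threshold of 20 is only meaningful on the natural
  intensity scale; a flag switches to the log2 scale.
- **TSV dialect**: tab-separated, UTF-8, header required, `.` decimal,
  no quoting; writers emit 10 significant digits, making read/write
  round-trips bit-identical.
- Indexing is 0-based internally; user-facing identifiers are always
  strings.

## Problem sizes

The test suite and the acceptance script run simulations at 300–2,000
genes with 3–6 probes (unit tests) or the realistic 11–20 probes
(headline checks). These sizes give stable Monte-Carlo behaviour for the
calibration and recovery checks (binomial standard error ≤ 0.01 on the
0.05-level exceedance fractions at G = 500) while keeping each run in
seconds; the statistics themselves are size-independent.

## Known limitations

- The closed-form engine requires complete probe × array blocks; the
  REML fallback is slower and, at variance boundaries, intentionally
  disagrees with the mean-square ratio (see above).
- The pooled null assumes genes are exchangeable under the null; strong
  inter-gene correlation or gene-specific null distributions would bias
  pooled p-values — a known trade-off of cross-gene pooling.
- π₀ estimation is unstable for very small m; use `fixed_one` (BH) when
  testing few genes.
- Only two-level designs are supported; multi-level inputs are rejected
  at validation.
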