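# Methods

This note documents the statistical models implemented in
`thermoshift`, the assumptions of the synthetic-data generator, the
numerical choices, and what the test suite does and does not establish
about real data.

## Melting model and the pooled-window statistic

Each protein's soluble fraction is a three-parameter logistic in
temperature,

    f(T) = π + (1 − π) / (1 + exp(k (T − Tm))),

with melting point `Tm` (°C), slope `k` (1/°C, positive) and
non-denaturable plateau `π ∈ [0, 1)`. The form is the simplest
monotone-decreasing sigmoid whose midpoint parameter is directly the
melting point of the denaturable fraction; a reciprocal-Kelvin variant
(logistic in 1/T) is a documented alternative that we do not implement,
since over a 5–15 °C span the two are nearly indistinguishable and the
Celsius form keeps `Tm` interpretable.

A pooled-window experiment combines equal aliquots of the soluble
fraction from each window temperature, so the measured quantity is
proportional to the **arithmetic mean** of `f` over the window (a sum
would differ only by the constant window size, which cancels in log
ratios; the mean stays on the fraction scale). The pooled log2 ratio

    Δ = log2( mean_T f(T; Tm + ΔTm) / mean_T f(T; Tm) )

is strictly increasing in ΔTm whenever the window overlaps the melting
transition, which is what makes the single pooled number a usable proxy
for stabilization. The response is strongest when `Tm` sits at or below
the window centre and fades as `Tm` moves above the window — an
intrinsic sensitivity limitation quantified below.

## Synthetic-data generator

The generator emulates the statistical structure of a two-arm screen:

* `Tm ~ Normal(52.5, 2.0)` truncated to [40, 70] °C, so the 51–56 °C
  assay window straddles the typical melting point;
* `k ~ LogNormal(median 1.0, σ = 0.25)` capped to [0.1, 5]: a median
  10–90 % transition width of ~4.4 °C, on the steep side of typical
  cellular melting curves (wider transitions are common in meltome
  data; steeper ones are rare), so the defaults are mildly optimistic
  about detectability;
* plateau uniform on [0, 0.2]; base abundance `10^Normal(6, 1)`,
  spanning several orders of magnitude like a deep proteome;
* a fraction of proteins (default 5 %) receives
  `ΔTm ~ Normal(+1.5, 0.5)` °C ("substrates"); an optional disjoint
  fraction receives a log2 abundance effect, which multiplies **both**
  channels — this is precisely the confound the abundance arm is
  designed to remove;
* every measurement is multiplied by log-normal noise with unit mean
  and a stated coefficient of variation (default CV 8 % for the screen,
  5 % for spike-in gradients), because reporter-ion intensity noise is
  scale-dependent;
* replicate design 3-vs-3 by default, with the unbalanced 3-vs-2
  abundance arm supported.

What the generator does **not** model: peptide-to-protein roll-up,
missing values (all matrices are complete; the analysis side enforces a
complete-case contract), TMT channel interference, co-isolation, or
correlated noise between proteins. Passing recovery tests therefore
demonstrates the correctness and calibration of the statistics under
the stated noise model, not robustness to every artifact of real MS
data.

The spike-in gradient simulator uses five temperatures
{49, 51, 53, 55, 57} °C and 2 replicates by default; the exact
temperature values of such assays vary by lab, so they are
configurable, and these defaults are placeholders on a sensible grid
around the transition.

## Differential stability testing

Normalization follows the global-loess convention for log2 intensity
matrices: each sample is median-centred to the grand median, then a
locally weighted regression (tricube lowess, span 0.4, 2 robustness
iterations) of the per-sample deviation against the row-mean intensity
is subtracted, and medians are re-centred. This removes
intensity-dependent bowing; on data that never had such artifacts it
can only blur signal slightly, so the simulation-facing tests of exact
generative identities bypass it.

The moderated two-group test shrinks per-protein variances toward a
prior estimated across the proteome. With residual degrees of freedom
`d_g = n_a + n_b − 2` and sample variance `s²_g`, the prior `(d₀, s₀²)`
solves the moment equations of `log s²` under a scaled-F sampling
model: `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)` has mean `log s₀²
+ ψ(d₀/2) − log(d₀/2)` and excess variance `ψ′(d₀/2)`, solved for `d₀`
by Newton inversion of the trigamma function. The posterior variance is
`s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g)` and the moderated t is referred
to Student t with `d₀ + d_g` degrees of freedom (normal when `d₀ = ∞`).
Two degenerate branches: sample variances below 10⁻¹² are clamped
before taking logs, and when every `s²_g` is exactly equal the spread
carries no information, so the prior is set to that common variance and
moderation reduces to the ordinary pooled t (the shrinkage fixed
point). The implementation is cross-checked against the reference
empirical-Bayes implementation in R (limma) in the test suite.

Regulation calls use the screen's operational rule — |log2 ratio| > 0.1
and raw p < 0.01 — with Benjamini–Hochberg adjusted values reported
alongside so the corresponding FDR can be audited; both conventions
(raw-p rule vs FDR ≤ 5 %) are emitted because published screens state
both without fixing their order. Joint classification labels a protein
`concordant_both` (expression-driven) when both channels are regulated
in the same direction with log2 ratios within 0.1 of each other,
`stability_only` / `abundance_only` when exactly one channel responds,
and `discordant` otherwise. Consensus across treatments is the
intersection of per-treatment calls ("in common"), with per-treatment
tables always written so unions can be formed downstream.

## Curve comparison (NPARC)

For a spiked protein measured in two conditions, the null model fits
one logistic to all points and the alternative one logistic per
condition; the statistic

    F = ((RSS₀ − RSS₁)/3) / (RSS₁/(n − 6))

is referred to F(3, n − 6). Theoretical degrees of freedom are used;
the empirical-df moderation of the original NPARC method is out of
scope and listed as a limitation — at the implemented scale
(≥ 10 observations per protein) simulations show type-I error within
[0.025, 0.075] at α = 0.05, slightly conservative.

One normalization choice matters for calibration: quantities are
normalized per **protein** (single reference = mean of all points at
the lowest temperature, both conditions pooled), not per condition.
Dividing each condition by its own noisy two-replicate reference
injects a random per-condition scale that the nested F-test reads as a
curve difference, tripling the nominal type-I error in simulation.
Consequently equal spike-in amounts per condition are assumed; genuine
loading imbalances should be corrected against the carrier proteome
before testing.

Curve fitting is bounded least squares (`Tm ∈ [35, 75]`,
`k ∈ (0, 5]`, `π ∈ [0, 0.5]`), multi-start over a 2 °C `Tm` grid with
the best three starts (by initial residual) polished by a trust-region
solver (gradient tolerance 10⁻⁸, ≤ 500 evaluations); ties break by
lower RSS then lower `Tm`. Polishing only the best starts is a runtime
choice — on this single-basin model it reproduces the full multi-start
optimum. If the alternative fit is numerically perfect (RSS ≤ 10⁻¹²)
the result carries a `perfect_fit` flag: p = 1 when the null is equally
perfect, else p = 0.

## Set statistics

Overlap tests use the upper-tail hypergeometric probability
`P(X ≥ k)`, computed through the log survival function so tails around
10⁻³³⁰ are reported exactly as log10 values; the representation factor
is `k·N/(K·n)`. The upper tail is the only direction meaningful for an
enrichment claim, and at these magnitudes two-siding is immaterial.

Subset-shift tests are the Mann–Whitney U (subset vs remaining
proteome; exact null when both groups ≤ 12 and tie-free, tie-corrected
normal approximation with continuity correction otherwise) and the
Wilcoxon signed-rank (paired columns, zero differences dropped).

Pre-ranked enrichment ranks proteins by decreasing score (ties broken
by identifier for determinism) and takes the signed extremum of a
running sum with hit increments ∝ |score|^w (w = 1 by default; w = 0
recovers the Kolmogorov–Smirnov running sum) and miss decrements
1/(N − K). The null resamples same-size member sets ("gene
permutation" — a pre-ranked input has no sample labels to permute). NES
divides the observed score by the mean |ES| of same-sign permutations;
the nominal p-value is the add-one-smoothed fraction of same-sign
permutation scores at least as extreme, which is null-uniform. External
GSEA tools normalize against unprinted permutation ensembles, so
numeric NES equality with any particular published heatmap is not
claimed — only null behaviour and ranking invariances.

## Methyl-site annotation and occupancy

An arginine site is `canonical_rg` when it is immediately followed by
glycine and sits in a chain of ≥ 2 RG/RGG units (greedy RGG spans,
inter-unit spacers ≤ 4 residues, all unit starts within 10 residues of
the site); `noncanonical_rg` when the RG is isolated; `non_rg`
otherwise. The literature does not fix the boundary between canonical
and non-canonical precisely, so `max_spacer`, `min_repeats` and
`window` are parameters, and the defaults are one reasonable reading of
the repeated-RG(G) definition. Only R-followed-by-G counts as an RG
context (glycine-preceding GR contexts do not); lysine sites get
`not_applicable`. Positions are 1-based throughout; flank windows
truncate at sequence ends.

Occupancy uses the counterpart-decrease estimator only:
`θ = 1 − (unmod_test/loading_test)/(unmod_ref/loading_ref)`, clamped to
[0, 1]. It is scale-invariant and unbiased under multiplicative noise
to first order; a response-factor-corrected mod/(mod+unmod) estimator
would need calibration standards and is out of scope.

## Problem sizes and known limitations

The simulation scales used throughout the tests and the acceptance
script — 2000 proteins with 100 substrates for the screen, 1000 null
and 200 shifted pairs for curve-comparison calibration, 100 assays for
occupancy — are the package's chosen desk-scale analogues of a full
screen (which quantifies ~8000 proteins); all statistics are
per-protein, so results transfer directly.

Known limitations:

* **Detection ceiling of the pooled window.** Under the default
  conditions (ΔTm = +1.5 ± 0.5 °C, CV 8 %, 3-vs-3), substrates whose
  `Tm` falls in the upper half of the 51–56 °C window produce pooled
  log2 shifts below ~0.3, within ~3 standard errors of the noise, and
  roughly a quarter to a third of substrates are missed; two-treatment
  consensus sensitivity plateaus near 0.7. This is a property of the
  assay geometry, not of the test: steeper melting curves or a larger
  ΔTm raise it quickly.
* The F-test uses theoretical degrees of freedom (no empirical-df
  moderation) and assumes homoscedastic residuals on the fraction
  scale; with multiplicative noise this is adequate at CV ≤ 10 % but
  untested beyond.
* Complete-case analysis only; matrices with missing values must be
  filtered (the pipeline drops and counts incomplete rows), and no
  imputation is offered.
* The loess normalization estimates its trend from the data and can
  absorb a small part of a genuine, widespread treatment effect
  (robust weighting limits but does not eliminate this).
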