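# Methods

## Dose–response model

Viability is modeled as a decreasing four-parameter logistic on the log₁₀
molar concentration axis:

    v(c) = bottom + (top − bottom) / (1 + 10^{h·(log₁₀c − m)})

with `top` the low-dose asymptote (≈100% for vehicle-normalized data),
`bottom` the high-dose asymptote, `m = logAC₅₀` the half-maximal
concentration, and `h > 0` the Hill slope. The parameterization fixes the
direction: this is an inhibition/cytotoxicity screen, and rising (stimulation)
curves are not modeled — the fitter rejects solutions with `bottom > top` and
falls back to the flat model.

**Fitting.** Because the model is linear in `(top, bottom)` given `(m, h)`,
the fit is initialized by an exhaustive grid: `m` over
`[log₁₀c_min − 1, log₁₀c_max + 1]` in steps of 0.05 log units and `h` over
{0.3, 0.4, …, 5.0}, solving the two asymptotes in closed form at each node
and keeping the admissible node with least squared error. The winning node
seeds a Levenberg–Marquardt polish of all four parameters (parameterized as
`(top, span, m, h)` with `span = top − bottom ≥ 0`; analytic Jacobian;
tolerances 10⁻¹²). Refined solutions are kept only when they stay in the
admissible region and do not increase the SSE, so the final fit is never
worse than the best grid node. For whole-screen fitting the grid pass is
vectorized over curves (float32 node sweep, float64 re-solve of the winning
node) and the polish runs as a batched LM over all candidate curves at once;
the batched and per-curve paths agree to ~10⁻⁷ log units.

**Admissibility and degeneracy guards.**

* `bottom ≥ −30%` viability. An unconstrained 4PL happily trades a shallow
  slope against a deeply negative asymptote on noisy or incomplete curves;
  a lower asymptote far below zero viability is physically meaningless, and
  the guard keeps the potency estimate identifiable.
* Refinement is only spent on curves whose grid fit already beats the flat
  model **and** shows a response span ≥ 10%; for near-flat noise fits,
  sub-grid precision is irrelevant.
* A fit is *converged* only when its SSE improves on the flat model (the
  mean response) by more than 1% of total variance. Unconverged curves keep
  the flat model, `r² = 0` for constant profiles, and an undefined logAC₅₀.
* All-equal or fewer than 5 finite points: fit error / flat model.

**Curve summaries.** MAXR is the *observed* viability at the top tested
concentration (replicate-averaged), not the fitted value. AUC is the
trapezoidal integral of observed activity (`100 − v`) over the log₁₀
concentration axis, unclipped, so growth stimulation contributes negative
area; for the default 11-point threefold series the axis spans
`10·log₁₀3 ≈ 4.771` decades and constant full activity integrates to 477.12
activity·log-units. logAC₅₀ is reported from converged fits only.

## Curve response classes

The CRC rubric grades completeness, efficacy, and fit quality. Thresholds
(all configurable in `CrcRubric`):

| parameter | default | meaning |
|---|---|---|
| activity floor | 30% | max activity any dose must reach; otherwise class 4 |
| high efficacy | 80% | separates near-complete (.1) from partial (.2) response |
| r² cutoff | 0.9 | below it .1/.2 degrade to .3/.4 |
| bottom agreement | 10% | max gap between observed top-dose response and fitted lower asymptote for the plateau to count as reached |
| edge margin | 0.5 steps | how far inside the tested range logAC₅₀ must sit for a curve to count complete |

Decision order: floor not reached → 4; unconverged fit → 4 unless activity is
confined to the single top dose → −3; converged fits are *complete* (−1.x)
when logAC₅₀ is inside the range by the edge margin **and** the lower plateau
is reached, otherwise *incomplete* (−2.x), with −3 for single-top-dose
activity. The high-quality hit tier is exactly {−1.1, −1.2, −2.1, −2.2}.

## Differential pharmacology

* **Class calls.** Per MOA class, mean AUC per line and the percent ratio
  `100·mean_A/mean_B`, with both numerator and denominator floored at 1 AUC
  unit so classes inactive in one line cannot blow up the ratio. The z-score
  used for calling is computed on the **log₂ ratio** across classes: on the
  log scale swapping the two lines exactly negates every z-score, so the
  selective_a/selective_b calls are antisymmetric by construction (the raw
  percent ratio is reported alongside). Call threshold |z| ≥ 2.
* **Stringent potency hits**: high-quality CRC in line A and
  `logAC₅₀(A) − logAC₅₀(B) < −1` (≥10-fold more potent in A). Compounds with
  no finite potency in line B are right-censored at the top tested
  concentration, which conservatively counts them as "no more potent than the
  highest dose".
* **Shared hits**: MAXR < 30% in both lines (≥70% kill at top dose).
* **Enrichment**: per target, the 2×2 table of hit-set membership against
  the full annotated library (background includes the hit set), two-tailed
  Fisher's exact test, Benjamini–Hochberg q-values; flags at q < 0.01 and,
  separately, at raw p < 0.01. Multi-target compounds count once per
  annotated target.
* **Overlay**: targets whose gene-level expression differs by more than the
  fold-change threshold (default 2×) between the contrasted lines, each
  paired with the median and IQR of Δ-logAC₅₀ and the median Δ-MAXR of its
  compounds (same censoring rule), plus the fold-change direction.

## Expression workflow

Per-sample brightness is removed by equalizing the mean log₂ signal of a
housekeeping probe set across samples; linear-scale input is log₂-transformed
first. Probe rows are median-centered for visualization/clustering, collapsed
to genes by the mean over probes, and samples are clustered with Ward linkage
on Euclidean distances (merge heights are non-decreasing; the tree is
exported as Newick). Differential expression contrasts one line's replicates
against all remaining samples pooled: gene-level `log₂FC = mean(line) −
mean(rest)`, a pooled-variance two-sample t-test, and BH q-values; a gene
passes at |log₂FC| ≥ 1, p < 0.05, q < 0.1. The pooled test is the default
because with triplicate arrays the small group's variance estimate is too
unstable for Welch's test (~2 degrees of freedom, which costs roughly 15% of
sensitivity at a 1.5-log₂ effect); `welch=True` switches to the
unequal-variance test.

## Synthetic-screen generator

The generator emulates the study design the pipeline targets:

* **Library**: 1912 compounds in 20 MOA classes named by their primary
  target; ~10% of compounds carry a second annotated target. 35% of
  compounds are active (a typical fraction for an oncology-focused library);
  activity is shared between lines.
* **Actives**: complete-curve draws — `top = 100`, `bottom ~ U[0, 60]`
  (efficacy 40–100%, so every active clears the CRC activity floor),
  `hill ~ U[0.8, 2.5]`, true logAC₅₀ uniform over the central 7 points of
  the 11-point series so curves are mostly complete. Planted selective
  classes receive an exact logAC₅₀ shift (default −1.5, i.e. ~30-fold more
  potent) in line A only. Inactives are flat at 100%; an optional
  "ambiguous" fraction is pushed to the range edge for CRC edge-case tests.
* **Wells**: additive Gaussian noise (default sd 5% viability) on the
  percent scale, mapped onto a luminescence-like signal around a 1000-unit
  control scale and floored at a small positive value; 32 vehicle wells per
  line with the same noise model.
* **Expression**: 6000 probes over ~5500 genes (10% of genes with two
  probes), 8 lines × 3 replicates, gene baselines N(8, 1.5) log₂ units,
  per-sample brightness offsets N(0, 0.5) removed by normalization,
  replicate noise sd 0.3, 20 zero-effect housekeeping probes, and 900 genes
  planted at ±1.5 log₂ in line 1 (named genes can be forced so planted DE
  coincides with drug targets).

What it does **not** emulate: plate-geometry artifacts (edge effects,
dispensing drift, pintool carryover), replicate screening, compound-specific
noise heteroscedasticity, correlated gene modules, or line-specific
expression baselines beyond the planted contrast. Passing the planted-
recovery tests therefore demonstrates that the analysis recovers the signals
it models, not robustness to those real-data artifacts.

## Benchmarks and problem sizes

The test suite and `scripts/acceptance.py` run the recovery benchmarks at
these sizes, chosen to exercise the full study design while staying
desk-scale:

* 4PL recovery: 200 seeded curves; noiseless max |logAC₅₀ error| ~10⁻¹⁵
  (tolerance 10⁻³); at 5% noise, RMSE is computed over fits classified as
  complete curves (−1.x), matching the definition of the potency readout as
  the AC₅₀ of a complete fit — incomplete fits at the range edge have no
  identifiable AC₅₀, and including them makes the metric a property of the
  tail rather than the fitter (~0.11 vs a heavy-tailed ~0.15).
* Planted differential recovery: 20 seeded full screens (both planted
  classes must be called and enriched at q < 0.01 in ≥95% of seeds) and 10
  null screens for the false-positive arm (mean flagged classes ≤ 1; the
  |z| ≥ 2 rule across 20 classes gives ~1 expected flag under the null).
* DE recovery: 10 seeded expression matrices, sensitivity ≥ 0.9 and
  empirical FDR ≤ 0.1 for the 900 planted genes at a 3-vs-21 contrast.

## Known limitations

* Activation (stimulation) curve classes are not assigned; stimulation only
  enters as negative AUC contributions.
* Incomplete-curve potencies are intrinsically unstable; downstream deltas
  treat missing potencies by right-censoring at the top concentration rather
  than modeling the censoring distribution.
* The class-level AUC ratio (not per-compound ΔAUC) is used for selectivity
  calls; with very small classes (a handful of compounds) the class mean is
  noisy and the z-rule loses power.
* Housekeeping normalization assumes the housekeeping set is genuinely
  unregulated between lines; a regulated housekeeping gene biases all genes
  of the affected sample.
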