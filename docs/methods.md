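# Methods

This note documents the models behind `contambench`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical choices that matter for reproducing its results.

## The simulated experiment

The simulator emulates a positive-control design for low-biomass
amplicon sequencing: a whole-cell mock community is serially diluted
before DNA extraction, so each dilution round divides the mock template
while the reagent contamination introduced during extraction/PCR stays
constant per reaction.

### Two-compartment template model

With mock template `M0·λ^(−d)` at round `d` (λ = `dilution_factor`) and
constant contaminant template `C`, the expected contaminant read
fraction is `f_d = C/(C + M0·λ^(−d))`. This is the minimal mixing model
consistent with a constant-background mechanism; it is a modeling choice,
not an estimated curve. Only the ratio `C/M0` matters for read
fractions. Defaults `M0 = 400`, `C = 1`, `λ = 3`, `n_dilutions = 8` give
f_d (in %) of 0.25, 0.74, 2.2, 6.3, 16.8, 37.8, 64.6, 84.5, 94.3 across
D0–D8: the contaminant share crosses 50% at the sixth round, the regime
a real mock dilution series of this design exhibits.

### Community profiles

* **Mock profile** — 8 species slots drawn from a symmetric
  Dirichlet(100) (near-even, as in a commercial standard; infinite
  concentration gives exactly even), with one slot split 0.75/0.25 into
  two sequence variants, for 9 expected ASVs total. The split emulates a
  species whose 16S amplicon denoises into two variants.
* **Contaminant profile** — `n_contaminant_asvs` (default 200; the
  `paper_scale` preset uses 937) relative abundances from a symmetric
  Dirichlet(0.25): a few dominant taxa over a long tail, as reagent
  contamination presents in practice. The default desk-scale pool keeps
  the test suite fast; the full-scale preset changes richness and read
  depths only.

### Sampling mechanism

Each dilution sample draws its configured read depth multinomially from
`(1−f_d)·mock ⊕ f_d·contam`; then every read is independently replaced
with probability ε (`crosstalk_rate`, default 5·10⁻⁴) by a read from a
sample-private cross-talk pool with a skewed (geometric) assignment over
pool members — producing the single-sample, low-count ASVs that barcode
mis-assignment creates. The final contaminant read count is therefore
exactly `Binomial(N, 1 − (1−f_d)(1−ε))`, which is what the fidelity
checks test against. Multinomial (not Dirichlet-multinomial) sampling is
the default because the methods under test are threshold-based and no
overdispersion estimate is available to calibrate against; an
overdispersed variant would only widen the binomial intervals.

The **negative control** draws its reads from the contaminant profile
restricted to a "shared" subset (default fraction 0.2 of the pool,
chosen uniformly), mixed with a small leak of mock reads
(`negative_control_mock_leak`, default 0.017, spread over 3 of the 9
mock ASVs) — emulating cross-contamination/cross-talk into the blank.
Because the shared subset is uniform rather than abundance-weighted, the
per-sample overlap between contaminants and the control runs lower than
in a real run where the blank preferentially captures the prevalent
reagent taxa; the negative-control filter's contaminant-removal
percentages are correspondingly conservative here. Its qualitative
behavior (discarding leaked mock ASVs, missing non-shared contaminants,
worst-in-class accuracy) is unaffected.

**DNA concentrations** emulate a spectrophotometer reading:
`max(floor, γ·(M0·λ^(−d) + C) + N(0, σ))` with gain γ = 0.05 (ng/µl per
template unit, D0 ≈ 20 ng/µl), noise σ = 0.02 and floor 0.02. The floor
is set below the most-diluted sample's expected reading so the
inverse-concentration signal the frequency classifier relies on is not
clipped; a real near-blank NanoDrop reading is noisier and bounded away
from zero, which would degrade that classifier more than simulated here.

**Read depths** default to a geometric decline 12,000 → 2,000 with ±15%
multiplicative jitter (real runs are non-monotone); depths are exact by
construction. Deterministic per-sample substreams are derived from the
single experiment seed by content-keyed hashing, so adding a sample or a
method never perturbs the other streams.

### What the simulator does not emulate

Nucleotide-level error (chimeras, miscalls), PCR amplification bias,
taxonomy, overdispersion between technical replicates, and
abundance-correlated control sharing (above). Passing tests therefore
show that the methods behave correctly under the idealized generative
model each method assumes — not that they will reach the same accuracy
on a real sequencing run.

## Removal methods

* **Negative-control filter** — an ASV with nonzero count in any listed
  control is removed from every non-control sample (binary,
  dataset-wide).
* **Abundance filter** — per sample, an ASV is removed iff
  `count/sample_total < threshold` (strictly below; per-sample, not
  dataset-wide). Thresholds are proportions in the library; the CLI
  accepts percent values and divides by 100 exactly once.
* **Frequency classifier** — per ASV, over non-control samples with
  nonzero frequency (no pseudocounts; minimum 3 points, otherwise the
  ASV is unscoreable and kept, flagged by a NaN score): residual sums of
  squares of the log-log fits with slope fixed at −1 (`SS₋₁`) and 0
  (`SS₀`), both with free intercept; score = `F.cdf(SS₋₁/SS₀; n−1, n−1)`.
  Degenerate cases: `SS₀ = 0` → score 1; both zero (all concentrations
  equal) → ratio 1 → score 0.5. The score is invariant under rescaling
  all concentrations (only intercepts shift). Removal at `score < P*`
  (strict) applies dataset-wide, matching how such classifiers are used;
  the filters stay per-sample where their definition is per-sample.
* **Source attribution** — collapsed Gibbs sampler defined in the module
  docstring; defaults α_known = 0.001, α_unknown = 0.1, β = 10,
  10 restarts, 100 burn-in sweeps, 10 retained draws spaced 10 sweeps,
  rarefaction off (subsampling before attribution is common practice but
  contested; it is exposed as `rarefaction_depth` and defaults to off).
  Source environments: a **mock source** (the undiluted sample
  restricted to expected ASVs), a **contaminant profile** (diluted
  samples pooled with expected ASVs zeroed), and the **negative
  control**; scenario 1 (environment defined) retains each ASV's
  attribution to the mock source, scenario 2 (environment undefined)
  retains the attribution to the unknown source; case 1 uses both
  contaminant sources, case 2 the negative control only. Proportional
  retained fractions feed diversity/recovery via the proportion-weighted
  corrected table (counts × fraction, rounded toward zero), and feed the
  confusion analysis through binarization at 0.5 — the symmetric choice,
  exposed as `call_threshold`.

The Gibbs inner loop is numba-compiled; restarts are seeded
`seed + restart`, and the package's tests verify the sampler against
exhaustive enumeration of all assignment vectors on small sinks (the
correctness checks run the sampler at higher effort — 100 restarts ×
100 draws — so Monte Carlo error sits well below the 0.02 agreement
tolerance; pipeline defaults are unchanged).

## Evaluation

Per sample, over ASVs present in that sample: tp = contaminant removed,
fn = contaminant kept, tn = mock kept, fp = mock removed; accuracy =
(tp+tn)/(tp+fn+tn+fp). A dataset-wide variant counts each ASV once,
calling it removed iff removed in every sample where present (methods
with dataset-wide calls are unaffected by the rule). Alpha diversity:
observed ASVs, Shannon (−Σp·ln p; natural log by default, the convention
of the standard analysis stacks, with an optional base-2 flag), inverse
Simpson (1/Σp²).
"Expected" diversity is the same metric on the sample restricted to
expected ASVs. Composition recovery compares corrected relative
abundances to the true mock profile:
`L1 = Σ_expected |obs − truth| + Σ_contaminant obs ∈ [0, 2]`.

## Problem sizes and numerical choices

The default experiment (200 contaminants, ~2–12k reads/sample) is sized
so the entire method grid, including four Gibbs configurations over nine
sink samples, runs in well under a minute; the `paper_scale` preset
(937 contaminants, 41k–251k reads/sample) is used where contaminant
richness itself is the quantity of interest. Simulator fidelity is
checked by pooling contaminant read counts over 20 seeded replicates per
dilution and requiring them to fall in the exact 99% binomial interval
of the analytic fraction (including the cross-talk term), plus perfect
rank correlation of the mean fraction with dilution round. All
tolerances used in tests are stated inline; diversity formulas are
checked to 1e-10 against direct evaluation and against scikit-bio.

## Known limitations

* The frequency classifier's score formula is one concrete instantiation
  of the inverse-concentration test (F-CDF of the residual-sum ratio
  with (n−1, n−1) df); other implementations differ in small-n behavior.
* Unscoreable ASVs (fewer than 3 occurrences) are kept; in heavily
  cross-talk-affected data this leaves singletons in place, which is
  visible as the frequency method's residual false negatives at high
  dilution.
* The Gibbs sampler reports posterior means only; no convergence
  diagnostics beyond restart agreement are computed.
* Sample identifiers, not sequences, are the matching key; real
  pipelines must first collapse to exact ASVs.
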