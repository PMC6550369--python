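# contambench

Benchmarking computational contaminant removal for low-microbial-biomass
16S rRNA gene sequencing, using a mock-community dilution series with
known ground truth.

## The problem

In low-biomass environments (urine, lower airway, upper atmosphere),
bacterial DNA from reagents and sample handling can dominate an amplicon
sequencing run: the less template a sample carries, the larger the share
of its reads that come from contamination. A serial dilution series of a
mock community — a standard of known composition — makes this failure
mode measurable: every amplicon sequence variant (ASV) that is not one of
the expected mock sequences is, by construction, a contaminant, so
contaminant-identification methods can be scored exactly.

`contambench` provides:

* a seeded **simulator** of such an experiment: a 9-ASV mock community
  (8 species, one split into two sequence variants) serially diluted
  3-fold for 8 rounds (1:3 … 1:6561) against a constant reagent
  contaminant background, plus a negative control and barcode cross-talk
  singletons, with full ground truth;
* four **removal methods**: negative-control filtering, per-sample
  relative-abundance filtering, a frequency-based classifier
  (Decontam-style inverse-concentration test), and Bayesian source
  attribution (SourceTracker-style collapsed Gibbs sampling);
* an **evaluation** layer: per-sample confusion counts and accuracy,
  percent contaminants, alpha diversity (observed ASVs, Shannon,
  inverse Simpson) with expected counterparts, and composition recovery
  (L1 error against the true mock profile).

## Models

**Dilution model.** With mock template `M0·λ^(−d)` at dilution round `d`
(dilution factor λ) and constant contaminant template `C`, the expected
contaminant read fraction is

```
f_d = C / (C + M0·λ^(−d))
```

— 0 with no contaminant, 1 with no mock template, strictly increasing in
`d`. Reads are multinomial from the mixture `(1−f_d)·mock ⊕ f_d·contam`,
with each read independently replaced by a sample-private cross-talk
singleton at rate ε.

**Frequency classifier.** For each ASV, over the non-control samples
where it occurs, regress `y = log10(frequency)` on
`x = log10(DNA concentration)` twice with free intercept: slope fixed at
−1 (contaminant model, frequency ∝ 1/concentration) and slope fixed at 0
(constant model). The score is `F.cdf(SS₋₁/SS₀; n−1, n−1)`: 0 for a
perfect contaminant fit, 1 for a perfect constant fit. ASVs with score
below a threshold `P*` are removed dataset-wide.

**Source attribution.** Each sink read with taxon `t` is assigned to a
source `v` by collapsed Gibbs sampling,

```
P(z_i = v | z_−i) ∝ P(t|v) · (n_v^(−i) + β)
```

where known sources emit with fixed Dirichlet-smoothed probabilities
`P(t|v) = (m_tv + α₁)/(m_v + α₁·τ)` and an "unknown" source is a
Dirichlet(α₂)-smoothed urn over its currently assigned reads. The
retained fraction of an ASV is its posterior attribution to the
experimental source (scenario 1, environment known) or to the unknown
source (scenario 2, environment unknown).

## Worked example

```
python analysis/01_simulate.py
python analysis/02_apply_methods.py
python analysis/03_evaluate.py
```

The first driver prints the per-sample overview of the default seeded
experiment:

```
    n_reads  n_unique_asvs  pct_contaminants  analytic_pct
D0    11283             39              0.35          0.25
D1     9994             46              0.76          0.74
D2     6646             62              2.11          2.20
D3     5673             88              6.58          6.32
D4     5090            108             16.09         16.84
D5     3550            124             39.30         37.79
D6     3564            132             65.60         64.57
D7     2226            129             83.74         84.54
D8     1804            128             94.18         94.25
NC     4000             32             98.12           NaN
```

Reads per sample fall with dilution while the contaminant read share
climbs from 0.35% (undiluted) past 50% at the sixth dilution to 94% —
the empirical percentages track the analytic `f_d` curve. The third
driver then ranks the methods in the contaminated samples (D4–D8):

```
mean accuracy in contaminated samples (D4-D8):
sourcetracker_s1_case2    1.000
sourcetracker_s1_case1    1.000
sourcetracker_s2_case1    0.992
abundance_0.01            0.861
frequency_0.5             0.847
...
negctrl                   0.189
abundance_0.0001          0.073
```

Source tracking with a well-defined experimental source is nearly
perfect; the frequency classifier at `P* = 0.5` removes the large
majority of contaminant ASVs without ever discarding a mock ASV; the
negative-control filter performs worst — it throws away the expected
ASVs that leak into the blank while missing every contaminant the blank
does not contain. The same ordering holds for composition recovery (mean
L1 error 0.05 for scenario-1 source tracking vs 1.04 for the
negative-control filter).

Everything is also available as one command (`contambench run-all`) or
through the library API; `contambench simulate/apply/evaluate` expose the
individual stages on TSV files.

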