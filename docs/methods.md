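# Methods

## The inference model

The unit of observation is a diploid interphase nucleus co-hybridized with
an autosomal control probe and a test probe, scored for the number of
discrete nascent-transcript signals at each (0–4; values above 2 in a
diploid nucleus are anomalies).

**Diploid-control filter.** Only nuclei showing exactly two control signals
are scored for the test probe. This controls simultaneously for ploidy
(tetraploid cells show four control signals when control detection is good)
and for probe accessibility into the individual nucleus. Nuclei with one
control signal but informative test counts are excluded — the filter is on
the control count alone, with no rescue rule.

**Efficiency.** Hybridization efficiency p is probe-specific and estimated
from the heterogametic sex, where a sex-specific locus has exactly one
transcribing allele: p̂ = n₁/(n₁+n₀). Heterogametic nuclei with two signals
at a single-copy locus (which should not occur) are excluded from the
estimate and flagged with a warning. A pooled estimate across probes is
available (`pooled_efficiency`) but is not the default; the pipeline uses it
only for pseudoautosomal loci, which carry two alleles in both sexes and so
give no direct single-copy readout.

**Null and 2-df test.** Under biallelic transcription, signal counts follow
(p², 2pq, q²). The raw test is Pearson χ² with 2 df over the three
categories. When p is high the expected zero-signal count can fall below 1;
the test still runs (all three categories retained) but emits
`SmallExpectedCountWarning`, and the error-adjusted 1-df test below is the
primary inference in that regime. An expected count of exactly zero with a
nonzero observation is reported as an infinite statistic with p = 0.

**Error bound and adjusted 1-df test.** Autosomal loci are obligately
biallelic, so missed signals in autosomal control experiments measure
experimental error: missed = Σ(2·n₀ + n₁) over control summaries, out of
2·Σn expected signals. The exact Garwood interval for a Poisson count k is
[½χ²_{α/2}(2k), ½χ²_{1−α/2}(2k+2)] (lower limit 0 at k = 0); the upper 95%
limit divided by expected signals is the maximum error rate. For the
adjusted test the zero-signal class is removed, the (2-signal, 1-signal)
table renormalized, and the observed category fractions shifted toward the
renormalized expected fractions before a 1-df Pearson χ².

The phrase "adjusted toward the expected values by X%" admits two readings;
both are implemented behind `mode=`. The default, `"percentage_point"`,
moves each category fraction X percentage points toward expectation,
clamped so it never overshoots (the adjustment can only ever weaken
evidence, not manufacture it). The alternative, `"proportional"`, moves a
fraction X of the gap. The percentage-point reading is the default because
it is consistent with the reference arithmetic this pipeline reproduces and
is the more conservative of the two at realistic gaps.

**Multiplicity and the call.** P-values are Bonferroni-corrected
(multiplied by the family size, capped at 1). The family defaults to the
number of locus tests in the run, configurable because a fixed convention
cannot cover every panel design. Significance is called at α = 0.01 after
correction. `robustness_sweep` re-runs the adjusted test over a grid of
error rates (e.g. up to an arbitrary conservative 5-point shift) to show a
call does not hinge on the estimated error bound.

**Silencing estimate.** With silencing probability s, the one-signal
fraction is 2pq + s·p(2p−1), so ŝ = (f₁_obs − 2pq)/(p(2p−1)), clamped to
[0, 1]. This requires p > 0.5 for identifiability, comfortably satisfied by
observed efficiencies (0.94–1.0).

**Coordination.** Among nuclei monoallelic at both loci of a closely linked
pair, co-located signals indicate same-chromosome origin; the co-location
fraction near 1 supports one active and one inactivatable homologue. The
expected joint-biallelic fraction under independent silencing is the product
of the marginal biallelic fractions measured in single-probe experiments
(not renormalized to expressing nuclei — the expectation is over all scored
diploid nuclei). A 1-df χ² against that expectation, Bonferroni-corrected
over the pairs tested, classifies each pair: coordinated escape requires a
significant *excess*; a significant deficit is classified independent but
flagged anti-coordinated.

**Association.** The percentage of 1-active nuclei (replicates averaged
unweighted per probe) is regressed by OLS on the homogametic:heterogametic
expression ratio; R² and the slope's t-test p-value are reported. Expression
ratios are caller-supplied; loci confounded by sex-determination roles are
removed via an exclusion list rather than hard-coded names. A constant
response is reported as R² = 0, p = 1.

## The simulator

`simulate_population` draws, per nucleus: ploidy (tetraploid with
probability `tetraploid_fraction`; tetraploid cells carry twice the diploid
allele count before detection), silencing states (per nucleus, not
heritable — daughter cells are independent, so no lineage structure exists),
and detection (each transcribing allele Bernoulli(p), control alleles
Bernoulli(`control_efficiency`)). Allele bookkeeping: autosomal loci two
transcribing alleles in both sexes; sex-specific loci one always-active
allele plus, in the homogametic sex only, one inactivatable allele silenced
with probability s; pseudoautosomal loci one always-active plus one
inactivatable allele in *both* sexes, sharing the same s. Pair coupling:
locus B copies locus A's silencing state with probability ρ, else draws
independently — analytically tractable and spanning exactly the independent
(ρ = 0) and fully coordinated (ρ = 1) regimes. In pair experiments, when
both loci show one signal, the signals co-locate with probability γ
(`colocation_fidelity`) if both derive from the same chromosome and never
if from opposite chromosomes.

Default study conditions: scoring depth 200 nuclei per sex (matching the
≥100-cell scoring convention, with headroom), silencing probabilities
spanning 0.15–0.51 for the 11-locus Z-like panel and 0.25–0.62 for the
19-locus X-specific panel, 0.16–0.47 for the 9 pseudoautosomal loci,
efficiencies 0.94–1.0, autosomal s = 0. Tetraploid fraction defaults to
0.05 — microscopy fields show occasional 4n nuclei but no measured
frequency exists, so a small realistic value was fixed once. Control
efficiency defaults (0.985 chicken-like, 0.975 platypus-like) are set so
that the fraction of control nuclei showing two signals matches the ≥97% /
≥95% biallelic-control observations.

What the simulator does *not* emulate: image-level noise (spot splitting,
focal-plane loss), clonal structure, cell-cycle effects on nascent
transcription, probe-specific background, or between-individual variation
beyond the replicate mechanism. Passing tests therefore validate the
statistical machinery under the stated generative assumptions, not the
upstream microscopy scoring.

## Numerical and design choices

- χ² p-values come from the upper tail of the χ² distribution; no Yates
  continuity correction anywhere.
- `test_coordination` accepts fractional observed counts so tallies
  back-computed from published percentages can be tested directly.
- The calibration properties (type-I error, power) are measured
  conditionally on the true efficiency. Plugging in an efficiency estimated
  from a small heterogametic sample inflates the type-I error of the 2-df
  test noticeably (the test treats p̂ as known); this is a limitation of
  the method itself, mitigated in practice by the error-adjusted 1-df test
  and large heterogametic samples. The power at the weakest study condition
  (s = 0.15, n = 200, p = 0.95) remains above 0.9 with efficiency estimated
  from 200 heterogametic nuclei.
- Monte-Carlo problem sizes (500 replicates for calibration, 20–50 for
  recovery, n = 10,000 for convergence checks) were chosen so binomial
  noise is several times smaller than the margins being verified.
- Exact Poisson limits use `scipy.stats.chi2.ppf`; they reproduce the
  reference values (28.58, 54.47 for k = 40; 87.32 for k = 69) to the
  printed precision.
- Randomness: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; identical config and seed give bit-identical
  output.

## Known limitations

- Efficiency uncertainty is not propagated into the χ² tests (see above).
- The silencing estimator uses only the one-signal fraction; a full
  maximum-likelihood fit over all three categories would be marginally more
  efficient but the moment estimator's bias is ≪0.01 at study scales.
- Published per-locus percentage tables cannot be reproduced because the
  underlying per-nucleus data were never deposited; the package instead
  validates against the published summary arithmetic and simulator ground
  truth. Printed p-values for the two matched chicken pair tables are not
  targeted: a plain 1-df Pearson χ² on those tables gives p ≈ 0.98, and the
  derivation of the printed values is ambiguous. Only the significance
  pattern is reproduced.
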