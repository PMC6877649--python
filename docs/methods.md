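# Methods

## Skew quantification

Input is a phased VCF (biallelic heterozygous SNVs; unphased records are
dropped, not heuristically phased, since phasing is assumed to happen
upstream) and per-sample allelic read-count tables in the
GATK-ASEReadCounter column convention. Coordinates are 1-based inclusive
throughout; the *XIST* and pseudo-autosomal intervals are configuration
values with GRCh37 defaults (X:73,040,486–73,072,588; PAR1
X:60,001–2,699,520; PAR2 X:154,931,044–155,260,560), not hard-coded
constants.

Site filters: total allelic depth ≥ 10 and each allele observed at least
once in the RNA (the second filter guards against miscalled heterozygous
genotypes that would otherwise appear fully skewed). Depth is always
recomputed as `refCount + altCount`; rows whose printed total disagrees are
logged. A sample with no informative *XIST* SNV gets no skew call.

Per-site ASE is the reference-allele fraction re-oriented to haplotype 1.
`XIST_ASE` is the **unweighted** arithmetic mean of these phased fractions
across the sample's *XIST* SNVs. Averaging must happen after phase
alignment: raw reference fractions at SNVs with opposite phase would cancel
the signal. A depth-weighted mean is available behind a flag (off by
default) for sensitivity analyses. `DS = |0.5 − XIST_ASE|`; the
classification boundary DS = 0.3 is inclusive (a sample exactly at an 80:20
mosaic is skewed).

The alternative non-PAR estimator averages the phased fractions of all
non-PAR sites outside *XIST* (default minimum 5 informative sites), after
excluding sites in a configurable escape-gene list. Genes subject to XCI
are expressed from the active X, so this estimator's expectation under full
silencing is `1 − p` where `XIST_ASE` targets `p`; its deviation
`|0.5 − value|` is the quantity comparable to DS. Published accounts of
this class of estimator do not fully specify aggregation or escape
handling; the phase-aligned mean used here is one defensible choice and is
not claimed to match any particular external implementation.

## Synthetic cohort generator

The generator emulates a multi-tissue female twin cohort so every pipeline
stage can be validated against known ground truth. Per individual i and
tissue t the latent skew fraction is `p_it = logistic(z_it)` with

```
z_it = latent_sd · scale_t · ( √a2 · A_i + √c2 · C_f + √e2 · E_it )
```

A is shared exactly within MZ pairs and with correlation 0.5 within DZ
pairs; C is shared within families; tissue E-draws correlate with the
reference tissue at a per-tissue level `e_corr`, so the latent inter-tissue
correlation is `a2 + c2 + e_corr·e2`. Modelling the ACE structure on the
logit scale keeps p inside (0,1) while giving the twin model an exactly
multivariate-normal trait for recovery tests; the analysis pipeline fits
DS, which is a bounded, folded transform of z, and model-recovery tests are
run on both scales (DS-scale estimates are attenuated relative to the
latent truth — a real limitation of fitting ACE to a bounded trait, flagged
rather than hidden).

Blood-like tissues additionally receive an age drift: `|z|` grows by
`age_drift` per year above `age_threshold`, applied in the direction of the
existing skew (acquired skew amplifies whichever parental X already
dominates). Optional smoking and disease effects enter the same way and
default to zero so null calibrations are exact. An optional second variance
triple (`variance_components_older`) replaces the shares in blood-like
tissues at or above the age threshold, producing age-gated genetics.

Reads: per-site depth is negative binomial (gamma–Poisson; `dispersion = 0`
gives constant depth), and allelic counts are beta-binomial with intraclass
correlation `rho` around the expected haplotype-1 fraction — `p` inside
*XIST* (expressed from the inactive X), `((1−p) + p·e)/(1+e)` for a non-PAR
site with escape level e, and 0.5 in the PARs. `rho = 0` reduces exactly to
binomial sampling. Escape levels are zero-inflated Beta per site (default
75% fully silenced, Beta(1,4) otherwise). Counts are independent across
sites, consistent with short reads never spanning two SNVs. All randomness
flows from one `numpy` Generator seeded by a single integer; cohort outputs
are byte-identical across runs at a fixed seed.

### Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| cohort | 61 MZ + 63 DZ pairs + 174 singletons | ~420 informative individuals and realistic pair counts for a blood-tissue twin panel |
| ages | uniform 38–85 y | the age span of large adult twin registries |
| `latent_sd` | 1.3 | gives ~28% skew prevalence and mean DS ≈ 0.2 below the age threshold in blood-like tissue |
| `variance_components` | (0, 0.01, 0.99) | essentially pure unique environment below the threshold |
| `variance_components_older` | (0.34, 0, 0.66) | moderate additive genetics in blood-like tissue above the threshold |
| `age_threshold` | 55 y | onset of age-acquired skew in blood |
| `age_drift` | 0.025 /y | raises blood skew prevalence to ~38% and mean DS to ~0.24 in the older group |
| tissue `e_corr` | whole_blood 0.8, fat 0.42, skin 0.3 | strong concordance among blood-derived tissues, weak with primary tissues |
| tissue `latent_scale` | fat 0.69, skin 0.76 | primary tissues show ~12–16% skew prevalence |
| `n_xist_snps` / `n_nonpar_snps` | 3 / 30 | a typical informative sample has a handful of het *XIST* SNVs and tens of non-PAR ones |
| `depth_mean`, `depth_dispersion` | 30, 5 | bulk RNA-seq coverage at X-linked SNVs, overdispersed |
| `overdispersion_rho` | 0.01 | mild extra-binomial noise in allelic counts |
| smoking | 36% unknown, 14% of known current | plausible adult-cohort smoking structure; effect 0 by default |
| RA | 8 discordant MZ pairs, effect 0 | enough pairs for the paired test; null by default |

What the generator does **not** emulate: mapping bias and base-quality
error (assumed removed upstream of the count tables), linkage between
sites, phasing error, cell-type composition within a tissue, clonal
dynamics over time (time points resample reads around a fixed latent p),
and non-normal latent skew (e.g. point masses from completely clonal
samples). Tests passing on synthetic data therefore validate the
estimators and inference machinery under the stated model, not robustness
to those artefacts.

## Cohort statistics

- Prevalence percentages round half-up to integer percent.
- Tissue–tissue and longitudinal concordance use Spearman rank correlation
  (average ranks on ties) on individuals present in both groups; fewer than
  3 shared individuals yields an "insufficient data" result, not an error.
- Age association: OLS of DS on age (slope, two-sided p). Twin relatedness
  is not modelled in the regression; family identifiers are carried in the
  output so users can check clustering. The lowess trend uses span 2/3; the
  onset ("inflection") is the first age where the smoothed first derivative
  exceeds a threshold and stays positive. The default threshold is
  *relative* — half the maximum smoothed slope — because a symmetric
  smoother crosses exactly half the plateau slope at the hinge of a
  piecewise-linear trend, making the detected onset insensitive to the
  (heavy) smearing that span 2/3 induces; an absolute threshold is
  available.
- Age-group tests split at 55 (55 itself in the older group): Welch t-test
  on mean DS (the unequal-variance default is deliberate; a pooled flag
  exists) and a 2×2 chi-square on skewed/random counts without continuity
  correction, plus decade-bin (40–50, 50–60, 60–70, >70) skew frequencies.
- Disease-discordant MZ pairs: paired Wilcoxon signed-rank on DS, exact
  null distribution for ≤ 25 pairs, normal approximation above; zero
  differences dropped, with a degeneracy flag (reported non-significant)
  when more than half the pairs tie exactly.
- Smoking: OLS of DS on current-vs-never smoking with age as covariate,
  fitted separately below/above the age threshold; unknown status excluded.

## Twin models

ACE maximum likelihood uses the exchangeable bivariate-normal likelihood,
which is invariant to within-pair ordering by construction, computed from
per-zygosity sufficient statistics (n, Σ(x+y), Σ(x²+y²), Σxy) so the fit
cost does not grow with the number of pairs. Optimization is L-BFGS-B over
(μ, a², c², e²) with non-negativity bounds, multi-started from the
Falconer-derived components, equal shares, and a near-CE point; the fitted
CE optimum is included as an additional start, which guarantees the nesting
property ll(ACE) ≥ ll(CE). The DZ additive correlation is fixed at 0.5 (no
assortative-mating adjustment). The p-value for A refers the likelihood
ratio of ACE vs CE to the 50:50 mixture of χ²₀ and χ²₁ (the null pins a
variance on its boundary); a likelihood ratio at numerical zero reports
p = 1.

Intraclass Spearman correlations use double entry (each pair contributes
both orderings; ranks on the doubled set), making the statistic exactly
invariant to twin labelling, with a seeded permutation p-value (default
10,000 permutations, two-sided on |IC|, `(1+k)/(B+1)` estimator) obtained by
reshuffling individuals into pseudo-pairs.

Stratified heritability assigns each complete pair to the younger/older
group by its shared pair age (co-twins share a birth date; if ages disagree
numerically the mean is used with a warning), reports ACE + IC per (tissue,
age group), skips empty strata, and still reports IC when one zygosity is
missing. Pairs with one informative co-twin and singletons never enter.
An optional within-stratum age residualization of the trait is exposed but
off by default.

## Numerical and testing choices

Degenerate inputs: zero-depth sites must be filtered before ASE; constant
age vectors raise a degenerate-design error in the age regression; an
all-tied discordant-pair set reports p = 1 with a degeneracy flag; beta
parameters collapse gracefully at allelic fractions 0/1 and at rho = 0.

Problem sizes in the recovery and calibration test suites — e.g. 200
samples at depth 1000 for estimator calibration, 100 replicates of 500+500
pairs for ACE recovery, 1000 (4000 for the exact Wilcoxon, whose n = 20
attainable size is 4.84%) replicates for type-I-error calibration, 600+600
pairs for the age-gated heritability contrast, 3000 samples for onset
detection — were chosen so each check's Monte Carlo error is small relative
to the asserted tolerance while the whole suite stays desk-scale.

## Known limitations

- DS is bounded and non-normal; ACE fits to DS are attenuated relative to
  the latent scale (quantified in the simulation tests, where fits on the
  latent scale recover the generating shares).
- The age regression and group tests treat co-twins as independent
  observations.
- The non-PAR estimator's aggregation is one defensible reading of a
  sparsely documented method class.
- The generator's escape model is per-site, not per-gene-with-many-sites,
  which slightly understates within-gene correlation of escape.
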