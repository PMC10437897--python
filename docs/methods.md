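# Methods

This note documents the models, numerical choices and limitations behind
`mlidscan`. It is written for a user who wants to know *why* the pipeline
behaves as it does, not just what the functions return.

## Data model and coordinates

Methylation is represented as β values (methylated / total signal) in
[0, 1], in a probes × samples matrix with explicit sample roles (control /
patient) and an optional aligned detection p-value matrix. Genomic
coordinates are 1-based, fully closed intervals on hg19; the build is a
config tag and is never inferred from the data. Chromosome names are
normalized to `chr`-prefixed strings on load. Missing β values are an
explicit `NA` sentinel; any probe with a missing value in an analysis
sample is dropped during QC with a logged count.

The bundled iDMR catalog contains twelve regions relevant to 11p15.5
imprinting disorders. The *PPIEL* and *FAM50B* intervals are exact
published coordinates; the remaining intervals are representative hg19
loci adequate for synthetic cohorts and examples. Full research catalogs
(~77 regions) are user-supplied as BED-like TSV. *VTRNA2-1* is
auto-flagged `excluded` because it is polymorphically imprinted in the
general population; excluded regions never contribute to MLID verdicts.

## Probe QC

Rules run in the fixed order detection → SNP → cross-reactive → sex
chromosome → missing, and a probe is charged to the first rule it trips,
so per-rule counts are deterministic and sum correctly. The detection
rule defaults to the strict `any_sample` aggregation (a probe fails if
its detection p ≥ 0.05 in any sample); `all_samples` is available because
published pipelines rarely state the aggregation. Sample-level QC
(conversion controls, sex checks) is out of scope.

## BMIQ normalization

Infinium type II probes have a compressed dynamic range. The correction
is strictly per sample:

1. A 3-component beta mixture (states U < H < M by mean) is fitted by EM
   separately to the type I and type II β vectors. The M-step is an exact
   weighted maximum-likelihood fit of each component's (a, b) from the
   sufficient statistics (Σw, Σw ln x, Σw ln(1−x)) using L-BFGS-B
   warm-started at the current parameters; if the optimizer fails to
   improve the expected complete-data log-likelihood, the current
   parameters are kept, so the observed-data log-likelihood is
   non-decreasing by construction.
2. Type II U-state values are mapped by the quantile transform
   β′ = F⁻¹(U,I)(F(U,II)(β)); M-state values analogously.
3. H-state values get an affine (dilation) map from the empirical type II
   U/H and H/M boundaries to their quantile-mapped images. If a
   neighbouring state is empty, the corresponding boundary anchors to the
   identity at the H extremes; if the boundaries degenerate (overlap), the
   H values are left unchanged.

Numerical choices: values are clipped to [1e-6, 1−1e-6] before fitting
(the beta density is undefined at 0/1); EM initialization uses fixed
tercile cut-points of the sorted data, making the whole fit deterministic
(the `seed` argument exists for API symmetry only); defaults max_iter =
500, tol = 1e-6 on the log-likelihood; state assignment is maximum
posterior with ties broken toward H. A component weight below 1e-4, or
data with essentially no spread, raises a degenerate-component error; at
least 30 probes per design type are required. Type I values are returned
bit-identical, the transform is monotone within each state, and output
stays in [0, 1]. Alternative normalizations (SWAN, noob, functional
normalization) are out of scope.

The pipeline default is filter-then-normalize; normalization can be
disabled or reordered by running the stages individually.

## Single-case statistics

The Crawford–Howell t-test treats the patient as a sample of size one
from the control population: t = (x − x̄)/(s·√((n+1)/n)) with the n−1
sample standard deviation, df = n − 1 and a two-tailed Student-t p. With
the typical n = 4 controls the test has 3 degrees of freedom — wide tails
are the price of honest single-case inference, which is why the DMP rule
couples the raw p < 0.05 with the large effect gate |Δβ| > 0.2 (a
20-percentage-point methylation difference). **No multiple-testing
correction is applied at the probe level**: the joint rule, not the
p-value alone, controls false calls. Both thresholds are strict
inequalities. Probes with zero control variance are skipped and counted.

## Region rule

Over a region's probes in genomic order, a call requires
(i) ≥ `min_significant` (default 4) passing DMPs, (ii) a run of
≥ `min_consecutive` (default 2) *adjacent* passing DMPs sharing one
direction, and (iii) no direction mixing among the region's passing DMPs.
"Adjacent" means neighbouring among the region's mapped probes, not
genome-wide adjacency. The published wording of such rules is ambiguous
between "≥ 4 significant probes" and "region covered by ≥ 4 probes"; the
default is the former (it matches reported borderline calls with exactly
4 significant probes), and `require_run_among_significant=False` gives the
latter. Mixed-direction regions are never aberrant but are flagged
`mixed` for review. Raising either threshold can only remove calls
(monotonicity, property-tested). A region with no mapped probes yields a
non-aberrant call with `n_probes = 0`.

## Epigenotype and MLID

The epigenotype derives solely from ICR1 (*H19/IGF2*:IG-DMR) and ICR2
(*KCNQ1OT1*:TSS-DMR): IC2 aberrant-hypo → IC2-LoM, IC1 aberrant-hyper →
IC1-GoM, IC1 aberrant-hypo → IC1-LoM, neither → none. If both ICRs are
aberrant (not observed in practice), the label follows the larger mean
|Δβ| and both regions are recorded as disease regions. MLID is ≥ 1
additional aberrant, non-excluded, non-disease region. Mechanism calling
(UPD, copy-number) is out of scope.

## Cohort level

Group DMPs use |mean Δβ| > 0.2 between patients and controls with a
per-probe Welch t-test p < 0.05. Welch was chosen because the groups are
small, unequal and heteroscedastic; a Mann–Whitney option exists. The
group comparison pools all patients against all controls. Sample
clustering on the group-DMP probes uses agglomerative hierarchical
clustering with Euclidean distance and average linkage — the common
default for methylation heatmaps — cut at k = 2 to expose the
two-epigenotype structure of mixed BWS/SRS cohorts. Per-patient count
tables report hyper/hypo DMP counts and percentages of a configurable
panel size (default: the analyzed-probe count) to 3 decimals.

## Clinical scoring and group statistics

The BWS consensus score is 2 points per cardinal feature and 1 per
suggestive feature over closed vocabularies; ≥ 4 is classical BWS. NH-CSS
is 1 point per each of six items. Pyrosequencing %mC standard-deviation
scores are (x − mean)/sd against a matched control panel (sample sd).
Growth-chart SDS values are accepted as precomputed inputs — reference
charts are external resources out of scope.

Fisher's exact test is two-sided under the point-probability convention
(sum of table probabilities ≤ the observed table's), delegated to
`scipy.stats.fisher_exact` and verified in the tests against a full
hypergeometric enumeration over all small tables. Mann–Whitney uses an
own exact enumeration of all group assignments (midranks, so ties are
handled) for m + n ≤ 12, matching the sample sizes such cohorts have, and
the tie-corrected normal approximation beyond.

## Synthetic cohorts

The generator emulates the targeted study design: 4 controls (default),
iDMR probes centred at β = 0.5 with per-probe sd 0.02, a genome-wide
background that is bimodal (≈45% near 0.1, ≈45% near 0.9, 10% mid-range),
and a small per-entry detection-failure probability (default 0.002).
Noise is beta-distributed via moment matching — a = μ(μ(1−μ)/σ² − 1),
b = (1−μ)(…) — so draws respect [0, 1] without clipping. Epimutations are
planted as mean shifts direction·effect·mosaic_fraction, the linear
consequence of a cell-fraction mixture of epimutated and normal cells.
Type II probes pass through a fixed monotone compression,
β′ = expit(0.8·logit(β)), chosen so that BMIQ's correction is observable;
the truth table's realized Δβ is measured before this map, since it is
the ground truth of the epimutation itself. Probe positions within a
region are evenly spaced in closed form (8 per region by default), and
configurable fractions of background probes carry SNP/cross-reactive/XY
flags (2% each) to exercise QC. Everything is reproducible from a single
seed.

What the generator does **not** emulate: raw two-channel intensities,
batch effects, cell-type composition, probe-specific baselines within a
region, and spatial correlation of noise along a region. Passing the
recovery tests therefore demonstrates the pipeline's logic and
calibration under the stated noise model, not performance on real arrays
with those additional artifacts.

## Validation strategy and problem sizes

Because raw clinical array data cannot be bundled, genome-wide behaviour
is validated by properties rather than by reproducing per-patient counts:

- **Parameter recovery** — 50 seeded cohorts (4 controls, 6 patients,
  effect 0.3, mosaic 1.0, sd 0.02; 12-region catalog, 8 probes/region,
  200 background probes, normalization on): planted aberrant iDMRs
  recovered with sensitivity ≥ 0.9, ≥ 90% of replicates free of unplanted
  calls, ≥ 90% of null patients MLID-negative.
- **Type-I calibration** — the single-case p < 0.05 rate over 20 000 null
  probes with n = 4 controls lies within 0.05 ± 0.01.
- **Oracle equivalence** — DMP calling, the region rule, Fisher exact
  (all 2×2 tables with N ≤ 15) and Mann–Whitney (m + n ≤ 10, with ties)
  agree exactly with independent brute-force enumerations; the
  Crawford–Howell statistic agrees to 1e-12 with the pooled two-sample t
  for a singleton group, which is algebraically the same quantity.
- **BMIQ properties** — type I identity, within-state monotonicity and
  Kolmogorov–Smirnov distance reduction under the synthetic compression
  model.

Cohort sizes in the tests are chosen to keep the suite fast while leaving
the per-region probe counts and control-group size at realistic values.

## Known limitations

- The Crawford–Howell test assumes approximately normal control noise;
  with beta-distributed noise at sd 0.02 around 0.5 the approximation is
  excellent, but calibration may degrade for probes near the [0, 1]
  boundary.
- With 4 controls, a single outlying control inflates s_c and can mask
  true DMPs; the pipeline does not perform control outlier rejection.
- The H-state BMIQ transform is an affine dilation between empirical
  state boundaries, which is robust but cruder than the U/M quantile
  maps; rank order within the state is still preserved.
- Region calls depend on probe coverage: regions with < 4 retained probes
  can never be called aberrant under the default rule.
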