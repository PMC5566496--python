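# Methods

This note records the models, the defaults and the open design choices behind
`mucometa`, in the order the pipeline runs.

## Synthetic cohort generator

The generator is first-class code, not a fixture: its job is to emulate the
*structure* of a paired mucosal 16S + MAS-NMR study closely enough that every
downstream stage can be validated by recovering planted truths.

**Design.** 18 patients, three biopsy sites each (`tumour`, `5cm`, `10cm`).
Histology is drawn per patient at the prevalences of a typical right-sided
colon-cancer cohort (EMVI 5/18, LVI 6/18, PNVI 1/18, KRAS 2/18,
well/moderate/poor differentiation 1/11/6, T stage 0–4 at 3/1/1/5/8, N stage
11/4/3) and held constant across the patient's samples.  A toggle biases
poor differentiation towards T3/T4 tumours, mirroring the tendency of
advanced tumours to be poorly differentiated.

**Counts.** Genus counts follow a Dirichlet-multinomial compositional model:
per-sample log abundance = smooth baseline (log-abundances linear from +3 to
−3 over 60 genera) + a patient-level N(0, σ_p) effect shared by the patient's
three samples + planted covariate effects; proportions are the softmax, a
Dirichlet draw with concentration p/overdispersion adds sample-level
dispersion (overdispersion→0 recovers the exact multinomial), and reads are
multinomial at a uniform depth in 5 000–50 000.  Defaults: 60 genera,
overdispersion 0.02, σ_p = 1.1.  σ_p was set so that inter-individual
variation dominates geographic site variation — roughly half of the simulated
patients form private Ward subtrees (with wide run-to-run spread), the
qualitative structure seen in mucosal cohorts.  Planted enrichments mirror
the classical associations (Fusobacterium ↑ on tumour; Streptococcus,
Solobacterium ↑ and Subdoligranulum ↓ with poor differentiation; Bacteroides
with EMVI; Roseburia with LVI; Aggregatibacter with KRAS).  Read depth and
genus count are not constrained by any published value and are exposed in the
config.

**Spectra.** Each spectrum is
`dilution_i × Σ_m conc_im × multiplet_m(ppm) + N(0, noise_sd)` on the
−1..10 ppm axis at 0.00055 ppm.  Multiplets are Lorentzian line sums with
Pascal's-triangle intensity ratios (1 / 1:1 / 1:2:1 / 1:3:3:1), J = 0.0175 ppm
(≈7 Hz at 400 MHz), half-width 1.5 mppm.  The metabolite panel uses
literature tissue shifts (lactate 1.33 d / 4.15 q, alanine 1.47 d, taurine
3.26/3.42, creatine 3.02/3.93, cholines 3.22, lipid envelopes 0.90/1.29/2.02,
…) with tumour log-fold-changes encoding the known directions (lactate,
taurine +1.0; glycine, alanine +0.7; lipids −0.5…−0.7; creatine, leucine,
valine 0).  Dilution factors are log-normal (σ = 0.3), which makes PQN
recovery a well-posed estimation problem; a small random axis shift
(σ = 3 mppm) gives calibration real work.  What the generator does **not**
emulate: baseline/phase artefacts, peak-shape distortions, ppm-dependent
lineshape, macromolecule background, or replicate-insert correlation
structure — so passing tests demonstrate correctness of the statistics, not
robustness to raw-spectrum pathology (out of scope: spectra are assumed
phased and baseline-corrected).

**qPCR.** `Ct_fn = Ct_pan − log2(ratio) + N(0, 0.3)` with log-normal
per-sample ratios around site medians (default tumour 4× the off-tumour
sites, matching the magnitude of reported tumour over-representation).

## NMR preprocessing

Stage order is enforced (calibrate → bin → exclude → PQN → scale; violations
raise).  Calibration shifts the axis so the tallest local maximum in
1.40–1.54 ppm sits at 1.47; among near-tied maxima (the two alanine doublet
lines) the lowest-ppm line is chosen, a fixed convention that keeps all
spectra of a cohort referenced to the same line (a constant half-J offset is
irrelevant downstream).  Bins are half-open `[lo+k·res, lo+(k+1)·res)`
aggregated by the **mean** of raw points (the choice among mean/sum is not
dictated by anything we reproduce; mean conserves intensity scale across
resolutions).  Exclusion membership is by bin centre; the defaults are the
four solvent/contaminant windows (PEG is nested inside the ethanol CH2
window).  PQN = total-area normalization, median-spectrum reference, per-row
median quotient over reference-positive columns, division by the quotient;
the stored per-sample dilution factor is area × quotient, i.e. the full scale
removed from the raw row.  PQN is idempotent (second-pass factors 1 within
1e-9).  Unit-variance scaling centres and divides by the sample SD
(ddof = 1); zero-variance columns are centred and flagged, not dropped, so
bin indices stay stable.  STOCSY runs on the normalized, never the scaled,
matrix.  Replicate inserts, when present in real data, are separate rows
sharing a patient id; patient-grouped CV then holds them out together.

Dilution-recovery experiments hold the per-sample metabolite variation at
zero (class effects only) so that the only per-sample scale is the planted
dilution; the residual recovery error then comes from the tumour/normal
composition difference slightly biasing the median quotient per class.

## Chemometrics

- **PCA**: centred SVD; Hotelling T² on the first k scores with the
  F-distribution limit `k(n²−1)/(n(n−k))·F_α(k, n−k)` at 95% confidence
  (the screening confidence is a convention, exposed in config).
- **PLS-DA**: NIPALS PLS2 on dummy-coded classes with standard X/Y deflation.
  Each component is initialized from the dominant left singular vector of the
  current X'Y and every direction's sign is fixed (largest element positive),
  so fits are deterministic with no random initialization anywhere.
  New-sample scores use R = W(P'W)⁻¹.
- **OPLS-DA**: binary only (one-vs-rest for multi-class).  w ∝ X'y; per
  orthogonal component the X-loading is stripped of its projection on w,
  the resulting class-orthogonal variation is deflated from X, and a single
  predictive component is extracted last.  With zero orthogonal components
  this reduces exactly to one-component PLS-DA.  The pipeline default is one
  orthogonal component; `n_orthogonal` can be chosen by maximizing
  cross-validated Q² when model selection is wanted.
- **MMC**: eigenvectors of S_b − S_w (class-size-weighted between-class minus
  pooled within-class scatter, both divided by n).  When variables outnumber
  samples the scatter matrices are formed in a PCA subspace retaining 95%
  variance, which stabilizes them; directions are mapped back and remain
  orthonormal.  A singleton class makes S_w ill-defined and raises unless a
  ridge `regularize` is supplied.
- **Cross-validation**: leave-one-sample-out or leave-one-patient-out (all
  rows of a patient held out together).  Per fold, scaling means/SDs are
  re-estimated on training rows only.  Q² = 1 − PRESS/TSS on pooled dummy-Y
  predictions; class prediction is nearest class mean in predictive-score
  space; the ROC score is the predicted indicator of the positive class.
- **Pseudo-loadings ANOVA**: per-variable one-way ANOVA p (constant variables
  p = 1 by convention), Benjamini–Hochberg q, sign of the
  class-of-interest-minus-reference mean difference, and magnitude = the
  covariance of the variable with the model's predictive score.

## Ecology

Rarefaction is multivariate-hypergeometric subsampling (without replacement)
to the lowest row sum.  Shannon uses the natural log.  The "Tau" similarity
index has no canonical definition in this setting; it is concretized as the
mean Kendall τ-b of a sample's genus vector against every other sample (a
constant vector is reported missing), behind a named function so an
alternative definition can be swapped without touching callers.  Index
normalization divides by the same patient's on-tumour value and fails loudly,
naming the patient, when the tumour sample is absent.  Bray-Curtis feeds
Ward linkage (Lance-Williams update on the dissimilarities; Bray-Curtis is
not Euclidean, so the tree is interpreted as a grouping heuristic — merge
heights are still monotone).  Patient concordance uses the private-subtree
criterion: a patient is concordant iff the smallest subtree containing all
their samples contains nobody else's; this is invariant to leaf-order
permutations.  NMDS minimizes Kruskal stress-1 by SMACOF majorization with
isotonic regression (20 restarts by default, best returned; restart seeds
derive from the run seed).  Genus–histology tests are Mann-Whitney (binary)
or Kruskal-Wallis (ordinal) on relative abundances with BH-FDR; whether to
test tumour-only or all-site samples is a caller choice (the pipeline tests
all sites).  Cluster–histology association uses Fisher's exact test (2×2),
chi-square (larger), or Kruskal-Wallis (ordinal).

## qPCR

Relative quantity = efficiency^(−ΔCt) with efficiency fixed at 2 (no standard
curve is modelled; the parameter is exposed).  The site comparison is a
paired Wilcoxon signed-rank, one-sided (tumour > 10 cm) to match the
directional over-representation hypothesis; two-sided is available.  Under a
null simulation the test holds its 5% level within Monte-Carlo error.

## Integration network

Metabolite features enter as bucket integrals (±0.02 ppm around each template
peak) rather than all 20 000 bins, so network nodes are named metabolites; a
full-bin mode is available by passing any feature frame.  Correlation is
Spearman with midranks and the t-approximation p-value (the regression
slope/p alternative is implemented); genera present in fewer than a quarter
of samples are excluded by the pipeline before correlation, since rank
correlations on near-constant vectors are tie-dominated.  Edges keep pairs
with p < 0.05 (or BH q with `use_fdr`); signs come from ρ.  Stage networks
use all samples of the patients in each stage group (T-stage map
0–2 → "0/1", 3 → "3", 4 → "4", configurable); stage-consistent edges must
match in pair **and** sign across every stage.  Layouts are seeded
Fruchterman-Reingold with |ρ| edge weights; connected components are laid
out separately and tiled so bounding boxes cannot overlap.

## Orchestration and determinism

A single run seed is expanded through `numpy.random.SeedSequence` into one
seed per stage; every stochastic step (simulation, rarefaction, NMDS
restarts, layouts) consumes only these.  The manifest records parameters,
stage seeds and the SHA-256 of every artifact; rerunning the same config and
seed reproduces every hash, which the test suite asserts end-to-end.

## Problem sizes and limitations

Validation experiments use the cohort's natural scale (54 samples, 20 000
bins, 60 genera) for the pipeline runs, and smaller planted-truth designs
(n = 27–100, 5–400 variables, 100–500 Monte-Carlo replicates) for the
calibration experiments — sizes chosen to make Monte-Carlo error small
relative to the properties asserted.  Known limitations: OPLS-DA is binary
(one-vs-rest otherwise); no variable selection or permutation-based model
p-values; no phylogenetic (UniFrac) distances; ordinal trend tests for
multi-level histology are not implemented.  Matched tissue 16S + MAS-NMR
cohorts of this design are not publicly available, so validation is by
recoverable-structure properties on synthetic cohorts; clinical AUCs and
p-values measured on real tissue are outside what these tests can certify.
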