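# Methods

This note documents the models, conventions and design choices behind
`neoforest`, in the spirit of a statistical-software methods appendix.

## Feature definitions

**Sequence descriptors.** The mutant peptide (8–12 residues, standard
20-letter alphabet) and its predicted 9-residue binding core are the
inputs. The *non-anchor subsequence* is core positions 4–8 (1-based):
positions 2 and 9 are the canonical MHC-I anchors and position 1–3/9
flank the groove, so 4–8 is the TCR-facing stretch. Features:

| feature | definition |
|---|---|
| HydroAll / HydroCore | mean Kyte–Doolittle hydropathy of the full peptide / non-anchor subsequence |
| PropHydroAro | fraction of {V,I,Y,F,W,L} in the full peptide |
| Aro | fraction of {F,W,Y} in the full peptide |
| PropAro, PropSmall, PropAcidic, PropBasic | fractions of {F,W,Y}, {A,G,S,T,C,P,N,D}, {D,E}, {K,R,H} in the non-anchor subsequence |
| CysRed | count of C in the full peptide |
| Inst | Guruprasad instability index, (10/L)·Σ DIWV(aa_i, aa_{i+1}) |
| pI | pH of zero Henderson–Hasselbalch net charge, EMBOSS pKa set, bisection on [0, 14] to 1e-3 |
| mw | average-isotope molecular weight |
| DAI | %Rank_EL(wild-type) − %Rank_EL(mutant); positive = the mutation improved predicted presentation |
| SelfSim | normalised BLOSUM62 string kernel between mutant and wild type, K(a,b)/√(K(a,a)K(b,b)), K summing position-wise substitution-score products over all k-mer pairs, k ≤ 3 |

Design points that were genuinely open and the choices made:

- *Hydrophobicity scale*: Kyte–Doolittle (configurable map). It is the
  standard hydropathy scale and the one practitioners reach for first.
- *"Small" residue set*: the Taylor grouping {A,G,S,T,C,P,N,D}
  (configurable) — a standard physicochemical classification.
- *CysRed*: a count rather than a fraction; configurable.
- *DAI sign*: wild-type minus mutant, so that positive values mean
  improved binding; a flag flips it. Rank-based classifiers are
  orientation-symmetric in AUC magnitude, so only interpretation is
  affected.
- *Self-similarity kernel*: a normalised substitution-matrix k-mer
  kernel (k ≤ 3, BLOSUM62) — the standard peptide kernel in the epitope
  literature; both matrix and k are pluggable.
- *8-mer cores*: an 8-mer presented on MHC-I stretches across the
  groove, so its 9-position core contains an inserted position. The
  caller marks it `X`; `X` scores 0 on hydrophobicity scales and is
  excluded from class-proportion numerators and denominators.
- Instability, molecular weight and the underlying residue tables come
  from biopython's `ProteinAnalysis`; the test-suite cross-checks them
  against direct table arithmetic.

**Mutation context.** `ValMutRNACoef` = n_variant / (n_coverage + 100):
the +100 pseudo-coverage shrinks poorly covered variants toward 0.
RNA validation is a trichotomy (validated / not found / insufficient
coverage, default minimum coverage 1).

**Patient (TME) covariates.** CYT is the geometric mean of GZMA and
PRF1 TPM, with a default pseudocount of 0.01 so a single silent gene
does not zero the statistic. Cell-population scores are means of
log2(TPM+1) over marker genes (raw-TPM mode available); the package
ships an illustrative synthetic marker configuration of ten
populations, and real analyses should supply a curated marker list.
`MCPmean` is the plain mean of the non-missing population scores — the
populations are strongly inter-correlated, and forests cannot rank
correlated inputs meaningfully, so one pooled infiltration covariate is
used. `HLAexp` sums TPM over HLA-A/B/C (sum vs mean is a config
choice; sum is the default).

## Feature sets

The default `improve` set has the 22 features listed in
`datasets.IMPROVE_FEATURES`: the sequence descriptors above minus
HydroAll (|ρ| ≈ 1 with HydroCore) plus the external predictor columns
minus VarAlFreq (collinear with PrioScore); one-hot mutation
consequence/position encodings and the RNA-validation coefficient are
computed but excluded by default. `improve_simple` further drops
PrioScore and CelPrev (the features an external benchmark set cannot
supply); `improve_tme` adds CYT, MCPmean and HLAexp.

## Dataset handling

Missing values are imputed with the **training-fold mean** only; test
rows never contribute to the means. The correlation filter removes one
member of every pair with |Spearman ρ| ≥ 0.7: the highest-correlation
pair is resolved first, the member with the lower univariate partial
AUC (orientation-free: the better of the feature and its negation) is
dropped, and exact ties drop the later feature in canonical name
order, making the result independent of column order. The filter runs
inside each training fold by default; a whole-dataset mode exists.

## Partitioning

Cross-validation folds must respect two leakage channels: patient
identity (patient-level covariates are constant within a patient) and
sequence redundancy (the same immunogenic mutation can recur across
patients). Patients are clustered into connected components via edges
between owners of immunogenic peptides sharing any identical contiguous
6-mer; components are assigned to folds greedily, largest first into
the currently smallest fold (the seed only permutes tie order among
equally full folds). Motif edges involve immunogenic peptides only;
negatives follow their patient. Finally, any training peptide whose
mutant sequence occurs verbatim in the test fold is removed from
training. Motif length 6 is a compromise — short enough that
near-identical 8–12-mers collide, long enough that unrelated random
peptides essentially never do (a random 9-mer pair shares a given
6-mer with probability ≈ 20⁻⁶) — and is configurable.

## Ensemble

Hyperparameters are fixed: depth 6, 2,000 trees per forest, minimum
leaf 6, 50 subsamples of 500 negatives. Each subsample trains one
forest on all positives plus a fresh without-replacement negative draw;
draws are independent across subsamples via per-subsample spawned RNG
streams, so results are reproducible from one seed and invariant to
the number of subsamples requested. The ensemble score is the mean of
the forests' positive-class probabilities (averaging probabilities
rather than ranks; the two orderings are nearly identical and
probabilities compose simply). When fewer than 500 negatives exist,
every draw uses all of them and a warning is logged. Feature
importances are impurity importances averaged over forests, then over
folds, with features deselected in a fold contributing 0 there.

The cross-validation loop re-runs feature selection and imputation per
training fold. A *test profile* (200 trees, 10 subsamples) exists for
routine runs and simulation studies; the full 2,000 × 50 profile is
kept for fidelity runs. The packaged simulation studies use the test
profile on 30-patient × 200-peptide cohorts — forest ensembles of this
form are insensitive to tree count well below 200 trees at these
sample sizes.

## Evaluation conventions

- AUC by trapezoid over the tie-grouped empirical ROC (equivalently the
  Mann–Whitney statistic; the suite asserts equality to 1e-12).
- **AUC01** is the *unnormalised* area over FPR ∈ [0, 0.1]: range
  [0, 0.1], perfect = 0.1, chance = 0.005, with linear interpolation at
  the cut. A McClish-normalised variant is behind a flag.
- The DeLong paired test uses the structural-component covariance
  estimate and a two-sided normal p-value; identical score vectors
  return p = 1 by convention, and a zero variance estimate with unequal
  AUCs (e.g. two mutually perfect classifiers on a tiny sample) is an
  error rather than a fabricated p-value.
- The operating point is the threshold minimising
  |sensitivity − specificity| over observed scores plus midpoints, ties
  toward higher specificity; a score equal to the threshold counts
  positive. Orientation is explicit everywhere because the
  eluted-ligand rank baseline is better when *low*.
- MCC uses the convention 0 when any marginal is empty.
- Per-patient top-k capture ranks each patient's peptides by score with
  ties broken by peptide id; patients without positives are undefined
  (missing), not zero.

## Survival stratification

A patient's neoepitope load is the count of peptides at or beyond the
operating-point cutoff. Quartile groups use linear-interpolation
quantiles (R type 7, matching the default of the R survival stack):
high when load ≥ Q3, low when load ≤ Q1, medium-low on (Q1, Q2],
medium-high on (Q2, Q3). Both outer groups claim their boundary, so
when quartiles coincide the precedence is
high > low > medium-high > medium-low. Kaplan–Meier curves and the
log-rank test come from lifelines; the high-vs-low hazard ratio is a
single-binary-covariate Cox fit by Newton iteration on the Breslow
partial likelihood (cross-checked against lifelines to 1e-4 in the
suite), with an explicit error when a group has no events (monotone
likelihood).

## Synthetic cohort generator

The generator emulates the *structure* of a barcode-multimer screen:

- 30 patients by default, 100–400 candidates each, peptide lengths
  8:9:10:11 at 10:60:20:10 (the MHC-I ligand length bias), residues
  uniform over the 20-letter alphabet (human-proteome frequencies can
  be supplied);
- eluted-ligand ranks drawn bimodally below 2, mimicking a screen
  pre-filtered to predicted binders with strong- and weak-binder peaks;
- labels from a logistic model over z-scored core hydrophobicity
  (weight 1.0), hydrophobic/aromatic proportion (0.5), presentation
  rank (−0.4), cellular prevalence (0.3) and a patient-level
  immunocompetence scalar (0.4) that also scales the patient's
  GZMA/PRF1/marker/HLA expression — the weights mirror the qualitative
  importance ordering seen in real screens, with core hydrophobicity
  dominant;
- the intercept is calibrated by bisection so the expected positive
  rate equals the target (default 2.7%), which keeps the realised
  prevalence a single binomial draw around the target;
- 5% of immunogenic sequences are duplicated into other patients
  (staying immunogenic) so cross-patient motif edges exist; 10% of
  records are frameshift-like (no wild-type peptide), exercising the
  missing-value path for DAI and SelfSim;
- RNA read support is Poisson coverage with binomial variant reads at
  the simulated allele fraction; survival times are exponential with
  hazard decreasing in the patient's true immunogenic count, with
  uniform censoring.

What the generator does **not** emulate: HLA-specific binding motifs
(all external predictor columns other than the rank are pure noise),
biophysically realistic rank–sequence coupling, inter-feature
correlation structure of real predictors, cohort heterogeneity, or
label noise from false-negative screening. Passing tests therefore
demonstrate that the pipeline recovers signal *of the planted form*
under realistic prevalence and cohort geometry — not that the model
attains any particular performance on real screens.

## Known limitations

- The "nested" aspect of cross-validation is per-fold feature selection
  and imputation only; hyperparameters are fixed, so no inner
  hyperparameter loop exists.
- The correlation filter's univariate criterion (partial AUC at 0.1)
  is a configurable choice; full AUC gives slightly different
  deselections on weak features.
- With constant prediction scores the operating-point search returns
  the single available candidate, which makes every peptide predicted
  positive.
- The Cox fit is intentionally limited to one binary covariate;
  multivariate or stratified models are out of scope.
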