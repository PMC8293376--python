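# Methods

This package implements a peptide-to-fiber-type analysis chain for
skeletal-muscle proteomics: absolute label-free quantification, fiber-type
profiling, and discriminative peptide-panel selection. This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Problem setting

Skeletal muscle fibers are classed as type I, IIa, IIb or IIx by their
dominant myosin heavy chain (MYH) isoform (MYH7, MYH2, MYH4 and MYH1
respectively; IIb is rodent-specific). DIA mass spectrometry of
laser-microdissected fibers yields a long-format peptide intensity table:
one row per (sample, protein group, peptide, proteotypicity flag,
intensity), with intensities missing — not zero — where a peptide was not
quantified. The pipeline turns such tables into absolute protein amounts,
fiber-type profiles, and a minimal peptide panel that assigns fiber types.

## Absolute quantification

**LOESS normalization.** Between-sample intensity-dependent bias is removed
on the log2 scale by cyclic normalization against the per-peptide row mean:
for each sample, `lowess` of M = sample − reference on
A = (sample + reference)/2 is fitted over peptides observed in both, and
the fitted trend is subtracted; the reference is recomputed each cycle
(defaults: span 0.7, 3 cycles). LOESS normalization has no single
canonical mode or span, so both are explicit configuration, not
inferences.
Missing cells are excluded from fitting and remain missing. A sample
sharing fewer than 10 observed peptides with the reference is rejected by
name.

**iBAQ.** For protein p and sample s,
iBAQ(p,s) = Σ (observed peptide intensities of p in s) / N_theo(p), where
N_theo is the number of fully tryptic peptides (cleave C-terminal of K/R,
not before P, zero missed cleavages) of length 6–30 from the protein's
sequence. Without a FASTA, N_theo falls back to the number of distinct
observed peptides per protein — logged as an approximation. A protein with
no observed peptide in a sample is missing there; zero-filling would
corrupt the ratio.

**aLFQ scaling.** Relative iBAQ values become absolute amounts by
proportional allocation of a known total protein mass (default 200 ng).
Scaling is **per sample** (each sample's non-missing quantities sum exactly
to the configured total); the classical global variant (divide by the grand
sum over all samples) is available via `per_sample=False` for comparison.
Percentages are per-sample shares summing to 100.

Exactness of the two conservation laws (per-sample ng total; per-sample
percentage total) is by construction and is verified to 1e-9 relative
tolerance in the tests and the acceptance script.

## Fiber-type profiling

**MYH fiber calling.** Proteotypic peptide intensities of each MYH isoform
are summed over all samples of a fiber type; the called type is the argmax
over types. Ties report all maximizers rather than picking one, because
hybrid fibers genuinely co-express isoforms.

**Filter → impute → cluster.** Proteins quantified in fewer than 50% of
samples are removed. Remaining missing log2 values are drawn from
Normal(μ_s − 1.8·σ_s, (0.3·σ_s)²), with μ_s, σ_s the observed mean and SD
of sample s — the standard left-censored ("downshifted normal") imputation;
width 0.3 and downshift 1.8 are the conventional defaults. Imputation is
per sample column (respecting sample-specific detection limits); a
whole-matrix mode exists behind `per_sample=False`. Rows are reduced to
per-fiber-type medians, Z-scored (population SD; constant rows dropped with
a warning), pre-clustered by k-means (k = min(300, n_rows), ≤ 10
iterations, deterministic k-means++ under the seed), and the pre-cluster
centroids merged by Euclidean average-linkage hierarchical clustering; the
tree is cut into `n_final` clusters (default 4) and membership propagated
back to proteins. When rows ≤ k_pre the k-means stage is the identity. The
reduction from 300 pre-clusters to a handful of final profiles has no
canonical rule, so the cut count is explicit configuration (default 4).

**Annotation percentages.** Given a protein → category map (unmapped →
"Other"), the per-cluster composition is count / cluster size × 100,
rounded to 2 decimals for reporting. The arithmetic is always exact
count/size: reference tables of this kind occasionally contain internally
inconsistent entries (e.g. 53 of 137 reported as 37.23% where
53/137 = 38.69%), and this implementation makes no attempt to reproduce
such inconsistencies.

**PCA.** Samples are observations, proteins features; top-two component
scores and loadings are returned with loadings ordered by decreasing
maximal absolute value for separator inspection.

## Peptide-panel selection

**RF-RFE.** Starting from all peptides (sample × peptide log2 matrix,
imputed), each round (1) estimates panel accuracy by repeated stratified
k-fold cross-validation with a seeded random forest (defaults 5 folds × 10
repeats, 500 trees, √p features per split, no depth limit), (2) computes
feature importances, and (3) removes the ⌈drop_fraction × size⌉
least-important peptides (≥ 1, never past `min_panel`), recording
(panel, accuracy). The selected panel is the smallest within 0.5 percentage
points of the trace maximum; ties break to the smaller panel, then
lexicographic order. Inside the loop the forest's Gini importances are used
(free with the fit); the standalone `rf_importance` defaults to
permutation-style importances, and `rfe(importance="permutation")` switches
the loop over. Inputs are canonically sorted, making accuracy estimates
invariant to sample and column order.

**Threshold decision tree.** A small CART (Gini impurity, thresholds at
midpoints between adjacent distinct training values, `min_leaf` guard) is
grown over the selected 1–3 peptides, giving human-readable classification
rules. On separable training data all terminal nodes are pure; identical
samples with conflicting labels yield an impure leaf rather than an error.
The implementation is cross-checked against scikit-learn's CART in the
tests.

**Confirmation.** A trained panel classifier is applied to an independent
labeled data set: panel peptides are matched by sequence, samples with
incomplete panel values dropped, classes with fewer than `min_class_n`
(default 4, reflecting that a three-sample class is too small for
meaningful per-class accuracy) excluded and listed, and each panel peptide
Z-scored within the external set before prediction. Per-data-set Z-scoring
is this package's explicit harmonization choice for cross-platform shifts;
it makes confirmation invariant to global intensity scaling, which the
tests assert.

## Synthetic data generator

The generator defines the study conditions all tests run under: 4 fiber
types × 14 samples (56 total), four MYH-like proteins whose linear-scale
cross-type profiles follow coarse published proportions (e.g. type-I
isoform ~20% carried into IIa, near-zero in IIb), five slow and five fast
marker proteins with ±2/±1 log2 gradients over the I → IIa → IIx → IIb
ordering, and 250 background proteins with 2–8 peptides each. Cell values
are Normal on log2 (protein baseline U[18,30] + peptide ionization offset
N(0,1) + type effect, within-type SD 0.4), exported linear. Missingness is
left-censored: P(missing) = Φ((c − x)·strength/σ) with c solved by
bisection to hit the target overall fraction (default 0.2). Optionally a
two-peptide panel is planted (fixed sequences TINEVENQVLTR and
IAEQELLDASER): peptide A takes three levels across IIa < IIb < IIx (type I
at the IIa level), peptide B lifts all fast types one separation (default
4 log2) above type I — so the pair jointly, but neither alone, separates
all four types. Planted peptides are fully observed.

What the generator does **not** emulate: chromatographic drift, charge
states, fragment-level DIA signal, peptide-level interference, correlated
protein modules beyond the class effects, or realistic protein-group
ambiguity. Passing tests therefore demonstrate correctness of the
computations under the assumed log-normal/left-censored model, not
performance on real acquisitions. The within-type SD (0.4) and
peptides-per-protein range (2–8) are stand-ins chosen once as plausible for
DIA fiber data; no published values exist for them.

## Problem sizes and numerical choices

- Tests and examples run the generator at 6 samples/type and 40–60
  background proteins; the 20-seed panel-recovery check and the acceptance
  script use the full default design (56 samples, 250 background proteins).
  Inside the 20-seed elimination loop the forest uses 50 trees with
  3-fold × 1-repeat CV and drop_fraction 0.3 — elimination needs only a
  stable importance ranking; the selected two-peptide panel is then scored
  at the full defaults (500 trees, 5×10 CV).
- Determinism: every stochastic step (generator, censoring, imputation,
  k-means, forests, CV splits, permutation importances) takes an explicit
  seed; fixed seeds give bit-identical outputs.
- Degenerate inputs: all-missing samples, single-class labels, constant
  matrices/rows, too-small classes for stratification, and panels without
  matching peptides raise errors naming the offending sample/field; ties in
  MYH calling and CART majority votes break deterministically
  (report-all and lexicographic respectively).

## Known limitations

- The per-sample aLFQ totals are exact by construction; accuracy of
  absolute amounts still depends on iBAQ's linearity assumptions and the
  theoretical-count fallback when no FASTA is given.
- Average linkage is computed on k-means centroids when rows exceed
  `k_pre`, so the final partition can differ from linkage on the raw rows.
- The RFE trace is not monotone in panel size and is not required to be;
  only the extremes are sanity-checked.
- Cross-data-set confirmation assumes a location/scale shift is the
  dominant platform difference; nonlinear response differences are not
  corrected.
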