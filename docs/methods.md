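# Methods

`abcc2pred` re-implements, as a tested and reusable pipeline, the workflow
used to build binary classifiers of putative ABCC2/MRP2 substrates from
NCI-60-style screening data: compounds are labeled by the Pearson
correlation coefficient (PCC) between their cytotoxicity profile and
transporter mRNA expression, cleaned by a multistep curation protocol,
described by 2D connection-table descriptors, split into training and test
sets, reduced by correlation-based feature selection, and classified by
cost-sensitive learners evaluated with imbalance-aware statistics.  The
original inputs (the NCI structure archive and the screening supplementary
table) are external downloads, so the package ships a synthetic library
generator that emulates their statistical structure; every stage is
exercised end to end without network access.

## Labeling model

A compound is a *substrate* iff its PCC is **lower than or equal to** the
threshold (−0.25 by default; −0.30 as the stricter alternative).  The
boundary is inclusive by definition and the package treats it as such
everywhere.  On the real data this yields a strongly imbalanced problem
(roughly 13% substrates at −0.25), which motivates the cost-sensitive
machinery below.

## Curation protocol

Seven ordered steps (the now-standard cleaning recipe for QSAR datasets):
inorganics (no carbon) → mixtures (keep the single organic component of
organic/inorganic salts, delete multi-organic mixtures) → organometallics
→ unsupported elements (outside {H, B, C, N, O, F, Si, P, S, Cl, Br, I}) →
chemotype standardization (clear stereo, normalizer, neutralizer,
canonical tautomer) → duplicates (identical standardized structures with
agreeing PCC keep the first entry; conflicting PCC deletes the whole
group, exact agreement tolerance 1e−6) → permanent charges (net formal
charge ≠ 0 removed; net-zero zwitterions are retained because the rule
tests the net charge only).  The order is semantic: a metal counter-ion
salt survives the metal check because desalting runs first.

Deliberately open choices, pinned here: "similar organic weight" for
mixtures is operationalized as *any* record with ≥ 2 carbon-containing
components is removed — the only reading that needs no size heuristic;
tautomer canonicalization uses the RDKit MolStandardize scoring rules
(named in `CurationConfig.tautomer_ruleset`) since canonical tautomers
differ between toolkits and reproducibility matters more than parity with
any particular commercial tool.

The optional protonation variant (`charge_variant="charged"`) ionizes
strong acids (carboxylic, sulfonic, sulfinic, sulfate/sulfamate,
phosphorus oxyacids, one ionization each) and strong bases (aliphatic
amines, amidines, guanidines — not amides, anilines or aromatic ring
nitrogens) by substructure rules; no pKa model is used.  The SMARTS
definitions live in `abcc2pred.config`.

## Descriptor panel

The 25-descriptor modelling panel combines simple counts (donor atoms,
halogen/heteroatom counts, bonds including hydrogens, SSSR rings, TPSA)
with van-der-Waals surface-area (VSA) descriptors: per-atom surface areas
from Labute's connection-table approximation, summed over atoms binned by

* PEOE (Gasteiger–Marsili) partial charge, computed on the
  explicit-hydrogen graph with 6 damping iterations, half-open bins
  [lo, hi) at 0.05-wide edges; `PEOE_VSA_FNEG`/`FPOS` are the negative/
  positive area fractions of the total area (zero-charge atoms belong to
  neither numerator), and `PEOE_VSA_PPOS` sums area over atoms with
  charge > +0.2, consistent with the printed bin edges;
* Wildman–Crippen atomic logP contribution (`SlogP_VSA0` ≤ −0.40,
  `SlogP_VSA1` in (−0.40, −0.20]), heavy atoms with attached hydrogens'
  area folded in;
* Wildman–Crippen molar-refractivity contribution for the `SMR_VSA*`
  columns.  The reference bin bounds for these columns are printed with
  negative signs although Wildman–Crippen MR contributions are
  non-negative; the bounds are implemented exactly as printed ((lo, hi]
  on the sorted pair), so on real chemistry these columns are constant
  zero and the z-scorer flags them.  They are retained for panel
  completeness; this is a documented limitation, not an error path.

Pharmacophore-typed descriptors use explicit, shipped rules: `vsa_don` is
the area of *pure* donors, defined as N–H nitrogens (an O–H oxygen is
simultaneously an acceptor, hence not pure); `vsa_base` counts basic
nitrogens with the same SMARTS set the protonation variant uses;
`vsa_other` is the area of atoms matching none of
acidic/basic/donor/acceptor/hydrophobe (S, P, Si, B in practice).  The
extended panel adds the remaining charge and logP bins (which tile the
axes, so bin sums conserve the total area to 1e−6) plus simple counts;
descriptors of the original 93-descriptor commercial panel without a
public definition are not reproduced.

Structural keys are the public 166-key MACCS set; Tanimoto similarity is
|A∩B|/|A∪B| with the empty/empty case defined as 1.

## Splitting

* `random_stratified`: per-class floor sizing — floor(0.8 × class size)
  of each class goes to training (154 substrates → 123), uniform given
  the seed.
* `maccs_diverse` / `descriptor_diverse`: deterministic greedy MaxMin.
  Training size is ceil(fraction × N) (1204 → 964).  The first pick is
  the first member of the most distant pair; each later pick maximizes
  the minimum distance to the picked set; all ties break toward the
  earlier input index, so diverse splits carry no RNG.  Distances are
  1 − Tanimoto over structural keys, or a continuous Tanimoto
  dissimilarity over z-scored, min–max-rescaled descriptors (Euclidean
  available by option).  Diverse selection ignores labels, so diverse
  training sets have uncontrolled class ratios — a property of the
  method.

## Feature selection

CFS merit: merit(S) = k·r̄cf / sqrt(k + k(k−1)·r̄ff) with mean absolute
feature–class and feature–feature correlations.  The default correlation
is Pearson (point-biserial against the binary class): the descriptors are
continuous and z-scored, and Pearson is deterministic and parameter-free.
A symmetric-uncertainty mode (equal-frequency 10-bin discretization) is
available for comparison with entropy-based implementations.  The search
is forward best-first from the empty set, expanding the open subset with
the highest merit and stopping after 5 consecutive non-improving
expansions; ties break by descriptor vocabulary order.  On enumerable
problems (≤ 12 features) the search result matches exhaustive subset
enumeration in the test suite.  Selection is performed once on the
training set before cross-validation (the workflow's protocol); a nested
per-fold variant is available for leakage-aware analysis.

## Cost-sensitive modelling

Five base learners with pinned defaults (the original workflow names
none): Gaussian naive Bayes; 1-nearest-neighbour with Euclidean distance;
an entropy decision tree with minimum leaf size 2; a 100-tree random
forest with √p features per split; a linear-kernel SVM with C = 1.
Misclassification costs (FN : FP, FN = substrate predicted non-substrate)
are realized as instance weights rescaled to sum to n, passed as sample
weights where the learner supports them and as a seeded weighted resample
of size n otherwise (kNN).  Bagging draws B bootstrap replicates of the
weighted training set (rows sampled with probability proportional to
weight) and aggregates by majority vote with ties going to the substrate
class; B = 10 by default.  The cost grid ships the four published presets
(65:2.5, 150:3.5, 81:1.20, 80:1.10) plus 1:1, scored by cross-validated
G-mean — the selection criterion for "best" is not stated in the source
workflow, and G-mean is the natural imbalance-robust default; this is a
documented assumption.

Cross-validation is stratified k-fold (k ∈ {5, 10}); per-fold confusion
matrices are pooled (summed) before metrics are computed, so pooled
TP + FN equals the substrate total exactly.

## Evaluation

Substrate is the positive class.  Specificity = TN/(TN+FP), sensitivity =
TP/(TP+FN), precision = TP/(TP+FP), G-mean = √(sens·spec), MCC with the
standard four-marginal denominator, accuracy = (TP+TN)/n.  The *balanced*
accuracy (sens+spec)/2 is always reported alongside: published report
tables in this area quote it under the name "Accuracy" (every printed row
is consistent with the balanced variant and not with the standard
formula), so both are computed and the display rounding (two decimals;
percent scale for rates) matches print precision.  Zero denominators
yield 0 with an `undefined` flag rather than an exception, so degenerate
CV folds cannot crash a run.  F-measure is computed and reported but is
never a headline statistic.

## Applicability domain

PCA of the training compounds in the space of the model's selected
descriptors (inputs are assumed z-scored with training parameters; the
model centers and optionally rescales).  The published domain call was a
visual score plot; the operational rule here is a bounding box over the
first two component score ranges, expandable by a margin (margin m scales
each accepted range by 1 + m; the in-domain set grows monotonically with
m), with leverage (h* = 3p/n) as an alternative criterion.  Decisions are
invariant under rigid rotations of the feature space because only the
covariance eigenstructure enters.

## Synthetic data generator

The generator emulates the real inputs' statistical shape, not their
chemistry: molecules are assembled from a seeded fragment grammar
(benzene, naphthalene, pyridine and C3–C8 chains; Cl, Br, OH, NH2, COOH,
SO3H, NO2, SMe substituents, up to four per scaffold, unique after
standardization), and activities follow

    pcc = β0 + β1·z(PEOE_VSA_FNEG) + β2·z(vsa_don) + β3·z(SlogP_VSA0) + ε

with β = (−0.15, −0.10, −0.08), ε ~ N(0, 0.15), clipped to [−1, 1].  The
signal enters through the three descriptors consistently reported as
discriminative for this transporter (fractional negative charge,
H-bond-donor area, low-logP area), so downstream feature-selection
recovery tests the workflow's central qualitative claim at desk scale.
The intercept is calibrated by placing the k-th smallest signal value
exactly at the −0.25 threshold, k = round(0.13·n), reproducing the real
class imbalance; calibration outside ±0.02 of the target raises.  Dirty
records (inorganics, multi-organic mixtures, a strippable salt,
organometallics, a selenium compound, a permanent cation, a
conflicting-PCC duplicate pair) are appended with machine-readable
expected fates; their structures (saturated carbocycles, metals) are
outside the grammar's reach so they can never collide with clean records.

What the generator does **not** emulate: natural-product-like scaffold
complexity, the correlation structure of a real screening library,
assay noise heterogeneity, or any upstream derivation of PCC values from
cytotoxicity/mRNA matrices.  Passing end-to-end tests therefore shows the
machinery is correct and the workflow can recover a known signal of
realistic size under realistic imbalance — not that the published
real-data performance figures are reproduced, which would require the
external structure archive and bit-exact parity with the commercial
descriptor implementation.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at
n = 2000 compounds over 10 seeded replicates (signal recovery and test
G-mean), the cost-monotonicity experiment at n = 600 over 25 (suite) /
10 (script) replicates, and the splitter sizing checks at the published
N = 1204.  These sizes were chosen as the smallest at which the class
counts and stochastic bounds are stable.  Other numerical conventions:
population standard deviation throughout z-scoring; constant descriptor
columns map to zero and are flagged; merit ties and MaxMin ties break
deterministically (vocabulary/input order); bagging vote ties go to the
minority class; seeds derived from a user seed stay below 2^31.

## Known limitations

* Descriptor values approximate the commercial originals (different
  partial-charge parameterization details, VSA radii, pharmacophore
  typing); bit-exact parity is out of scope by design.
* The `SMR_VSA*` columns are constant zero under the printed bin bounds
  (see above).
* Best-first search with a stale limit is a heuristic; global optimality
  is verified only on enumerable problems.
* The curation idempotence guarantee is as strong as the tautomer
  canonicalizer's; the shipped rule set is idempotent on all tested
  chemistry.
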