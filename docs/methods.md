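# Methods

## Potency normalization

Bioactivity records arrive in mixed standard types and units. Only
concentration-typed records (IC50, EC50, Ki, Kd, AC50, Potency) are
convertible to the molar scale; the transform is

    score = −log10(concentration in mol/L)

with unit conversions nM → ×1e−9, µM → ×1e−6, M → ×1, and
µg/mL → (value × 1e−3 g/L) / MW, where MW is the RDKit average
molecular weight of the compound's structure. Functional and binding
types are pooled without type-specific offsets: the score is a single
consistent potency axis, not a per-assay calibrated pIC50. Percent-type
readouts (Inhibition, Activity) have no molar magnitude and yield no
score. Records with relation `>` (less potent than the reported bound)
are marked right-censored: they contribute no value to potency averages
— which would otherwise be biased downward by an unknown amount — but
they do count as inactivity evidence; `<` records contribute their bound.
Scores are never clipped; the activity threshold is applied downstream.

## Subtype averaging

The three melatonin receptor subtypes (MTNR1A, MTNR1B, MTNR1C) are
strongly correlated, so a compound's measured melatonin score is the
unweighted mean of its per-subtype mean scores. Mean-of-means, rather
than a pooled record mean, prevents a heavily assayed subtype from
dominating. `subtype_correlation` reports Pearson and Spearman
coefficients per subtype pair with the shared-compound count, and leaves
coefficients absent below 3 shared compounds.

## The 60-variable validation row

Each record ("experimental fact") is encoded as exactly 60 features in
six families: 20 chemical descriptors (molecular weight, weighted QED,
Crippen logP, TPSA, H-bond donors/acceptors, rotatable bonds, ring and
atom counts, …), 14 assay variables (type and BAO format codes, assay
coverage, 11 description keyword flags), 10 target variables (target and
target-class codes, GPCR/subtype/enzyme-family flags), 6 taxonomy
variables (organism code, human/rat/mouse/mammal flags), 6
cell-line/tissue variables and 4 enumerated bookkeeping codes (standard
type, relation, units, assay enumeration). The composition honors the
stated six families and the count of 60; the identity of the original
variables is not public, so this schema is the package's own documented
stand-in. Categoricals are dictionary/integer encoded with sorted,
persisted dictionaries (random forests split on them directly); missing
categoricals encode as −1 and missing numerics as the fitted median. A
row is labeled active iff its compound's averaged measured score strictly
exceeds 4.0, the same constant used for hit calling, keeping training
labels and screening calls self-consistent.

## Negative augmentation

Melatonin-measured populations are nearly all active, so negatives are
constructed from external evidence: a compound is an eligible negative
when it is inactive in at least 10 *distinct* GPCR-class assays, where a
record is inactive if its comment contains "not active", its score is
below 4, or it is right-censored with bound below 4. Eligible compounds
are sampled once per pipeline invocation under a recorded seed; each
contributes one inactive row (encoded from its lexicographically first
inactive panel record) with placeholder activity score 0, far below any
active threshold so the regression target stays defined. The default
sample size preserves the reference class ratio of 60 000 negatives per
1 617 active compounds, scaled by the number of active compounds
actually present; when fewer compounds are eligible than requested, all
are used and a warning is emitted.

## Models and aggregation

The validation set is split 80/20 at the record level (seeded
permutation; sizes within one record of the fraction). Defaults: 100
trees, unlimited depth, √p features per split for classification and p/3
for regression, single-threaded for determinism; the seed is mandatory
and stored in the bundle together with the schema fingerprint, which is
checked before any prediction. Per compound, countRatio = active calls /
occasions in the set being scored (test set during evaluation, full
universe during screening), and the mean predicted score is the average
regression output. The evaluation report includes the regression
correlation both per record and per compound — the aggregation makes
either reading defensible — plus the confusion matrix, classifier AUROC
and the countRatio distribution stratified by true label.

## Screening and the combined score

A compound's final melatonin score is its measured averaged score
whenever one exists; the model only fills the gap, as
`countRatio × mean predicted score`. The product rule is a deliberate,
isolated choice (`combine_scores`): it damps compounds the classifier
calls active inconsistently while preserving the regression magnitude,
and can be swapped without touching the rest of the pipeline. Hits are
strict `score > 4`. Screening streams in configurable batches so the
record universe never has to fit in memory at once.

## Cardiovascular cross-filter

Assays are flagged cardiovascular when description or tissue contains
any configured keyword (defaults: heart, cardiac, aort, coronary,
arrhythmi, blood pressure, hypertens, vasoconstrict, vasodilat, atria,
ventric, vascular; the stem "aort" covers both "aorta" and "aortic").
The matched term is stored per assay so flagging is auditable. A CV hit
is one record with measured score > 4.5 in a flagged assay for a
compound with melatonin score > 4, both comparisons strict; the summary
counts distinct records, assays and molecules. Hits split into in-vivo
(explicit "in vivo" wording, or tissue without cell line) and in-vitro
tables, and export as a bipartite assay–molecule graph in which unnamed
molecules carry an `anonymous` attribute so renderers can hide raw
registry ids.

## Synthetic universe

The generator emulates the statistical structure of a ChEMBL export, not
its relational schema. Defaults were chosen once as the package's study
conditions: 2 000 compounds, 30 % truly melatonin-active, subtype latent
potencies multivariate normal with correlation 0.9 (active mean 7,
inactive mean 2, SD 1 on the −log10 molar scale, redrawn so planted
labels respect the threshold 4 exactly), measurement noise SD 0.5, unit
mixture 55 % nM / 30 % µM / 15 % µg/mL, 5 % right-censored records, 3 %
percent-inhibition readouts, 30 melatonin assays (10 per subtype), a
50-assay GPCR inactivity panel covering the unmeasured inactives (60 %
planted with ≥ 10 inactive assays), and 40 cardiovascular assays in
which 25 % of the actives are planted potent (score > 5.2). This yields
roughly 18 000 records and runs end to end in well under a minute on one
CPU — the scale at which the whole suite and the recovery checks are
exercised. Structures are drawn from a bundled list of 196 well-known
drug molecules so descriptors are computable and realistic.

What the generator does *not* emulate: chemical structure–activity
signal (structures are assigned cyclically, independent of the planted
label), assay-quality heterogeneity, inter-assay systematic offsets, and
documents/citations. Consequently a passing recovery test demonstrates
that the pipeline machinery — normalization, labeling, augmentation,
aggregation, precedence of measured scores, CV filtering — is correct,
and that the model exploits assay/target metadata; it does not
demonstrate QSAR-style generalization from chemistry alone, which on
real data depends on the descriptor–activity relationship. For the same
reason the held-out regression correlation on synthetic data is
informative but moderate, while worked tests of the learners themselves
use constructed feature tables with planted signal.

## Numerical choices and edge cases

Zero or negative concentrations, unknown units, and µg/mL without a
molecular weight yield no score, with a warning. Unit invariance holds
to 1e−9 on the score scale. Correlations on fewer than 3 points or
against a constant vector are reported as absent rather than NaN-ing
downstream. Ties in hit sorting break by compound id. All randomness
(generator, negative sampling, split, forests) derives from one seed;
repeated runs with the same config write byte-identical output tables.

## Known limitations

The keyword CV flag is a transparent stand-in for expert curation and
will over- or under-flag unusual assay descriptions. The product
combination rule for predicted scores is one of several defensible
choices. Real ChEMBL exports may carry additional unit spellings beyond
nM/µM/M/µg/mL; unrecognized units are skipped rather than guessed.
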