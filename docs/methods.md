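# Methods

This note records the modeling and numerical choices made in
`prp-variant`, the reasoning behind them, and their limits.

## Variant model and consequence calling

Variants are biallelic SNVs with 1-based genomic coordinates. Each gene
carries one canonical transcript (preference: explicit canonical tag,
then longest CDS, then lexicographic transcript id). CDS positions are
enumerated in translation order — for minus-strand transcripts from the
3'-most exon backwards, with alleles complemented — so consequence
calling is strand-symmetric by construction. The consequence rules are
applied in this order to the affected codon: `start_lost` (first codon
no longer translates to M), `stop_gained` (non-stop codon becomes
stop), `stop_lost` (stop codon becomes non-stop), `missense`
(amino-acid change), else `synonymous`; positions outside the CDS are
`non_coding`. Nonsynonymous = {missense, start_lost, stop_gained,
stop_lost}. The reference allele is checked against the genome and a
mismatch is an error, never a silent skip. Tests verify the caller
exhaustively against re-translation of the full mutated CDS.

## Features (34)

Four categories, in a fixed canonical order:

- **frequency (6)** — two population allele frequencies
  (`gnomAD_AFv2`, `gnomAD_AFv4`), codon usage of reference and
  alternate codon (`CFref`, `CFalt`), and neighbor preference
  frequencies (`NPFref`, `NPFalt`).
- **conservation (20)** — phyloP100/phyloP470/phastCons100/phastCons470
  aggregated as the mean over the allele position, the codon (3
  positions), the enclosing protein domain, and the gene; plus
  100-species alignment-column frequencies of the reference/alternate
  nucleotide (`m100_AFref/alt`) and amino acid (`m100_AAFref/alt`).
- **substitution (5)** — BLOSUM62, PAM250, Grantham distance, codon
  substitution rate (`codonST`), amino-acid substitution rate (`aaST`).
- **intolerance (3)** — `pLI`, `pRec`, `pNull`.

**NPF definition.** NPF is computed as the triplet frequency
normalized by the center-residue count:

    f(A_ijk) = n(A_ijk) / n(A_j)

where `n(A_ijk)` counts occurrences of the exact triplet *i-j-k* in the
reference proteome and `n(A_j)` counts all occurrences of the center
residue *j*. A center residue that occurs but never inside the queried
triplet therefore has frequency 0; a center residue that never occurs
gives a missing value. `NPFref` uses the reference amino acid as
center, `NPFalt` substitutes the alternate amino acid between the same
neighbors. Variants at protein termini (no flanking residue) and
alternate stop codons yield missing values. An alternative
normalization that sums the numerator over all contexts is degenerate
(it always yields 1) and was rejected; the oracle tests pin the
implemented definition.

**Missing values** are first-class: any unavailable annotation is a
missing cell, never silently zero. Preprocessing imputes allele
frequencies with 0 (absence from a population survey is evidence of
rarity) and all other features with the training median, then z-scores
using training mean and standard deviation (a zero standard deviation
maps to scale 1). The preprocessor is fit on training data only and is
refit inside every CV fold, so no validation information leaks.

## Curation

Training labels: (likely) pathogenic → TP, (likely) benign → TN, all
other clinical-significance values excluded. The primary filter also
requires a high review tier (practice guideline, expert panel, or
multiple submitters without conflicts) and a nonsynonymous consequence.
The rare-benign augmentation then samples, uniformly without
replacement under the curation seed, up to 3,000 single-submitter
benign variants with allele frequency **strictly below 3e-4** (the
first quartile of the training-TN allele frequencies motivates the
cutoff; a smaller eligible pool clamps with a warning). Test sets are
deduplicated against the training set and earlier test sets, records
with conflicting labels across sources are dropped from the test set
entirely, and a first-registration date cutoff (2022-01-01) keeps test
data temporally disjoint where dates exist; sources without review
status or dates skip only those filters.

## Training

Four interchangeable classifier families sit behind one interface:
XGBoost, LightGBM, scikit-learn histogram gradient boosting, and a
multilayer perceptron. The MLP search space uses a conditional
structure (hidden-layer widths sampled only for the chosen depth) and
maps its regularization search onto the `alpha` L2 penalty, since the
scikit-learn MLP has no dropout.

Hyperparameters are tuned with a hand-implemented univariate TPE
sampler: after a random startup phase, trials are split into the top
gamma = 0.25 ("good") and the rest; each parameter gets Parzen
Gaussian-mixture densities l(x) (good) and g(x) (bad) — with a flat
prior component and bandwidth (hi−lo)/√n — and the candidate maximizing
l(x)/g(x) among 24 seeded proposals is chosen. Integer and
log-uniform parameters transform into the appropriate metric;
categorical parameters use add-one-smoothed frequency ratios. A median
pruner cancels a trial whose running-mean fold AUC falls below the
median of completed trials' partial means at the same fold index, after
a warmup of 5 completed trials.

The objective is mean held-out AUC over a seeded stratified k-fold
split (k = 10 at protocol scale). Search-space sizes come in two
scales: `full` (100–2000 trees, depth ≤ 12) mirroring the protocol, and
`desk` (50–300 trees, depth ≤ 8) for laptop-scale runs and tests; both
are the package's own choices. The final model refits on the whole
training table and is serialized with its preprocessor, feature schema,
threshold and a data-hash fingerprint. Classification uses
score ≥ threshold → pathogenic (the boundary counts as pathogenic);
the default threshold is 0.5.

## Evaluation

All eight metrics are computed from first principles: accuracy,
precision, sensitivity, specificity, F1, MCC (any zero denominator
yields a missing value, never 0 or NaN), tie-corrected Mann–Whitney
AUC via rank sums, and step-wise AUPRC (precision summed against recall
increments at distinct score values, no interpolation). Missing scores
are excluded from every metric and reported as a missing rate, so tools
with different coverage are compared honestly. Allele-frequency strata
use five half-open bins [0,1e-4), [1e-4,1e-3), [1e-3,1e-2),
[1e-2,1e-1), [1e-1,1] (the last closed) — decade edges spanning the
rare-to-common range, with the extra sub-1e-4 bin because the rare
regime is the problem statement. Tool comparison accepts per-tool
thresholds and score directions ("lower = more pathogenic" tools are
negated).

## Interpretation

Attributions are Shapley values on the log-odds margin. Tree ensembles
use their exact tree-path decomposition (XGBoost `pred_contribs`,
LightGBM `pred_contrib`); other models use a seeded
permutation-sampling estimator against a background sample, whose
telescoping sum makes local additivity exact by construction. Exports:
`bar` (global mean |contribution|), `summary` (long table), `waterfall`
(per-variant, |contribution|-descending), `decision` (cumulative path
from base value to output with probability-scale conversion).

## Synthetic generators and their realism

- **Reference**: random CDSs (ATG start, no internal stops, terminal
  stop) laid on a toy chromosome with both strands used, written as
  FASTA/GFF3/protein FASTA. All SNV consequences on it are enumerable,
  giving an exhaustive caller oracle.
- **ClinVar-style VCF**: a planted composition of
  significance/review-status/AF-class/year cells drawn from real SNVs
  of the toy genome, so the curation outcome of every record is known
  in advance and recorded in a manifest. Registration dates, absent
  from real ClinVar VCFs, are emitted as a side table.
- **Resources**: conservation tracks are class-conditional normals with
  a +1.5σ mean shift at pathogenic positions (phastCons squashed into
  [0,1] by a logistic); alignment columns are drawn concordant with
  conservation; codon usage and constraint values come from Dirichlet
  draws; substitution tables cover all pairs. This captures the
  *direction* of real signals, not their correlation structure.
- **Tabular generator**: class-shifted unit normals on 6 of 34 features
  (two AF features and `NPFalt`, `m100_AAFalt`, `aaST` shifted down for
  pathogenic variants, `m100_AAFref` up; |shift| = 1.5σ). For m
  independent features with shift d the Bayes-optimal AUC is
  Φ(d·√m/√2), giving closed-form targets for recovery tests.

Problem sizes in tests and the acceptance script (n = 2000 tabular
rows, ~340 curated toy variants, 10 TPE trials, 10-fold CV) are chosen
to finish in minutes on one CPU while leaving the statistical
assertions comfortable margins.

## Limitations

- Synthetic features are conditionally independent given the class;
  real annotation features are strongly correlated (the Spearman matrix
  utility exists precisely because of that), so synthetic performance
  numbers say nothing about real-data performance.
- The toy genome has one transcript per gene; overlapping transcripts
  and splice-region effects are out of scope.
- The curation model treats clinical significance as flat strings;
  real submission records carry richer per-submitter structure.
- The TPE implementation is univariate (no parameter interactions in
  the sampler) and the pruner compares partial means only, which is
  standard but can prune slow-starting configurations.
- The permutation-sampling Shapley fallback scales linearly in
  permutations × features × background size; for wide backgrounds the
  tree route is strongly preferred.
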