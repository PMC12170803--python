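"""The 34-feature annotation engine.

Features fall into four categories:

* frequency (6): gnomAD allele frequencies (v2/v4 exomes), codon usage
  frequency of the reference and alternate codon (CFref/CFalt), and
  neighbor preference frequency of the reference and alternate residue in
  its flanking context (NPFref/NPFalt);
* conservation (20): phyloP (100-way, 470-way) and phastCons (100-way,
  470-way) at the allele, codon, domain and gene level, plus the
  reference/alternate nucleotide and amino-acid frequencies in 100-way
  multiple-alignment columns (m100_AFref/alt, m100_AAFref/alt);
* substitution (5): BLOSUM62, PAM250, Grantham, and the human-specific
  codon- and amino-acid substitution rates codonST/aaST;
* gene intolerance (3): pLI, pRec, pNull.

Missing values are first-class: every accessor returns ``None`` when a
resource does not cover the query, and imputation happens only inside the
fitted :class:`PreprocessingModel`.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from prp.resources import ResourceBundle, STANDARD_AA, TRACK_IDS, query_track
from prp.variants import CodingEffect, GenomicVariant, TranscriptModel, variant_key

logger = logging.getLogger(__name__)

_CONS_LEVELS = ("allele", "codon", "domain", "gene")

#: Canonical, versioned feature order. Models and preprocessors persist it.
FEATURE_NAMES = (
    # frequency
    "gnomAD_AFv2",
    "gnomAD_AFv4",
    "CFref",
    "CFalt",
    "NPFref",
    "NPFalt",
    # conservation: 4 tracks x 4 aggregation levels
    *(f"{t}_{lvl}" for t in TRACK_IDS for lvl in _CONS_LEVELS),
    "m100_AFref",
    "m100_AFalt",
    "m100_AAFref",
    "m100_AAFalt",
    # substitution
    "BLOSUM62",
    "PAM250",
    "Grantham",
    "codonST",
    "aaST",
    # gene intolerance
    "pLI",
    "pRec",
    "pNull",
)

FEATURE_CATEGORIES = {
    "frequency": FEATURE_NAMES[:6],
    "conservation": FEATURE_NAMES[6:26],
    "substitution": FEATURE_NAMES[26:31],
    "gene_intolerance": FEATURE_NAMES[31:34],
}

#: Features imputed with 0 (absence from gnomAD read as unobserved).
AF_FEATURES = ("gnomAD_AFv2", "gnomAD_AFv4")

assert len(FEATURE_NAMES) == 34


# ---------------------------------------------------------------------------
# Neighbor preference frequency
# ---------------------------------------------------------------------------

@dataclass
class NPFTable:
    """Amino-acid triplet counts from a reference proteome.

    ``frequency(i, j, k)`` returns n(A_ijk) / n(A_j): the count of the
    triplet with center j and neighbors (i, k), relative to the total count
    of residue j in the proteome. Residues with similar neighbor
    preferences substitute for one another more often, so a low frequency
    of the mutant residue in the reference context flags an unusual
    substitution.
    """

    triplet_counts: dict = field(default_factory=dict)
    center_counts: dict = field(default_factory=dict)

    def frequency(self, i: str, j: str, k: str) -> Optional[float]:
        n_j = self.center_counts.get(j, 0)
        if n_j == 0:
            return None
        return self.triplet_counts.get((i, j, k), 0) / n_j


def build_npf_table(proteome: dict) -> NPFTable:
    """Count every interior amino-acid triplet of every proteome sequence.

    Sequences containing letters outside the 20 standard amino acids are
    skipped with a warning (a trailing stop ``*`` is stripped first);
    sequences shorter than 3 contribute no triplets but still count
    centers.
    """
    if not proteome:
        raise ValueError("empty proteome")
    table = NPFTable()
    standard = set(STANDARD_AA)
    for name, seq in proteome.items():
        seq = seq.rstrip("*")
        if not set(seq) <= standard:
            warnings.warn(
                f"skipping proteome sequence {name!r}: non-standard residues"
            )
            continue
        for aa in seq:
            table.center_counts[aa] = table.center_counts.get(aa, 0) + 1
        for t in range(1, len(seq) - 1):
            trip = (seq[t - 1], seq[t], seq[t + 1])
            table.triplet_counts[trip] = table.triplet_counts.get(trip, 0) + 1
    if not table.center_counts:
        raise ValueError("proteome contains no usable sequences")
    return table


def npf_features(effect: CodingEffect, table: NPFTable) -> tuple:
    """(NPFref, NPFalt): triplet frequency of the reference and alternate
    residue in the reference flanking context.

    Missing at protein termini (no flanking residue) and for stop ('*')
    residues at the queried center.
    """
    prev_aa, next_aa = effect.prev_aa, effect.next_aa
    if prev_aa is None or next_aa is None:
        return None, None
    if prev_aa not in STANDARD_AA or next_aa not in STANDARD_AA:
        return None, None

    def f(center):
        if center not in STANDARD_AA:
            return None
        return table.frequency(prev_aa, center, next_aa)

    return f(effect.ref_aa), f(effect.alt_aa)


# ---------------------------------------------------------------------------
# Frequency / conservation / substitution accessors
# ---------------------------------------------------------------------------

def codon_usage_features(effect: CodingEffect, bundle: ResourceBundle) -> tuple:
    """(CFref, CFalt): codon usage frequency of the ref and alt codon."""
    return (
        bundle.codon_usage.get(effect.ref_codon),
        bundle.codon_usage.get(effect.alt_codon),
    )


def alignment_frequency(
    column: str, symbol: str, alphabet_size: int = 5
) -> Optional[float]:
    """Frequency of ``symbol`` in an alignment column, gaps removed.

    f(x) = n(x) / sum over the alphabet of n, where the denominator is the
    column length after removing '-' gaps. Empty columns yield missing.
    ``alphabet_size`` documents the alphabet (5 for DNA incl. N, 20 for
    protein); counting itself is symbol-exact.
    """
    stripped = column.replace("-", "")
    if not stripped:
        return None
    return stripped.count(symbol) / len(stripped)


def conservation_features(
    variant: GenomicVariant,
    effect: CodingEffect,
    transcript: TranscriptModel,
    bundle: ResourceBundle,
) -> dict:
    """The 16 track-by-level conservation features.

    Per track: allele = score at the variant position; codon = mean over
    the codon's three genomic positions; domain = mean over the genomic
    positions of every domain interval (codon coordinates) containing the
    variant's codon index, missing when no domain contains it; gene = mean
    over all CDS positions. Means skip positions the track does not cover.
    """
    cds_positions = transcript.cds_positions()
    gene = transcript.gene_id

    domain_positions: list = []
    for start, end in bundle.domain_intervals.get(gene, ()):
        if start <= effect.codon_index <= end:
            lo = (start - 1) * 3
            hi = min(end * 3, len(cds_positions))
            domain_positions.extend(cds_positions[lo:hi])

    out = {}
    for track_id in TRACK_IDS:
        def score(pos):
            return query_track(bundle, track_id, variant.chrom, pos)

        def mean_over(positions):
            vals = [s for s in map(score, positions) if s is not None]
            return float(np.mean(vals)) if vals else None

        out[f"{track_id}_allele"] = score(variant.pos)
        out[f"{track_id}_codon"] = mean_over(effect.codon_genomic_span)
        out[f"{track_id}_domain"] = (
            mean_over(domain_positions) if domain_positions else None
        )
        out[f"{track_id}_gene"] = mean_over(cds_positions)
    return out


def multiz_features(
    variant: GenomicVariant,
    effect: CodingEffect,
    transcript: TranscriptModel,
    bundle: ResourceBundle,
) -> dict:
    """Reference/alternate symbol frequencies in 100-way alignment columns.

    The nucleotide column is keyed by genomic position (genome-strand
    alleles); the amino-acid column by (gene, codon index), with the alt
    frequency read for the alternate residue in that same column.
    """
    out = {
        "m100_AFref": None,
        "m100_AFalt": None,
        "m100_AAFref": None,
        "m100_AAFalt": None,
    }
    nuc_col = bundle.nuc_columns.get((variant.chrom, variant.pos))
    if nuc_col is not None:
        out["m100_AFref"] = alignment_frequency(nuc_col, variant.ref, 5)
        out["m100_AFalt"] = alignment_frequency(nuc_col, variant.alt, 5)
    aa_col = bundle.aa_columns.get((transcript.gene_id, effect.codon_index))
    if aa_col is not None:
        if effect.ref_aa in STANDARD_AA:
            out["m100_AAFref"] = alignment_frequency(aa_col, effect.ref_aa, 20)
        if effect.alt_aa in STANDARD_AA:
            out["m100_AAFalt"] = alignment_frequency(aa_col, effect.alt_aa, 20)
    return out


def substitution_features(effect: CodingEffect, bundle: ResourceBundle) -> tuple:
    """(BLOSUM62, PAM250, Grantham, codonST, aaST) lookups.

    Amino-acid pairs involving '*' use the table when the key exists
    (BLOSUM62/PAM250 score stops), else missing.
    """
    aa_pair = (effect.ref_aa, effect.alt_aa)
    codon_pair = (effect.ref_codon, effect.alt_codon)
    return (
        bundle.blosum62.get(aa_pair),
        bundle.pam250.get(aa_pair),
        bundle.grantham.get(aa_pair),
        bundle.codon_st.get(codon_pair),
        bundle.aa_st.get(aa_pair),
    )


def intolerance_features(gene_id: str, bundle: ResourceBundle) -> tuple:
    """(pLI, pRec, pNull) for a gene; all missing when the gene is absent."""
    triple = bundle.constraint.get(gene_id)
    return triple if triple is not None else (None, None, None)


def assemble_features(
    variant: GenomicVariant,
    effect: CodingEffect,
    transcript: TranscriptModel,
    bundle: ResourceBundle,
    npf_table: Optional[NPFTable] = None,
) -> dict:
    """The full 34-entry feature mapping in canonical order.

    Missing values are ``None``; imputation is the preprocessor's job.
    Synonymous and non-coding effects are a caller error — curation must
    filter them first.
    """
    if effect.consequence not in ("missense", "start_lost", "stop_gained", "stop_lost"):
        raise ValueError(
            f"assemble_features requires a nonsynonymous effect, got "
            f"{effect.consequence}"
        )
    if npf_table is None:
        npf_table = build_npf_table(bundle.proteome) if bundle.proteome else NPFTable()

    key = variant_key(variant)
    cf_ref, cf_alt = codon_usage_features(effect, bundle)
    npf_ref, npf_alt = npf_features(effect, npf_table)
    blosum, pam, grantham, codon_st, aa_st = substitution_features(effect, bundle)
    pli, prec, pnull = intolerance_features(transcript.gene_id, bundle)

    vec = {
        "gnomAD_AFv2": bundle.af_v2.get(key),
        "gnomAD_AFv4": bundle.af_v4.get(key),
        "CFref": cf_ref,
        "CFalt": cf_alt,
        "NPFref": npf_ref,
        "NPFalt": npf_alt,
    }
    vec.update(conservation_features(variant, effect, transcript, bundle))
    vec.update(multiz_features(variant, effect, transcript, bundle))
    vec.update(
        {
            "BLOSUM62": blosum,
            "PAM250": pam,
            "Grantham": grantham,
            "codonST": codon_st,
            "aaST": aa_st,
            "pLI": pli,
            "pRec": prec,
            "pNull": pnull,
        }
    )
    return {name: vec[name] for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessingModel:
    """Fitted imputation + z-score parameters, persisted with the model.

    Allele-frequency features impute to 0 (absence from gnomAD is read as
    unobserved); every other feature imputes to the training-set median.
    Normalization is a z-score with the training mean/sd computed after
    imputation; a zero sd falls back to scale 1.
    """

    feature_names: tuple
    impute: dict
    center: dict
    scale: dict
    fingerprint: str

    @property
    def fitted(self) -> bool:
        return bool(self.center)


def _fingerprint(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(str(df.shape).encode())
    h.update(np.ascontiguousarray(df.to_numpy(dtype=float)).tobytes())
    return h.hexdigest()[:16]


def fit_preprocessor(feature_table: pd.DataFrame) -> PreprocessingModel:
    """Fit imputation and normalization parameters on the training split only."""
    df = feature_table.astype(float)
    impute, center, scale = {}, {}, {}
    for col in df.columns:
        if col in AF_FEATURES:
            impute[col] = 0.0
        else:
            med = df[col].median(skipna=True)
            impute[col] = 0.0 if pd.isna(med) else float(med)
        filled = df[col].fillna(impute[col])
        center[col] = float(filled.mean())
        sd = float(filled.std(ddof=0))
        scale[col] = sd if sd > 0 else 1.0
    return PreprocessingModel(
        feature_names=tuple(df.columns),
        impute=impute,
        center=center,
        scale=scale,
        fingerprint=_fingerprint(df.fillna(np.nan)),
    )


def apply_preprocessor(
    model: PreprocessingModel, feature_table: pd.DataFrame
) -> pd.DataFrame:
    """Impute then z-score with the stored parameters; never re-estimates."""
    if not model.fitted:
        raise ValueError("preprocessor has not been fitted")
    if tuple(feature_table.columns) != model.feature_names:
        raise ValueError(
            "feature columns do not match the fitted preprocessor schema"
        )
    df = feature_table.astype(float).copy()
    for col in df.columns:
        df[col] = (df[col].fillna(model.impute[col]) - model.center[col]) / model.scale[col]
    return df


def spearman_matrix(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlations between features.

    Ties are handled by average ranks; constant columns yield missing
    correlations for their pairs.
    """
    if len(feature_table) < 3:
        raise ValueError("need at least 3 rows for rank correlations")
    corr = feature_table.astype(float).corr(method="spearman", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    # a constant column has no rank variance: blank its off-diagonal entries
    for col in feature_table.columns:
        observed = feature_table[col].dropna()
        if observed.nunique() <= 1:
            corr.loc[col, :] = np.nan
            corr.loc[:, col] = np.nan
            corr.loc[col, col] = 1.0
    return corr
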