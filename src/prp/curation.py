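"""ClinVar-style dataset curation: filter, label, augment, dedup.

Training labels follow the clinical-significance consensus: (likely)
pathogenic records become true positives, (likely) benign records true
negatives, and everything else (uncertain significance, conflicting,
drug response, ...) is excluded. The primary filter additionally requires
a high review tier; the rare-benign augmentation then adds
single-submitter benign variants with allele frequency strictly below a
cutoff (default 3e-4, the first quartile of training-TN AFs in the source
data) to balance the classes in the low-AF range.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional

import numpy as np

from prp.variants import NSSNV_CONSEQUENCES

logger = logging.getLogger(__name__)

TP, TN = "TP", "TN"


def normalize_token(token: str) -> str:
    """Normalize a CLNSIG/CLNREVSTAT token: case, underscores, commas."""
    token = token.strip().lower().replace("_", " ")
    token = token.replace(",", " ")
    return re.sub(r"\s+", " ", token).strip()


#: Source-specific shorthand mapped onto the ClinVar-style tokens
#: (Humsavar "LP/P"/"LB/B", ClinGen assertion strings).
SIGNIFICANCE_ALIASES = {
    "lp/p": "pathogenic/likely pathogenic",
    "lb/b": "benign/likely benign",
}

DEFAULT_TP_SET = frozenset(
    {"pathogenic", "likely pathogenic", "pathogenic/likely pathogenic"}
)
DEFAULT_TN_SET = frozenset(
    {"benign", "likely benign", "benign/likely benign"}
)
DEFAULT_REVIEW_SET = frozenset(
    {
        "practice guideline",
        "reviewed by expert panel",
        "criteria provided multiple submitters no conflicts",
    }
)
AUGMENT_REVIEW_STATUS = "criteria provided single submitter"


@dataclass(frozen=True)
class ClinicalRecord:
    """One clinically asserted SNV, consequence-annotated."""

    key: tuple  # (chrom, pos, ref, alt)
    consequence: str
    clinical_significance: str
    review_status: Optional[str] = None
    af: Optional[float] = None
    first_registered: Optional[date] = None
    source: str = "clinvar"
    gene: Optional[str] = None


@dataclass
class CurationConfig:
    tp_set: frozenset = DEFAULT_TP_SET
    tn_set: frozenset = DEFAULT_TN_SET
    review_set: frozenset = DEFAULT_REVIEW_SET
    augment_size: int = 3000
    augment_af_cutoff: float = 3e-4
    augment_review_status: str = AUGMENT_REVIEW_STATUS
    seed: int = 0
    test_date_cutoff: date = date(2022, 1, 1)

    def __post_init__(self):
        if self.tp_set & self.tn_set:
            raise ValueError("TP and TN significance sets must be disjoint")
        if self.augment_size < 0:
            raise ValueError("augmentation size must be >= 0")


@dataclass(frozen=True)
class LabeledRecord:
    record: ClinicalRecord
    label: str  # TP | TN
    provenance: str  # "primary" | "augmentation"


@dataclass
class LabeledVariantSet:
    """Curated variants with TP/TN labels and per-record provenance."""

    records: list = field(default_factory=list)

    def __post_init__(self):
        keys = [lr.record.key for lr in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate variant keys in labeled set")

    def keys(self) -> set:
        return {lr.record.key for lr in self.records}

    def labels(self) -> dict:
        return {lr.record.key: lr.label for lr in self.records}

    def genes(self) -> list:
        return sorted(
            {lr.record.gene for lr in self.records if lr.record.gene is not None}
        )

    def counts(self) -> dict:
        out = {TP: 0, TN: 0}
        for lr in self.records:
            out[lr.label] += 1
        return out

    def __len__(self):
        return len(self.records)


def label_record(record: ClinicalRecord, config: CurationConfig) -> Optional[str]:
    """TP / TN / None(excluded) from the clinical-significance string."""
    sig = normalize_token(record.clinical_significance)
    sig = SIGNIFICANCE_ALIASES.get(sig, sig)
    if sig in config.tp_set:
        return TP
    if sig in config.tn_set:
        return TN
    return None


def primary_filter(
    records: Iterable[ClinicalRecord], config: CurationConfig
) -> LabeledVariantSet:
    """Consequence, significance and review-tier filter; dedup by key."""
    seen = set()
    out = []
    for rec in records:
        if rec.consequence not in NSSNV_CONSEQUENCES:
            continue
        label = label_record(rec, config)
        if label is None:
            continue
        status = normalize_token(rec.review_status or "")
        if status not in config.review_set:
            continue
        if rec.key in seen:
            continue
        seen.add(rec.key)
        out.append(LabeledRecord(rec, label, "primary"))
    return LabeledVariantSet(out)


def augment_rare_tn(
    records: Iterable[ClinicalRecord],
    config: CurationConfig,
    exclude_keys: Optional[set] = None,
) -> list:
    """Sample rare benign variants from the single-submitter tier.

    Eligible: labels TN, review status equals the augmentation tier, AF
    strictly below the cutoff, key not already selected. A uniform sample
    without replacement of size ``min(config.augment_size, pool)`` is drawn
    reproducibly under the config seed.
    """
    exclude_keys = exclude_keys or set()
    want = normalize_token(config.augment_review_status)
    pool, seen = [], set()
    for rec in records:
        if rec.key in exclude_keys or rec.key in seen:
            continue
        if rec.consequence not in NSSNV_CONSEQUENCES:
            continue
        if label_record(rec, config) != TN:
            continue
        if normalize_token(rec.review_status or "") != want:
            continue
        if rec.af is None or not rec.af < config.augment_af_cutoff:
            continue
        seen.add(rec.key)
        pool.append(rec)
    pool.sort(key=lambda r: r.key)
    n = min(config.augment_size, len(pool))
    if n < config.augment_size:
        warnings.warn(
            f"augmentation pool has only {len(pool)} eligible records, "
            f"requested {config.augment_size}"
        )
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(len(pool), size=n, replace=False) if n else []
    return [LabeledRecord(pool[i], TN, "augmentation") for i in sorted(idx)]


def build_training_set(
    records: Iterable[ClinicalRecord], config: CurationConfig
) -> LabeledVariantSet:
    """Primary filter plus rare-TN augmentation; disjoint by construction."""
    records = list(records)
    primary = primary_filter(records, config)
    augmented = augment_rare_tn(records, config, exclude_keys=primary.keys())
    return LabeledVariantSet(primary.records + augmented)


def first_quartile_af(tn_records: Iterable[ClinicalRecord]) -> float:
    """First quartile (linear interpolation) of TN allele frequencies.

    Used to sanity-check the augmentation AF cutoff against the data.
    """
    afs = [r.af for r in tn_records if r.af is not None]
    if len(afs) < 4:
        raise ValueError("need at least 4 TN records with AF present")
    return float(np.percentile(afs, 25, method="linear"))


def build_test_set(
    records: Iterable[ClinicalRecord],
    training_set: LabeledVariantSet,
    other_test_sets: Iterable[LabeledVariantSet] = (),
    config: CurationConfig = None,
) -> LabeledVariantSet:
    """Curate an independent test set.

    Applies the significance filter (and the review-tier filter for
    sources that carry a review status), drops keys present in the
    training set or any earlier test set, drops keys with conflicting
    labels across sources, and keeps only records first registered on or
    after the date cutoff (records without a date pass the date rule).
    """
    config = config or CurationConfig()
    taken = set(training_set.keys())
    for ts in other_test_sets:
        taken |= ts.keys()

    candidates = []
    for rec in records:
        if rec.consequence not in NSSNV_CONSEQUENCES:
            continue
        label = label_record(rec, config)
        if label is None:
            continue
        if rec.review_status is not None:
            if normalize_token(rec.review_status) not in config.review_set:
                continue
        if rec.first_registered is not None:
            if rec.first_registered < config.test_date_cutoff:
                continue
        if rec.key in taken:
            continue
        candidates.append(LabeledRecord(rec, label, "primary"))

    labels_by_key: dict = {}
    for lr in candidates:
        labels_by_key.setdefault(lr.record.key, set()).add(lr.label)
    conflicted = {k for k, ls in labels_by_key.items() if len(ls) > 1}

    seen = set()
    out = []
    for lr in candidates:
        if lr.record.key in conflicted or lr.record.key in seen:
            continue
        seen.add(lr.record.key)
        out.append(lr)
    return LabeledVariantSet(out)


def records_from_vcf(vcf_path, consequences: dict, dates: Optional[dict] = None,
                     afs: Optional[dict] = None, source: str = "clinvar") -> list:
    """Build ClinicalRecords from a ClinVar-style VCF.

    CLNSIG and CLNREVSTAT come from INFO; the consequence per variant key
    comes from the caller (``consequences``: key → consequence string, or
    key → (consequence, gene) tuples). Registration dates — absent from
    real ClinVar VCFs — and allele frequencies may be supplied as side
    tables keyed the same way (AF falls back to the INFO ``AF`` field).
    """
    from prp.variants import parse_variants, variant_key

    dates = dates or {}
    afs = afs or {}
    out = []
    for variant, info in parse_variants(vcf_path):
        key = variant_key(variant)
        ann = consequences.get(key)
        if ann is None:
            continue
        consequence, gene = ann if isinstance(ann, tuple) else (ann, None)
        sig = info.get("CLNSIG", "")
        status = info.get("CLNREVSTAT")
        if isinstance(sig, tuple):
            sig = ",".join(str(s) for s in sig)
        if isinstance(status, tuple):
            status = ",".join(str(s) for s in status)
        af = afs.get(key)
        if af is None:
            raw = info.get("AF")
            if isinstance(raw, tuple):
                raw = raw[0]
            af = float(raw) if raw is not None else None
        out.append(
            ClinicalRecord(
                key=key,
                consequence=consequence,
                clinical_significance=str(sig),
                review_status=str(status) if status is not None else None,
                af=af,
                first_registered=dates.get(key),
                source=source,
                gene=gene,
            )
        )
    return out
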