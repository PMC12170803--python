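"""Annotation resources behind the 34-feature engine.

Every resource is a strict, documented plain-text table so that synthetic
fixtures and real extracts (gnomAD, UCSC tracks, InterPro intervals,
constraint tables) are interchangeable. Conservation tracks are
per-position TSV rather than bigWig so fixtures stay hand-writable.

TSV dialects (tab-separated, ``#`` comment lines ignored):

===================  =======================================================
resource             columns
===================  =======================================================
codon_usage          codon, frequency (fraction or per-thousand; see config)
af (v2/v4)           chrom, pos, ref, alt, allele_frequency
conservation track   chrom, pos, score  (one file per track)
nuc_alignment        chrom, pos, column-string (gaps '-' allowed)
aa_alignment         gene, codon_index, column-string
domains              gene, codon_start, codon_end  (1-based inclusive)
gene_spans           gene, cds_length
codonST / aaST       from, to, rate
constraint           gene, pLI, pRec, pNull
===================  =======================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

TRACK_IDS = ("phyloP100", "phyloP470", "phastCons100", "phastCons470")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

MISSING = None


class ResourceValidationError(ValueError):
    """A resource file failed a load-time validation check."""


# Grantham (1974) physicochemical distances, upper triangle in the
# original row order; symmetric with zero diagonal.
_GRANTHAM_ORDER = "SRLPTAVGIFYCHQNKDEMW"
_GRANTHAM_UPPER = [
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],
    [194, 83, 99, 143, 85, 160, 122, 36, 37],
    [174, 154, 139, 202, 154, 170, 196, 215],
    [24, 68, 32, 81, 40, 87, 115],
    [46, 53, 61, 29, 101, 130],
    [94, 23, 42, 142, 174],
    [101, 56, 95, 110],
    [45, 160, 181],
    [126, 152],
    [67],
]


def grantham_matrix() -> dict:
    """The Grantham amino-acid distance matrix as a symmetric dict."""
    m = {}
    for a in _GRANTHAM_ORDER:
        m[(a, a)] = 0.0
    for i, a in enumerate(_GRANTHAM_ORDER[:-1]):
        for off, d in enumerate(_GRANTHAM_UPPER[i]):
            b = _GRANTHAM_ORDER[i + 1 + off]
            m[(a, b)] = float(d)
            m[(b, a)] = float(d)
    return m


def _biopython_matrix(name: str) -> dict:
    arr = substitution_matrices.load(name)
    alphabet = arr.alphabet
    out = {}
    for a in alphabet:
        for b in alphabet:
            out[(a, b)] = float(arr[a, b])
    return out


def _check_symmetric(m: dict, name: str):
    for (a, b), v in m.items():
        if m.get((b, a)) != v:
            raise ResourceValidationError(
                f"{name} matrix asymmetric at ({a},{b}): {v} != {m.get((b, a))}"
            )


@dataclass
class ResourceBundle:
    """All annotation resources, indexed for O(1) query."""

    proteome: dict = field(default_factory=dict)
    codon_usage: dict = field(default_factory=dict)
    af_v2: dict = field(default_factory=dict)
    af_v4: dict = field(default_factory=dict)
    tracks: dict = field(default_factory=dict)  # track_id -> {(chrom,pos): score}
    nuc_columns: dict = field(default_factory=dict)  # (chrom,pos) -> str
    aa_columns: dict = field(default_factory=dict)  # (gene, codon_index) -> str
    domain_intervals: dict = field(default_factory=dict)  # gene -> [(start,end)] codons
    gene_spans: dict = field(default_factory=dict)  # gene -> CDS length
    blosum62: dict = field(default_factory=dict)
    pam250: dict = field(default_factory=dict)
    grantham: dict = field(default_factory=dict)
    codon_st: dict = field(default_factory=dict)
    aa_st: dict = field(default_factory=dict)
    constraint: dict = field(default_factory=dict)  # gene -> (pLI, pRec, pNull)


def _rows(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _load_codon_usage(path, scale: str) -> dict:
    usage = {}
    for lineno, parts in _rows(path):
        try:
            codon, freq = parts[0].upper(), float(parts[1])
        except (IndexError, ValueError) as exc:
            raise ResourceValidationError(
                f"{path}:{lineno}: malformed codon-usage row"
            ) from exc
        usage[codon] = freq / 1000.0 if scale == "per_thousand" else freq
    if len(usage) != 64:
        raise ResourceValidationError(
            f"{path}: codon usage must cover all 64 codons, got {len(usage)}"
        )
    total = sum(usage.values())
    if abs(total - 1.0) > 1e-6:
        raise ResourceValidationError(
            f"{path}: codon usage sums to {total}, expected 1"
        )
    return usage


def _load_af(path) -> dict:
    table = {}
    for lineno, parts in _rows(path):
        try:
            chrom, pos, ref, alt, af = parts[:5]
            pos = int(pos)
            af = float(af)
        except (IndexError, ValueError) as exc:
            raise ResourceValidationError(
                f"{path}:{lineno}: malformed AF row"
            ) from exc
        if not 0.0 <= af <= 1.0:
            raise ResourceValidationError(
                f"{path}:{lineno}: AF {af} outside [0,1]"
            )
        table[(chrom, pos, ref, alt)] = af
    return table


def _load_track(path, track_id: str) -> dict:
    bounded = track_id.startswith("phastCons")
    track = {}
    for lineno, parts in _rows(path):
        try:
            chrom, pos, score = parts[0], int(parts[1]), float(parts[2])
        except (IndexError, ValueError) as exc:
            raise ResourceValidationError(
                f"{path}:{lineno}: malformed track row"
            ) from exc
        if bounded and not 0.0 <= score <= 1.0:
            raise ResourceValidationError(
                f"{path}:{lineno}: phastCons score {score} outside [0,1]"
            )
        track[(chrom, pos)] = score
    return track


def _load_pair_table(path, upper: bool = True) -> dict:
    table = {}
    for lineno, parts in _rows(path):
        try:
            a, b, rate = parts[0], parts[1], float(parts[2])
        except (IndexError, ValueError) as exc:
            raise ResourceValidationError(
                f"{path}:{lineno}: malformed substitution row"
            ) from exc
        if upper:
            a, b = a.upper(), b.upper()
        table[(a, b)] = rate
    return table


def _load_constraint(path) -> dict:
    table = {}
    for lineno, parts in _rows(path):
        try:
            gene = parts[0]
            pli, prec, pnull = (float(x) for x in parts[1:4])
        except (IndexError, ValueError) as exc:
            raise ResourceValidationError(
                f"{path}:{lineno}: malformed constraint row"
            ) from exc
        total = pli + prec + pnull
        if not (1 - 1e-3) <= total <= (1 + 1e-3):
            raise ResourceValidationError(
                f"{path}:{lineno}: pLI+pRec+pNull = {total}, not a simplex"
            )
        table[gene] = (pli, prec, pnull)
    return table


def _load_columns(path, key_is_gene: bool) -> dict:
    cols = {}
    for lineno, parts in _rows(path):
        try:
            key = (parts[0], int(parts[1]))
            col = parts[2]
        except (IndexError, ValueError) as exc:
            raise ResourceValidationError(
                f"{path}:{lineno}: malformed alignment-column row"
            ) from exc
        cols[key] = col
    return cols


def _load_intervals(path) -> dict:
    out: dict = {}
    for lineno, parts in _rows(path):
        try:
            gene, start, end = parts[0], int(parts[1]), int(parts[2])
        except (IndexError, ValueError) as exc:
            raise ResourceValidationError(
                f"{path}:{lineno}: malformed domain row"
            ) from exc
        if start > end:
            raise ResourceValidationError(
                f"{path}:{lineno}: interval start > end"
            )
        out.setdefault(gene, []).append((start, end))
    return out


def _load_spans(path) -> dict:
    out = {}
    for lineno, parts in _rows(path):
        try:
            out[parts[0]] = int(parts[1])
        except (IndexError, ValueError) as exc:
            raise ResourceValidationError(
                f"{path}:{lineno}: malformed gene-span row"
            ) from exc
    return out


def load_bundle(config: dict) -> ResourceBundle:
    """Load every resource named in ``config`` into an indexed bundle.

    ``config`` maps resource names to file paths; it may also be a path to
    a YAML file with the same mapping. Missing optional resources are
    allowed — the corresponding features become missing values downstream.
    Recognized keys: ``proteome_fasta``, ``codon_usage`` (+
    ``codon_usage_scale``: ``fraction`` | ``per_thousand``), ``af_v2``,
    ``af_v4``, ``track_<id>`` for the four conservation tracks,
    ``nuc_alignment``, ``aa_alignment``, ``domains``, ``gene_spans``,
    ``codon_st``, ``aa_st``, ``constraint``, ``grantham`` (optional
    override of the embedded table).
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            loaded = yaml.safe_load(fh)
        base = Path(config).parent
        config = {
            k: (v if k.endswith("_scale") else str(base / v))
            for k, v in loaded.items()
        }

    bundle = ResourceBundle(
        blosum62=_biopython_matrix("BLOSUM62"),
        pam250=_biopython_matrix("PAM250"),
        grantham=grantham_matrix(),
    )

    if "proteome_fasta" in config:
        bundle.proteome = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(config["proteome_fasta"]), "fasta")
        }
    if "codon_usage" in config:
        scale = config.get("codon_usage_scale", "fraction")
        bundle.codon_usage = _load_codon_usage(config["codon_usage"], scale)
    if "af_v2" in config:
        bundle.af_v2 = _load_af(config["af_v2"])
    if "af_v4" in config:
        bundle.af_v4 = _load_af(config["af_v4"])
    for track_id in TRACK_IDS:
        key = f"track_{track_id}"
        if key in config:
            bundle.tracks[track_id] = _load_track(config[key], track_id)
    if "nuc_alignment" in config:
        bundle.nuc_columns = _load_columns(config["nuc_alignment"], False)
    if "aa_alignment" in config:
        bundle.aa_columns = _load_columns(config["aa_alignment"], True)
    if "domains" in config:
        bundle.domain_intervals = _load_intervals(config["domains"])
    if "gene_spans" in config:
        bundle.gene_spans = _load_spans(config["gene_spans"])
    if "codon_st" in config:
        bundle.codon_st = _load_pair_table(config["codon_st"])
    if "aa_st" in config:
        bundle.aa_st = _load_pair_table(config["aa_st"])
    if "constraint" in config:
        bundle.constraint = _load_constraint(config["constraint"])
    if "grantham" in config:
        bundle.grantham = _load_pair_table(config["grantham"])

    for name, matrix in (
        ("BLOSUM62", bundle.blosum62),
        ("PAM250", bundle.pam250),
        ("Grantham", bundle.grantham),
    ):
        _check_symmetric(matrix, name)

    manifest = {
        "proteome": len(bundle.proteome),
        "codon_usage": len(bundle.codon_usage),
        "af_v2": len(bundle.af_v2),
        "af_v4": len(bundle.af_v4),
        "tracks": {k: len(v) for k, v in bundle.tracks.items()},
        "nuc_columns": len(bundle.nuc_columns),
        "aa_columns": len(bundle.aa_columns),
        "domains": sum(len(v) for v in bundle.domain_intervals.values()),
        "constraint": len(bundle.constraint),
    }
    logger.info("loaded resource bundle: %s", manifest)
    return bundle


def query_track(
    bundle: ResourceBundle, track_id: str, chrom: str, pos: int
) -> Optional[float]:
    """Per-position conservation score, or None where the track is silent."""
    if track_id not in TRACK_IDS:
        raise ValueError(f"unknown track {track_id!r}; expected one of {TRACK_IDS}")
    track = bundle.tracks.get(track_id)
    if track is None:
        return MISSING
    return track.get((chrom, pos), MISSING)
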