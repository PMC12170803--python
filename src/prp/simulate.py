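"""Synthetic inputs for the whole pipeline, generated at toy scale.

The generators stand in for the real resources (ClinVar VCFs, gnomAD AF
tables, UCSC conservation tracks, InterPro domains, constraint tables) so
every stage runs offline. Class-conditional choices mirror the biology the
real data shows: pathogenic variants are skewed rare (AF log-uniform over
[1e-6, 1e-3] vs [1e-5, 0.5] for benign) and sit at more conserved
positions (a configurable mean shift on every conservation track), so a
model trained on the synthetic data should recover the same feature
directionality — lower AF and higher reference-allele conservation
pointing toward pathogenicity.

All generators are deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from prp.features import FEATURE_NAMES
from prp.resources import STANDARD_AA, TRACK_IDS
from prp.variants import (
    COMPLEMENT,
    GenomicVariant,
    TranscriptModel,
    call_coding_effect,
    variant_key,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"

#: Default informative features and their signed class shifts (pathogenic
#: minus benign, in within-class standard deviations) for the tabular
#: generator. Signs follow the observed directionality: rarer alleles,
#: lower mutant-residue context frequencies and lower substitution rates
#: for pathogenic variants; higher reference-residue alignment frequency.
DEFAULT_SIGNAL = {
    "gnomAD_AFv2": -1.5,
    "gnomAD_AFv4": -1.5,
    "NPFalt": -1.5,
    "m100_AAFref": 1.5,
    "m100_AAFalt": -1.5,
    "aaST": -1.5,
}


@dataclass
class SimulationConfig:
    n_genes: int = 8
    cds_length_range: tuple = (150, 300)  # bounds, forced to multiples of 3
    seed: int = 0
    # ClinVar-style planting
    af_pathogenic: tuple = (1e-6, 1e-3)  # log-uniform bounds
    af_benign: tuple = (1e-5, 0.5)
    conservation_effect: float = 1.5  # mean shift at pathogenic positions
    alignment_depth: int = 30
    # tabular generator
    signal: dict = field(default_factory=lambda: dict(DEFAULT_SIGNAL))
    n_per_class: int = 1000
    missing_rate: float = 0.0

    def __post_init__(self):
        lo, hi = self.cds_length_range
        if lo < 9 or hi < lo:
            raise ValueError("cds_length_range must be sane and >= 9")


@dataclass
class SyntheticReference:
    genome: dict  # chrom -> sequence string
    transcripts: dict  # gene id -> TranscriptModel
    proteome: dict  # gene id -> amino-acid sequence (no stop)

    def write(self, out_dir) -> dict:
        """Write genome FASTA, transcript GFF3 and proteome FASTA."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        genome_path = out_dir / "genome.fa"
        with open(genome_path, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        gff_path = out_dir / "transcripts.gff3"
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene, tx in sorted(self.transcripts.items()):
                lo = min(s for s, _ in tx.exons)
                hi = max(e for _, e in tx.exons)
                fh.write(
                    f"{tx.chrom}\tsim\tgene\t{lo}\t{hi}\t.\t{tx.strand}\t.\t"
                    f"ID={gene}\n"
                )
                fh.write(
                    f"{tx.chrom}\tsim\tmRNA\t{lo}\t{hi}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={gene};tag=canonical\n"
                )
                for i, (s, e) in enumerate(tx.exons):
                    fh.write(
                        f"{tx.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{tx.strand}\t0\t"
                        f"ID={tx.transcript_id}.cds{i};Parent={tx.transcript_id}\n"
                    )
        prot_path = out_dir / "proteome.fa"
        with open(prot_path, "w") as fh:
            for gene, seq in sorted(self.proteome.items()):
                fh.write(f">{gene}\n{seq}\n")
        return {
            "genome_fasta": str(genome_path),
            "gff3": str(gff_path),
            "proteome_fasta": str(prot_path),
        }


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG start, no internal stops, one terminal stop codon."""
    non_stop = [
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in STOP_CODONS
    ]
    interior = [
        non_stop[i] for i in rng.integers(0, len(non_stop), size=n_codons - 2)
    ]
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    return "ATG" + "".join(interior) + stop


def simulate_reference(config: SimulationConfig) -> SyntheticReference:
    """Toy genome + canonical transcripts + proteome, both strands used."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cds_length_range
    chrom = "chr1"
    genome_parts = []
    pos = 1
    transcripts, proteome = {}, {}
    for g in range(config.n_genes):
        gap = int(rng.integers(20, 50))
        genome_parts.append(
            "".join(_BASES[i] for i in rng.integers(0, 4, size=gap))
        )
        pos += gap
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        cds = _random_cds(rng, n_codons)
        strand = "+" if g % 2 == 0 else "-"
        genomic = (
            cds
            if strand == "+"
            else "".join(COMPLEMENT[b] for b in reversed(cds))
        )
        gene = f"gene{g + 1}"
        transcripts[gene] = TranscriptModel(
            gene_id=gene,
            transcript_id=f"{gene}.t1",
            chrom=chrom,
            strand=strand,
            exons=((pos, pos + len(cds) - 1),),
        )
        proteome[gene] = str(Seq(cds).translate()).rstrip("*")
        genome_parts.append(genomic)
        pos += len(cds)
    return SyntheticReference(
        genome={chrom: "".join(genome_parts)},
        transcripts=transcripts,
        proteome=proteome,
    )


def enumerate_snvs(reference: SyntheticReference) -> dict:
    """All possible CDS SNVs bucketed by consequence.

    Returns consequence -> list of (GenomicVariant, gene id).
    """
    buckets: dict = {}
    for gene, tx in sorted(reference.transcripts.items()):
        for p in sorted(tx.cds_positions()):
            ref = reference.genome[tx.chrom][p - 1]
            for alt in _BASES:
                if alt == ref:
                    continue
                v = GenomicVariant(tx.chrom, p, ref, alt)
                eff = call_coding_effect(v, tx, reference.genome)
                buckets.setdefault(eff.consequence, []).append((v, gene))
    return buckets


# ---------------------------------------------------------------------------
# Resource tables
# ---------------------------------------------------------------------------

def simulate_resources(
    config: SimulationConfig,
    reference: SyntheticReference,
    out_dir,
    pathogenic_positions: Optional[set] = None,
) -> dict:
    """Write every annotation resource as TSV; return a load_bundle config.

    Conservation tracks are class-conditional normals: positions in
    ``pathogenic_positions`` are shifted up by ``config.conservation_effect``
    (phastCons values are squashed into [0,1] through a logistic).
    Alignment columns are sampled concordant with conservation — conserved
    positions keep the reference symbol with higher probability.
    """
    rng = np.random.default_rng(config.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pathogenic_positions = pathogenic_positions or set()

    paths = {}

    # codon usage: Dirichlet over the 64 codons
    codons = sorted(
        a + b + c for a in _BASES for b in _BASES for c in _BASES
    )
    usage = rng.dirichlet(np.full(64, 5.0))
    paths["codon_usage"] = out_dir / "codon_usage.tsv"
    with open(paths["codon_usage"], "w") as fh:
        for codon, f in zip(codons, usage):
            fh.write(f"{codon}\t{f:.10f}\n")

    # conservation tracks + nucleotide alignment columns
    track_rows = {t: [] for t in TRACK_IDS}
    nuc_rows = []
    chrom = next(iter(reference.genome))
    conserved_frac = {}
    for gene, tx in sorted(reference.transcripts.items()):
        for p in sorted(tx.cds_positions()):
            shift = (
                config.conservation_effect
                if (chrom, p) in pathogenic_positions
                else 0.0
            )
            base_cons = rng.normal(0.0, 1.0) + shift
            for t in TRACK_IDS:
                raw = base_cons + rng.normal(0.0, 0.3)
                if t.startswith("phastCons"):
                    score = 1.0 / (1.0 + np.exp(-raw))
                else:
                    score = raw
                track_rows[t].append((chrom, p, score))
            # concordant alignment column: conserved positions keep ref
            p_ref = 1.0 / (1.0 + np.exp(-(base_cons + 1.0)))
            conserved_frac[(chrom, p)] = p_ref
            ref = reference.genome[chrom][p - 1]
            col = "".join(
                ref
                if rng.random() < p_ref
                else "ACGTN"[int(rng.integers(5))]
                for _ in range(config.alignment_depth)
            )
            nuc_rows.append((chrom, p, col))
    for t in TRACK_IDS:
        paths[f"track_{t}"] = out_dir / f"{t}.tsv"
        with open(paths[f"track_{t}"], "w") as fh:
            for chrom_, p, s in track_rows[t]:
                fh.write(f"{chrom_}\t{p}\t{s:.6f}\n")
    paths["nuc_alignment"] = out_dir / "nuc_alignment.tsv"
    with open(paths["nuc_alignment"], "w") as fh:
        for chrom_, p, col in nuc_rows:
            fh.write(f"{chrom_}\t{p}\t{col}\n")

    # amino-acid alignment columns per codon
    paths["aa_alignment"] = out_dir / "aa_alignment.tsv"
    with open(paths["aa_alignment"], "w") as fh:
        for gene, tx in sorted(reference.transcripts.items()):
            prot = reference.proteome[gene]
            positions = tx.cds_positions()
            for ci, aa in enumerate(prot, 1):
                p_mid = positions[(ci - 1) * 3 + 1]
                p_ref = conserved_frac.get((tx.chrom, p_mid), 0.7)
                col = "".join(
                    aa
                    if rng.random() < p_ref
                    else STANDARD_AA[int(rng.integers(20))]
                    for _ in range(config.alignment_depth)
                )
                fh.write(f"{gene}\t{ci}\t{col}\n")

    # domains: 1-2 codon intervals per gene
    paths["domains"] = out_dir / "domains.tsv"
    with open(paths["domains"], "w") as fh:
        for gene, tx in sorted(reference.transcripts.items()):
            n_codons = tx.cds_length // 3
            for _ in range(int(rng.integers(1, 3))):
                start = int(rng.integers(1, max(2, n_codons - 5)))
                end = min(n_codons, start + int(rng.integers(3, 10)))
                fh.write(f"{gene}\t{start}\t{end}\n")

    # gene spans
    paths["gene_spans"] = out_dir / "gene_spans.tsv"
    with open(paths["gene_spans"], "w") as fh:
        for gene, tx in sorted(reference.transcripts.items()):
            fh.write(f"{gene}\t{tx.cds_length}\n")

    # substitution rate tables: every single-base codon pair / all aa pairs
    paths["codon_st"] = out_dir / "codon_st.tsv"
    with open(paths["codon_st"], "w") as fh:
        for c1 in codons:
            for i in range(3):
                for b in _BASES:
                    if b == c1[i]:
                        continue
                    c2 = c1[:i] + b + c1[i + 1 :]
                    rate = 10 ** rng.uniform(-6, -2)
                    fh.write(f"{c1}\t{c2}\t{rate:.3e}\n")
    paths["aa_st"] = out_dir / "aa_st.tsv"
    alphabet = STANDARD_AA + "*"
    with open(paths["aa_st"], "w") as fh:
        for a in alphabet:
            for b in alphabet:
                if a == b:
                    continue
                rate = 10 ** rng.uniform(-6, -2)
                fh.write(f"{a}\t{b}\t{rate:.3e}\n")

    # gene constraint simplex
    paths["constraint"] = out_dir / "constraint.tsv"
    with open(paths["constraint"], "w") as fh:
        for gene in sorted(reference.transcripts):
            pli, prec, pnull = rng.dirichlet((1.0, 1.0, 1.0))
            fh.write(f"{gene}\t{pli:.8f}\t{prec:.8f}\t{pnull:.8f}\n")

    ref_paths = reference.write(out_dir)
    cfg = {k: str(v) for k, v in paths.items()}
    cfg["codon_usage_scale"] = "fraction"
    cfg["proteome_fasta"] = ref_paths["proteome_fasta"]
    return cfg


# ---------------------------------------------------------------------------
# ClinVar-style VCF with planted composition
# ---------------------------------------------------------------------------

def default_plant() -> list:
    """Planted composition cells: the curation outcome of each is known.

    Each cell: n records with a given significance, review status, AF class
    ('rare' = below 3e-4, 'common' = above) and registration year.
    """
    return [
        dict(n=60, sig="Pathogenic", status="criteria_provided,_multiple_submitters,_no_conflicts", af="rare", year=2021),
        dict(n=20, sig="Likely_pathogenic", status="reviewed_by_expert_panel", af="rare", year=2023),
        dict(n=50, sig="Benign", status="criteria_provided,_multiple_submitters,_no_conflicts", af="common", year=2021),
        dict(n=20, sig="Likely_benign", status="practice_guideline", af="common", year=2023),
        dict(n=40, sig="Likely_benign", status="criteria_provided,_single_submitter", af="rare", year=2021),
        dict(n=10, sig="Benign", status="criteria_provided,_single_submitter", af="common", year=2021),
        dict(n=10, sig="Uncertain_significance", status="criteria_provided,_multiple_submitters,_no_conflicts", af="rare", year=2021),
        dict(n=10, sig="Conflicting_interpretations_of_pathogenicity", status="criteria_provided,_multiple_submitters,_no_conflicts", af="rare", year=2021),
    ]


def simulate_clinvar_vcf(
    config: SimulationConfig,
    reference: SyntheticReference,
    out_dir,
    plant: Optional[list] = None,
    filename: str = "clinvar.vcf",
) -> dict:
    """Write a ClinVar-style VCF with an exactly planted composition.

    Variants are real SNVs against the toy genome (the VCF ref allele
    always matches). Pathogenic cells draw from the stop_gained/missense/
    start_lost/stop_lost buckets; synonymous planting is supported via
    ``sig`` cells with ``consequence='synonymous'``. Returns a manifest of
    planted truths (per-cell keys and expected labels) and writes a
    registration-date side table, since real ClinVar VCFs carry no
    first-submission date.
    """
    rng = np.random.default_rng(config.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plant = plant if plant is not None else default_plant()

    buckets = enumerate_snvs(reference)
    ns_pool = []
    for cons in ("missense", "stop_gained", "start_lost", "stop_lost"):
        ns_pool.extend((v, g, cons) for v, g in buckets.get(cons, []))
    syn_pool = [(v, g, "synonymous") for v, g in buckets.get("synonymous", [])]
    rng.shuffle(ns_pool)
    rng.shuffle(syn_pool)

    records = []
    manifest: dict = {"cells": []}
    used = set()

    def draw(pool_name):
        pool = syn_pool if pool_name == "synonymous" else ns_pool
        while pool:
            v, g, cons = pool.pop()
            if variant_key(v) not in used:
                used.add(variant_key(v))
                return v, g, cons
        raise RuntimeError("exhausted SNV pool; enlarge the toy genome")

    def sample_af(af_class):
        if af_class == "rare":
            lo, hi = 1e-6, 2.9e-4
        else:
            lo, hi = 3.1e-4, 0.5
        return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))

    for cell in plant:
        cell_keys = []
        pool_name = cell.get("consequence", "nonsynonymous")
        for _ in range(cell["n"]):
            v, g, cons = draw(
                "synonymous" if pool_name == "synonymous" else "ns"
            )
            af = sample_af(cell["af"])
            reg = date(cell["year"], int(rng.integers(1, 13)), int(rng.integers(1, 28)))
            records.append(
                dict(
                    variant=v,
                    gene=g,
                    consequence=cons,
                    sig=cell["sig"],
                    status=cell["status"],
                    af=af,
                    date=reg,
                )
            )
            cell_keys.append(list(variant_key(v)))
        manifest["cells"].append({**{k: v for k, v in cell.items()}, "keys": cell_keys})

    records.sort(key=lambda r: (r["variant"].chrom, r["variant"].pos,
                                r["variant"].ref, r["variant"].alt))

    vcf_path = out_dir / filename
    chrom = next(iter(reference.genome))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f"##contig=<ID={chrom},length={len(reference.genome[chrom])}>\n"
        )
        fh.write('##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical significance">\n')
        fh.write('##INFO=<ID=CLNREVSTAT,Number=1,Type=String,Description="Review status">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, r in enumerate(records):
            v = r["variant"]
            info = (
                f"CLNSIG={r['sig']};CLNREVSTAT={r['status']};"
                f"AF={r['af']:.6e};GENE={r['gene']}"
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\tsim{i}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"
            )

    dates_path = out_dir / (filename.replace(".vcf", "") + "_dates.tsv")
    with open(dates_path, "w") as fh:
        for r in records:
            v = r["variant"]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{r['date'].isoformat()}\n"
            )

    manifest["vcf"] = str(vcf_path)
    manifest["dates"] = str(dates_path)
    manifest["consequences"] = {
        "|".join(map(str, variant_key(r["variant"]))): [r["consequence"], r["gene"]]
        for r in records
    }
    with open(out_dir / (filename.replace(".vcf", "") + "_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def load_dates(dates_path) -> dict:
    """Read the registration-date side table into key → date."""
    out = {}
    with open(dates_path) as fh:
        for line in fh:
            chrom, pos, ref, alt, iso = line.rstrip("\n").split("\t")
            out[(chrom, int(pos), ref, alt)] = date.fromisoformat(iso)
    return out


# ---------------------------------------------------------------------------
# Direct tabular harness
# ---------------------------------------------------------------------------

def simulate_feature_table(config: SimulationConfig):
    """Labeled 34-feature table with controlled class separation.

    Informative features (``config.signal``: name → signed shift in sigma
    units) are drawn from class-shifted unit normals; the other features
    are class-independent noise. With per-feature shift d on m independent
    features the Bayes-optimal AUC is Phi(d * sqrt(m) / sqrt(2)).
    Missingness is applied uniformly at ``config.missing_rate`` per cell.
    Returns (DataFrame with the 34 canonical columns, label array).
    """
    import pandas as pd

    unknown = set(config.signal) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown signal features: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed + 3)
    n = 2 * config.n_per_class
    labels = np.array([1] * config.n_per_class + [0] * config.n_per_class)
    perm = rng.permutation(n)
    labels = labels[perm]
    data = {}
    for name in FEATURE_NAMES:
        base = rng.normal(0.0, 1.0, size=n)
        shift = config.signal.get(name, 0.0)
        data[name] = base + shift * labels
    df = pd.DataFrame(data, columns=list(FEATURE_NAMES))
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        df = df.mask(mask)
    return df, labels
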