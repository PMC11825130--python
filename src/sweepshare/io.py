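"""Standard-format I/O: VCF, BED, GFF3+FASTA, and provenance-stamped TSV.

Coordinate conventions are centralized here: VCF and GFF3 are 1-based
inclusive per their standards; BED and all internal region coordinates
are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .scan import HaplotypeMatrix, QualityMask
from .regions import SweepRegion, SweepRegionSet

ANCESTRAL_REF = "A"
DERIVED_ALT = "T"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(hap: HaplotypeMatrix, path, sample_prefix: str = "ind") -> None:
    """Write phased biallelic VCF with an AA (ancestral allele) INFO tag.

    Haplotypes are paired into diploid phased genotypes; n_hap must be
    even. REF is the ancestral allele.
    """
    if hap.n_hap % 2:
        raise ValueError("VCF export pairs haplotypes into diploids; n_hap must be even")
    n_ind = hap.n_hap // 2
    samples = [f"{sample_prefix}{i + 1}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=sweepshare-{__version__}\n")
        fh.write(f"##contig=<ID={hap.chrom},length={hap.L}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(hap.n_sites):
            col = hap.derived[:, j]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_ind))
            fh.write(
                f"{hap.chrom}\t{hap.positions[j]}\t.\t{ANCESTRAL_REF}\t{DERIVED_ALT}"
                f"\t.\tPASS\tAA={ANCESTRAL_REF}\tGT\t{gts}\n"
            )


def read_vcf(path, L: int | None = None) -> HaplotypeMatrix:
    """Read a biallelic phased VCF into a haplotype matrix.

    Derived state is the allele differing from AA when the tag is present,
    otherwise the ALT allele. Multi-chromosome files are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    positions: list[int] = []
    columns: list[np.ndarray] = []
    chrom = None
    contig_len = None
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            parts = dict(
                kv.split("=") for kv in line[len("##contig=<"):-1].split(",") if "=" in kv
            )
            contig_len = int(parts.get("length", 0)) or None
    for var in vcf:
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("read_vcf handles a single chromosome per file")
        if len(var.ALT) != 1:
            raise ValueError(f"{path}: site {var.POS} is not biallelic")
        aa = var.INFO.get("AA")
        alleles = [var.REF] + var.ALT
        gts = np.array([g[:2] for g in var.genotypes], dtype=int).reshape(-1)
        if aa is not None and aa == var.ALT[0]:
            derived = (gts == 0).astype(np.int8)
        else:
            derived = (gts == 1).astype(np.int8)
        positions.append(var.POS)
        columns.append(derived)
    if chrom is None:
        raise ValueError(f"{path}: no variant records")
    length = L or contig_len or (max(positions) if positions else 1)
    return HaplotypeMatrix(
        chrom=chrom,
        L=int(length),
        positions=np.array(positions, dtype=np.int64),
        derived=np.column_stack(columns),
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed_mask(path, chrom: str) -> QualityMask:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    df = df[df["chrom"].astype(str) == chrom].sort_values("start")
    return QualityMask(
        chrom=chrom,
        starts=df["start"].to_numpy(np.int64),
        ends=df["end"].to_numpy(np.int64),
    )


def write_regions_bed(regions: SweepRegionSet, path) -> None:
    """BED6: name = region id, score = peak fitted value scaled to [0, 1000]."""
    rows = list(regions)
    peak_max = max((r.peak_fitted_value for r in rows), default=1.0) or 1.0
    with open(path, "w") as fh:
        for i, r in enumerate(rows):
            score = int(round(1000 * max(0.0, r.peak_fitted_value) / peak_max))
            name = f"{regions.population or 'region'}_{i + 1}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t.\n")


def read_regions_bed(path, population: str = "", subspecies: str = "") -> SweepRegionSet:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    regions = [
        SweepRegion(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            peak_bp=(int(r.start) + int(r.end)) / 2,
            peak_fitted_value=float(r.score) / 1000.0,
            population=population, subspecies=subspecies,
        )
        for r in df.itertuples(index=False)
    ]
    return SweepRegionSet(regions, population=population, subspecies=subspecies)


# ---------------------------------------------------------------------------
# GFF3 + FASTA -> spliced CDS records
# ---------------------------------------------------------------------------


def load_cds_records(fasta_path, gff3_path) -> list[dict]:
    """Extract spliced, phase-adjusted CDS records for degeneracy calling.

    Returns records consumable by :func:`sweepshare.mk.classify_degeneracy`:
    transcript, chrom, strand, seq (transcript orientation), and the
    1-based genomic position of every base in 5'->3' transcript order.
    """
    import gffutils
    from pyfaidx import Fasta

    from .mk import reverse_complement

    fasta = Fasta(str(fasta_path))
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_parent: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id or "cds"])
        for parent in parents:
            by_parent.setdefault(parent, []).append(cds)
    records = []
    for parent, parts in sorted(by_parent.items()):
        strand = parts[0].strand
        chrom = parts[0].seqid
        parts = sorted(parts, key=lambda c: c.start)
        seq_fwd = "".join(str(fasta[chrom][c.start - 1: c.end]) for c in parts)
        pos_fwd = np.concatenate(
            [np.arange(c.start, c.end + 1, dtype=np.int64) for c in parts]
        )
        if strand == "-":
            seq = reverse_complement(seq_fwd)
            pos = pos_fwd[::-1]
            phase_part = sorted(parts, key=lambda c: c.end, reverse=True)[0]
        else:
            seq = seq_fwd
            pos = pos_fwd
            phase_part = parts[0]
        phase = phase_part.frame
        offset = int(phase) if phase not in (None, ".", "") else 0
        seq = seq[offset:]
        pos = pos[offset:]
        trailing = len(seq) % 3
        if trailing:
            seq = seq[: len(seq) - trailing]
            pos = pos[: len(pos) - trailing]
        records.append(
            {"transcript": parent, "chrom": chrom, "strand": strand,
             "seq": seq.upper(), "genomic_positions": pos}
        )
    return records


# ---------------------------------------------------------------------------
# provenance-stamped TSV
# ---------------------------------------------------------------------------


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, seed: int | None = None,
              config: dict | None = None) -> None:
    """TSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sweepshare {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
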