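"""Genome, region and variant I/O with a single coordinate convention.

All coordinates inside the package are 0-based, half-open; BED shares this
convention, GFF3 (1-based, inclusive) and VCF (1-based POS) are converted at
the file boundary. Sequences are uppercased on read and any IUPAC ambiguity
code other than N is mapped to N (reference assemblies contain sparse
ambiguity codes; model code simply skips N-containing windows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from ._kmers import decode, encode, revcomp_codes

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class Genome:
    """Named DNA sequences over {A,C,G,T,N}, stored as uint8 code arrays."""

    def __init__(self, records: Iterable[tuple[str, str | np.ndarray]]):
        self._records: dict[str, np.ndarray] = {}
        for name, seq in records:
            if name in self._records:
                raise ValueError(f"duplicate record name: {name!r}")
            arr = seq if isinstance(seq, np.ndarray) else encode(seq.upper())
            self._records[name] = np.asarray(arr, dtype=np.uint8)

    @property
    def names(self) -> list[str]:
        return list(self._records)

    @property
    def total_length(self) -> int:
        return sum(len(a) for a in self._records.values())

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __len__(self) -> int:
        return len(self._records)

    def codes(self, name: str) -> np.ndarray:
        return self._records[name]

    def length(self, name: str) -> int:
        return len(self._records[name])

    def sequence(self, name: str, start: int = 0, end: int | None = None,
                 strand: str = "+") -> str:
        """Sequence slice; strand '-' returns the reverse complement."""
        arr = self._records[name][start:end]
        if strand == "-":
            arr = revcomp_codes(arr)
        return decode(arr)

    def base(self, name: str, pos: int) -> str:
        return decode(self._records[name][pos : pos + 1])

    def subset(self, names: Sequence[str]) -> "Genome":
        return Genome((n, self._records[n]) for n in names)

    def gc_fraction(self, name: str) -> float:
        """G+C over A+C+G+T (N excluded)."""
        a = self._records[name]
        acgt = np.count_nonzero(a < 4)
        if acgt == 0:
            return float("nan")
        gc = np.count_nonzero((a == 1) | (a == 2))
        return gc / acgt


@dataclass(frozen=True)
class Region:
    """0-based half-open genomic interval carrying a feature label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic SNV; pos is 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    allele_frequency: float | None = None

    def __post_init__(self):
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not an SNV: {self.ref}->{self.alt}")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    up = seq.upper()
    bad = set(up) - set("ACGTN")
    if bad:
        raise ValueError(f"characters outside ACGTN: {sorted(bad)}")
    return up.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-)FASTA into a Genome.

    Non-ACGTN characters are mapped to N; the number of such characters is
    logged as a warning. Duplicate record names or an empty file are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        arr = encode(seq)
        raw_n = seq.count("N")
        mapped = int(np.count_nonzero(arr == 4)) - raw_n
        n_mapped += mapped
        records.append((rec.id, arr))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if n_mapped:
        logger.warning("%s: %d non-ACGTN characters mapped to N", path, n_mapped)
    genome = Genome(records)
    return genome


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.names:
            fh.write(f">{name}\n")
            seq = genome.sequence(name)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_regions(path: str | Path, fmt: str = "bed",
                 genome: Genome | None = None) -> list[Region]:
    """Read BED4+ (0-based half-open) or GFF3 (converted) region files.

    With a genome supplied, regions extending past their record are errors.
    """
    fmt = fmt.lower()
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"unknown region format: {fmt}")
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 3:
                        raise ValueError("fewer than 3 columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                else:
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 columns")
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    label = fields[2]
                region = Region(chrom, start, end, label)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
            if genome is not None:
                if region.chrom not in genome:
                    raise ValueError(
                        f"{path}:{lineno}: unknown record {region.chrom!r}")
                if region.end > genome.length(region.chrom):
                    raise ValueError(
                        f"{path}:{lineno}: region beyond end of {region.chrom}")
            regions.append(region)
    return regions


def write_regions(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions as BED4."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def read_biallelic_snvs(path: str | Path, genome: Genome | None = None
                        ) -> list[VariantRecord]:
    """Read a VCF, keeping only bi-allelic single-nucleotide variants.

    Records with multi-base REF/ALT, more than one ALT allele, or symbolic
    alleles are dropped (INDEL/multi-allelic filtering). When a genome is
    supplied, records whose REF disagrees with the genome are dropped with a
    warning. Allele frequency is taken from the AF INFO field when present.
    The VCF FILTER column is ignored.
    """
    kept: list[VariantRecord] = []
    n_total = n_ref_mismatch = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            n_total += 1
            alts = rec.alts or ()
            if len(alts) != 1:
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if len(ref) != 1 or len(alt) != 1:
                continue
            if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
                continue
            pos = rec.pos - 1
            if genome is not None:
                if rec.chrom not in genome or pos >= genome.length(rec.chrom):
                    n_ref_mismatch += 1
                    continue
                if genome.base(rec.chrom, pos) != ref:
                    n_ref_mismatch += 1
                    continue
            af = rec.info.get("AF")
            if af is not None:
                af = float(af[0] if isinstance(af, tuple) else af)
            kept.append(VariantRecord(rec.chrom, pos, ref, alt, af))
    if n_ref_mismatch:
        logger.warning("%s: %d records dropped (REF mismatch with genome)",
                       path, n_ref_mismatch)
    logger.info("%s: kept %d of %d records as bi-allelic SNVs",
                path, len(kept), n_total)
    return kept


def write_vcf(variants: Iterable[VariantRecord], path: str | Path,
              genome: Genome | None = None) -> None:
    """Write SNVs as minimal VCF 4.2 (with AF INFO where present)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        if genome is not None:
            for name in genome.names:
                fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = "." if v.allele_frequency is None else f"AF={v.allele_frequency:.6g}"
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\n")
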