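"""Genome sequence/annotation data model, standard-format I/O and in-silico PCR.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open ``[start, end)``.  User-facing
output follows the format contracts: GFF3 and report text are 1-based
inclusive, BED6 is 0-based half-open.  ``transcript_length`` works on the
1-based inclusive coordinates that appear in publications and RACE reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
PRIMER_BASES = set("ACGT")


class GenomeFormatError(ValueError):
    """Raised for malformed or inconsistent genome/annotation inputs."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open, stranded genomic interval."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        """(start, end) in the 1-based inclusive convention of reports."""
        return self.start + 1, self.end


@dataclass(frozen=True)
class GeneFeature:
    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"  # CDS | sRNA | other
    translation: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.locus_tag}: bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_tag}: bad strand {self.strand!r}")
        if self.translation is not None:
            nt = self.end - self.start
            # annotated CDSs may or may not include the stop codon
            if len(self.translation) not in (nt // 3, nt // 3 - 1):
                raise ValueError(
                    f"{self.locus_tag}: translation length {len(self.translation)} "
                    f"inconsistent with CDS span {nt} nt"
                )

    @property
    def interval(self) -> Interval:
        return Interval(self.contig_id, self.start, self.end, self.strand)


@dataclass
class GenomeRecord:
    """One contig with its gene features; the coordinate ground truth."""

    contig_id: str
    sequence: str
    circular: bool = False
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise GenomeFormatError(f"invalid bases in sequence: {sorted(bad)}")
        for f in self.features:
            if f.contig_id != self.contig_id:
                raise GenomeFormatError(
                    f"feature {f.locus_tag} on unknown contig {f.contig_id!r}"
                )
            if f.end > len(self.sequence):
                raise GenomeFormatError(
                    f"feature {f.locus_tag} extends past contig end "
                    f"({f.end} > {len(self.sequence)})"
                )
        self.features.sort(key=lambda f: (f.start, f.end, f.locus_tag))

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_tag(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(f"locus_tag {locus_tag!r} not found in {self.contig_id}")

    def proteome(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS" and f.translation]


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValueError(f"{self.name}: {label} primer shorter than 10 nt")
            bad = set(p) - PRIMER_BASES
            if bad:
                raise ValueError(f"{self.name}: {label} primer has bad bases {sorted(bad)}")


# ---------------------------------------------------------------------------
# I/O


def _validate_gff_lines(gff_path: Path) -> None:
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise GenomeFormatError(
                    f"{gff_path}: malformed GFF line {lineno}: expected 9 columns"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise GenomeFormatError(
                    f"{gff_path}: malformed GFF line {lineno}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise GenomeFormatError(
                    f"{gff_path}: malformed GFF line {lineno}: bad coordinates {start}..{end}"
                )


_KIND_BY_FEATURETYPE = {
    "CDS": "CDS",
    "ncRNA": "sRNA",
    "sRNA": "sRNA",
}


def read_genome(
    fasta_path,
    gff_path,
    protein_fasta=None,
    circular: bool = False,
) -> GenomeRecord:
    """Read a single-contig FASTA plus GFF3 annotation into a GenomeRecord.

    GFF3 1-based inclusive coordinates are converted to internal 0-based
    half-open.  Translations, when wanted, come from a companion protein
    FASTA keyed by locus_tag.  Contig ids are taken verbatim (accessions
    are never normalized).
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise GenomeFormatError(f"{fasta_path}: no FASTA records")
    if len(records) > 1:
        raise GenomeFormatError(
            f"{fasta_path}: expected a single contig, found {len(records)}"
        )
    contig_id = records[0].id
    sequence = str(records[0].seq).upper()

    translations: dict[str, str] = {}
    if protein_fasta is not None:
        for rec in SeqIO.parse(str(protein_fasta), "fasta"):
            translations[rec.id] = str(rec.seq).upper()

    _validate_gff_lines(gff_path)
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    features = []
    for feat in db.all_features():
        kind = _KIND_BY_FEATURETYPE.get(feat.featuretype)
        if kind is None:
            kind = "other"
        if feat.featuretype == "region":
            continue
        if feat.seqid != contig_id:
            raise GenomeFormatError(
                f"{gff_path}: feature on unknown contig {feat.seqid!r} "
                f"(FASTA contig is {contig_id!r})"
            )
        tag = feat.attributes.get("locus_tag", feat.attributes.get("ID", [feat.id]))[0]
        features.append(
            GeneFeature(
                locus_tag=tag,
                contig_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                kind=kind,
                translation=translations.get(tag),
            )
        )
    return GenomeRecord(contig_id, sequence, circular=circular, features=features)


def write_genome_fasta(genome: GenomeRecord, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.contig_id}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i : i + width] + "\n")


def write_gff3(features: Iterable[GeneFeature], path, header_extra: str | None = None) -> None:
    """Write features as GFF3 (1-based inclusive)."""
    type_by_kind = {"CDS": "CDS", "sRNA": "ncRNA", "other": "misc_feature"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header_extra:
            fh.write(f"#!{header_extra}\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "ryhbkit",
                        type_by_kind.get(f.kind, "misc_feature"),
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.locus_tag};locus_tag={f.locus_tag}",
                    ]
                )
                + "\n"
            )


def write_protein_fasta(features: Iterable[GeneFeature], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for f in features:
            if f.translation:
                fh.write(f">{f.locus_tag}\n")
                for i in range(0, len(f.translation), width):
                    fh.write(f.translation[i : i + width] + "\n")


def write_bed6(intervals: Iterable[tuple[Interval, str, float]], path,
               header_extra: str | None = None) -> None:
    """Write (interval, name, score) triples as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"#{header_extra}\n")
        for iv, name, score in intervals:
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Sequence operations


def extract_interval(genome: GenomeRecord, iv: Interval) -> str:
    """Strand-correct sequence of an interval; '-' returns the reverse complement.

    On circular genomes the interval may run past the contig end (wrap-around).
    """
    n = len(genome.sequence)
    if iv.contig_id != genome.contig_id:
        raise ValueError(f"interval on unknown contig {iv.contig_id!r}")
    if 0 <= iv.start and iv.end <= n:
        s = genome.sequence[iv.start : iv.end]
    elif genome.circular:
        if len(iv) > n:
            raise ValueError("interval longer than the circular contig")
        start = iv.start % n
        end = start + len(iv)
        if end <= n:
            s = genome.sequence[start:end]
        else:
            s = genome.sequence[start:] + genome.sequence[: end - n]
    else:
        raise ValueError(
            f"interval [{iv.start}, {iv.end}) out of range on linear contig of length {n}"
        )
    return s if iv.strand == "+" else reverse_complement(s)


def transcript_length(start_1based: int, end_1based: int) -> int:
    """Transcript length in nt from 1-based inclusive boundary coordinates.

    This is the arithmetic used for RACE-mapped transcript boundaries:
    length = end - start + 1.
    """
    if start_1based > end_1based:
        raise ValueError(f"start {start_1based} > end {end_1based}")
    return end_1based - start_1based + 1


def _find_sites(seq: str, primer: str, max_mismatch: int) -> list[int]:
    """Start positions where `primer` matches `seq` with <= max_mismatch.

    'N' in the genome never matches a primer base.
    """
    if max_mismatch == 0:
        sites = []
        i = seq.find(primer)
        while i != -1:
            sites.append(i)
            i = seq.find(primer, i + 1)
        return sites
    sites = []
    k = len(primer)
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mm = sum(1 for a, b in zip(window, primer) if a != b or a == "N")
        if mm <= max_mismatch:
            sites.append(i)
    return sites


def insilico_pcr(
    genome: GenomeRecord,
    primers: PrimerPair,
    max_product: int,
    max_mismatch: int = 0,
) -> list[tuple[Interval, int]]:
    """Predict PCR amplicons from exact (default) primer binding sites.

    A product forms between a forward-primer site and a downstream
    reverse-primer site on the opposite strand, within ``max_product``.
    Product length includes both primers.  Results are sorted by contig,
    then 5' coordinate.
    """
    if max_product <= len(primers.forward) + len(primers.reverse):
        raise ValueError("max_product must exceed the summed primer lengths")
    seq = genome.sequence
    products = []
    # amplicon read on the plus strand: forward primer on +, reverse on -
    f_sites = _find_sites(seq, primers.forward, max_mismatch)
    r_rc_sites = _find_sites(seq, reverse_complement(primers.reverse), max_mismatch)
    for p in f_sites:
        for q in r_rc_sites:
            end = q + len(primers.reverse)
            length = end - p
            if q >= p and length <= max_product and length >= max(
                len(primers.forward), len(primers.reverse)
            ):
                products.append((Interval(genome.contig_id, p, end, "+"), length))
    # amplicon read on the minus strand: forward primer on -, reverse on +
    r_sites = _find_sites(seq, primers.reverse, max_mismatch)
    f_rc_sites = _find_sites(seq, reverse_complement(primers.forward), max_mismatch)
    for p in r_sites:
        for q in f_rc_sites:
            end = q + len(primers.forward)
            length = end - p
            if q >= p and length <= max_product and length >= max(
                len(primers.forward), len(primers.reverse)
            ):
                products.append((Interval(genome.contig_id, p, end, "-"), length))
    products.sort(key=lambda t: (t[0].contig_id, t[0].start, t[0].end, t[0].strand))
    return products


def write_pcr_tsv(products: list[tuple[Interval, int]], path,
                  header_extra: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"#{header_extra}\n")
        fh.write("contig\tstart_1based\tend_1based\tstrand\tproduct_bp\n")
        for iv, length in products:
            s1, e1 = iv.to_1based()
            fh.write(f"{iv.contig_id}\t{s1}\t{e1}\t{iv.strand}\t{length}\n")
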