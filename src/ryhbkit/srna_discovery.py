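"""Synteny-anchored discovery of an unannotated sRNA homolog.

The procedure mirrors how an unannotated small RNA can be found when
whole-gene BLAST and covariance-model searches fail: locate the anchor
gene whose neighborhood carries the sRNA in related genomes, take the
intergenic region immediately downstream of the anchor, and search it
for the conserved sRNA "core" (the segment carrying the mRNA-pairing
sequence and the Hfq site) by local alignment on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from ._align import local_align_codes, render_gapped
from .genome_model import (
    GeneFeature,
    GenomeRecord,
    Interval,
    extract_interval,
    reverse_complement,
)
from .orthology import AlignmentResult

NT_ALPHABET = "ACGTN"
_NT_INDEX = {c: i for i, c in enumerate(NT_ALPHABET)}


def nt_matrix(match: float, mismatch: float) -> np.ndarray:
    """Match/mismatch substitution table over ACGTN; N never matches."""
    m = np.full((5, 5), mismatch)
    for i in range(4):
        m[i, i] = match
    m[4, :] = mismatch
    m[:, 4] = mismatch
    return m


def encode_nt(seq: str) -> np.ndarray:
    codes = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        codes[i] = _NT_INDEX.get(c, 4)
    return codes


@dataclass(frozen=True)
class CoreModel:
    """The conserved sRNA core and the alignment scoring used to find it."""

    core_sequence: str
    min_score: float = 40.0
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self):
        if len(self.core_sequence) < 20:
            raise ValueError("core sequence shorter than 20 nt")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


@dataclass
class SrnaCandidate:
    locus: Interval
    core_alignment: AlignmentResult
    anchor_locus: str
    upstream_flank: str = ""


def default_core_sequence() -> str:
    """The packaged default core sequence.

    This fixture is a synthetic stand-in constructed by the package
    authors (see data/ryhb_core_synthetic.fasta); real analyses should
    supply a core extracted from an alignment of known ryhB homologs.
    """
    text = resources.files("ryhbkit.data").joinpath("ryhb_core_synthetic.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


def downstream_intergenic(
    genome: GenomeRecord, anchor: GeneFeature, max_len: int
) -> Interval:
    """Intergenic interval immediately 3' of the anchor on its coding strand.

    Extends to the nearer of the next annotated feature boundary (either
    strand) or ``max_len``.
    """
    if max_len < 50:
        raise ValueError("max_len must be >= 50")
    if anchor not in genome.features:
        raise ValueError(f"anchor {anchor.locus_tag} does not belong to the genome")
    n = len(genome.sequence)
    if anchor.strand == "+":
        start = anchor.end
        end = min(start + max_len, n)
        for f in genome.features:
            if f.start >= anchor.end and f is not anchor:
                end = min(end, f.start)
                break  # features are sorted by start
        if end <= start:
            raise ValueError(
                f"no downstream bases after {anchor.locus_tag} on a linear contig"
            )
        return Interval(genome.contig_id, start, end, "+")
    else:
        end = anchor.start
        start = max(end - max_len, 0)
        for f in reversed(genome.features):
            if f.end <= anchor.start and f is not anchor:
                start = max(start, f.end)
                break
        if end <= start:
            raise ValueError(
                f"no downstream bases after {anchor.locus_tag} on a linear contig"
            )
        return Interval(genome.contig_id, start, end, "-")


def _map_hit_to_genome(
    region_iv: Interval, ss: int, se: int, hit_on_annotated_strand: bool
) -> Interval:
    """Map a [ss, se) hit on the (possibly reverse-complemented) region
    sequence back to plus-strand genome coordinates."""
    if region_iv.strand == "+":
        if hit_on_annotated_strand:
            return Interval(region_iv.contig_id, region_iv.start + ss,
                            region_iv.start + se, "+")
        return Interval(region_iv.contig_id, region_iv.end - se,
                        region_iv.end - ss, "-")
    else:
        if hit_on_annotated_strand:
            return Interval(region_iv.contig_id, region_iv.end - se,
                            region_iv.end - ss, "-")
        return Interval(region_iv.contig_id, region_iv.start + ss,
                        region_iv.start + se, "+")


def find_core_homolog(
    region_seq: str, region_iv: Interval, core: CoreModel, anchor_locus: str = ""
) -> Optional[SrnaCandidate]:
    """Best local alignment of the core against the region, both strands.

    The region's annotated strand is tried first and wins score ties.
    Returns None when the best score is below ``core.min_score``.
    """
    if len(region_seq) < len(core.core_sequence) / 2:
        raise ValueError("region shorter than half the core length")
    sub = nt_matrix(core.match, core.mismatch)
    core_codes = encode_nt(core.core_sequence)
    results = []
    for on_annotated, seq in (
        (True, region_seq),
        (False, reverse_complement(region_seq)),
    ):
        score, qs, qe, ss, se, moves = local_align_codes(
            core_codes, encode_nt(seq), sub, core.gap_open, core.gap_extend
        )
        results.append((score, on_annotated, seq, qs, qe, ss, se, moves))
    # annotated strand listed first, so a tie keeps it
    best = max(results, key=lambda r: r[0])
    score, on_annotated, seq, qs, qe, ss, se, moves = best
    if score < core.min_score or not moves:
        return None
    top, bot = render_gapped(core.core_sequence, seq, moves)
    aln = AlignmentResult(
        score=score,
        identity=sum(1 for x, y in zip(top, bot) if x == y and x != "-") / len(top),
        query_interval=(qs, qe),
        subject_interval=(ss, se),
        aligned_query=top,
        aligned_subject=bot,
    )
    locus = _map_hit_to_genome(region_iv, ss, se, on_annotated)
    return SrnaCandidate(locus=locus, core_alignment=aln, anchor_locus=anchor_locus)


def discover_srna(
    query_genome: GenomeRecord,
    anchor_locus: str,
    core: CoreModel,
    max_len: int = 1000,
    flank_len: int = 100,
) -> Optional[SrnaCandidate]:
    """Full synteny-anchored discovery: anchor -> downstream region -> core hit.

    Attaches ``flank_len`` nt of sequence immediately 5' of the candidate
    (on the candidate's strand) for promoter/Fur-box scanning.
    """
    anchor = query_genome.feature_by_tag(anchor_locus)  # KeyError if absent
    region_iv = downstream_intergenic(query_genome, anchor, max_len)
    region_seq = extract_interval(query_genome, region_iv)
    cand = find_core_homolog(region_seq, region_iv, core, anchor_locus)
    if cand is None:
        return None
    n = len(query_genome.sequence)
    if cand.locus.strand == "+":
        fs = max(cand.locus.start - flank_len, 0)
        if fs < cand.locus.start:
            cand.upstream_flank = extract_interval(
                query_genome, Interval(query_genome.contig_id, fs, cand.locus.start, "+")
            )
    else:
        fe = min(cand.locus.end + flank_len, n)
        if fe > cand.locus.end:
            cand.upstream_flank = extract_interval(
                query_genome, Interval(query_genome.contig_id, cand.locus.end, fe, "-")
            )
    return cand


def find_all_core_homologs(
    region_seq: str, region_iv: Interval, core: CoreModel, anchor_locus: str = ""
) -> list[SrnaCandidate]:
    """All above-threshold, non-overlapping core hits (greedy best-first).

    Supports tandem-duplicate loci; the default pipeline uses only the
    single best candidate.
    """
    hits = []
    masked = region_seq
    while True:
        cand = find_core_homolog(masked, region_iv, core, anchor_locus)
        if cand is None:
            return hits
        hits.append(cand)
        # index of the hit on the annotated-strand region sequence
        if region_iv.strand == "+":
            s = cand.locus.start - region_iv.start
        else:
            s = region_iv.end - cand.locus.end
        e = s + len(cand.locus)
        masked = masked[:s] + "N" * (e - s) + masked[e:]


def render_candidate_report(cand: SrnaCandidate) -> str:
    s1, e1 = cand.locus.to_1based()
    aln = cand.core_alignment
    pairing = "".join(
        "|" if x == y and x != "-" else " "
        for x, y in zip(aln.aligned_query, aln.aligned_subject)
    )
    return (
        f"sRNA candidate on {cand.locus.contig_id}:{s1}-{e1} ({cand.locus.strand})\n"
        f"anchor: {cand.anchor_locus}\n"
        f"core alignment score {aln.score:g}, identity {aln.identity:.1%}\n"
        f"core    {aln.aligned_query}\n"
        f"        {pairing}\n"
        f"locus   {aln.aligned_subject}\n"
    )
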