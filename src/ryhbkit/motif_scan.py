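"""Fur-box consensus scanning with mismatch tolerance.

The Fur repressor binds a 19-bp inverted-repeat consensus
(GATAATGATAATCATTATC); a promoter window is called a Fur box when it
matches at least ``min_matches`` of the 19 consensus bases (the
operational criterion used for bacterial sRNA promoters, typically
15/19).  Offsets are reported relative to the transcription start site
(TSS): the base immediately 5' of the TSS is position -1, and a window
occupying upstream bases 26..44 is printed as offsets -44 to -26.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome_model import GenomeRecord, Interval, reverse_complement
from .srna_discovery import encode_nt

FUR_BOX_CONSENSUS = "GATAATGATAATCATTATC"


@dataclass(frozen=True)
class FurBoxModel:
    consensus: str = FUR_BOX_CONSENSUS
    min_matches: int = 15
    scan_both_strands: bool = True

    def __post_init__(self):
        if len(self.consensus) != 19:
            raise ValueError("consensus must be exactly 19 nt")
        if not 0 <= self.min_matches <= 19:
            raise ValueError("min_matches must be in [0, 19]")


@dataclass(frozen=True)
class FurBoxHit:
    offset_start: int  # 5'-most window base relative to the TSS (-1 = adjacent)
    offset_end: int
    strand_relative: str  # "same" | "opposite"
    matches: int
    window: str = ""


@dataclass(frozen=True)
class Promoter:
    """Upstream sequence, 5'->3' on the transcript strand, ending at the
    base immediately before the TSS."""

    sequence: str
    tss_genome_coord: Optional[int] = None
    promoter_id: str = "promoter"

    def __post_init__(self):
        if len(self.sequence) < 19:
            raise ValueError("promoter shorter than 19 nt")


def count_matches(window: str, consensus: str) -> int:
    """Number of identical bases between two 19-mers; N matches nothing."""
    if len(window) != 19 or len(consensus) != 19:
        raise ValueError("count_matches requires two 19-nt strings")
    return sum(
        1 for a, b in zip(window, consensus) if a == b and a in "ACGT" and b in "ACGT"
    )


def promoter_index_to_offset(index: int, promoter_len: int) -> int:
    """0-based promoter index -> TSS-relative offset (last base is -1)."""
    return index - promoter_len


def offset_to_promoter_index(offset: int, promoter_len: int) -> int:
    return offset + promoter_len


def tss_offset_to_genome(tss_genome_coord: int, offset: int, strand: str = "+") -> int:
    """TSS-relative offset -> plus-strand genome coordinate of that base."""
    return tss_genome_coord + offset if strand == "+" else tss_genome_coord - offset


def genome_to_tss_offset(tss_genome_coord: int, coord: int, strand: str = "+") -> int:
    return coord - tss_genome_coord if strand == "+" else tss_genome_coord - coord


def scan_promoter(p: Promoter, model: FurBoxModel = FurBoxModel()) -> list[FurBoxHit]:
    """All >= min_matches windows of the promoter (both strands by default).

    Hits are sorted by match count (descending), then by proximity of the
    window to the TSS.
    """
    L = len(p.sequence)
    hits = []
    for k in range(L - 18):
        window = p.sequence[k : k + 19]
        off_start = promoter_index_to_offset(k, L)
        off_end = off_start + 18
        m = count_matches(window, model.consensus)
        if m >= model.min_matches:
            hits.append(FurBoxHit(off_start, off_end, "same", m, window))
        if model.scan_both_strands:
            m2 = count_matches(reverse_complement(window), model.consensus)
            if m2 >= model.min_matches:
                hits.append(FurBoxHit(off_start, off_end, "opposite", m2, window))
    hits.sort(key=lambda h: (-h.matches, -h.offset_end, h.strand_relative))
    return hits


def _window_match_counts(seq_codes: np.ndarray, consensus_codes: np.ndarray) -> np.ndarray:
    """Match count of every 19-nt window against the consensus (vectorized)."""
    n = seq_codes.shape[0] - 18
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for off, c in enumerate(consensus_codes):
        if c == 4:  # N in the consensus matches nothing
            continue
        counts += seq_codes[off : off + n] == c
    return counts


def scan_genome(
    genome: GenomeRecord, model: FurBoxModel = FurBoxModel()
) -> list[tuple[Interval, int]]:
    """Genome-wide consensus scan on both strands, absolute coordinates.

    Windows that are their own reverse complement are reported once (on
    the plus strand).
    """
    seq = genome.sequence
    codes = encode_nt(seq)
    cons = encode_nt(model.consensus)
    cons_rc = encode_nt(reverse_complement(model.consensus))
    fwd = _window_match_counts(codes, cons)
    rev = _window_match_counts(codes, cons_rc)  # = matches of window revcomp vs consensus
    out = []
    for i in np.nonzero(fwd >= model.min_matches)[0]:
        out.append((Interval(genome.contig_id, int(i), int(i) + 19, "+"), int(fwd[i])))
    for i in np.nonzero(rev >= model.min_matches)[0]:
        window = seq[int(i) : int(i) + 19]
        if window == reverse_complement(window) and fwd[i] >= model.min_matches:
            continue  # palindromic window already reported on '+'
        out.append((Interval(genome.contig_id, int(i), int(i) + 19, "-"), int(rev[i])))
    out.sort(key=lambda t: (t[0].start, t[0].strand))
    return out


def write_hits_tsv(
    hits: list[FurBoxHit], path, promoter_id: str = "promoter",
    header_extra: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"#{header_extra}\n")
        fh.write("promoter\toffset_start\toffset_end\tstrand_relative\tmatches\twindow\n")
        for h in hits:
            fh.write(
                f"{promoter_id}\t{h.offset_start}\t{h.offset_end}\t"
                f"{h.strand_relative}\t{h.matches}\t{h.window}\n"
            )
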