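"""Local protein alignment and reciprocal best-hit (RBH) ortholog detection.

RBH is the operational orthology criterion used to anchor the synteny
search: two proteins, one per genome, each being the other's single
highest-scoring local-alignment match.  The aligner is an exact
Smith-Waterman with affine gaps (no heuristic seeding); an optional
k-mer prefilter can skip protein pairs sharing no 4-mer, which is safe
for the well-conserved anchors this pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Union

import numpy as np
from Bio.Align import substitution_matrices

from ._align import local_align_codes, render_gapped
from .genome_model import GeneFeature

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0

MatrixLike = Union[str, tuple[str, np.ndarray], Mapping[tuple[str, str], float]]


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity: float
    query_interval: tuple[int, int]  # 0-based half-open on the query
    subject_interval: tuple[int, int]
    aligned_query: str
    aligned_subject: str

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("gapped strings differ in length")


@dataclass(frozen=True)
class OrthologPair:
    query_locus: str
    subject_locus: str
    forward_score: float
    reverse_score: float


@lru_cache(maxsize=8)
def _named_matrix(name: str) -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    return alphabet, np.asarray(mat, dtype=np.float64)


def _resolve_matrix(matrix: MatrixLike) -> tuple[str, np.ndarray]:
    if isinstance(matrix, str):
        return _named_matrix(matrix)
    if isinstance(matrix, tuple):
        alphabet, arr = matrix
        return alphabet, np.asarray(arr, dtype=np.float64)
    # mapping {(a, b): score}
    letters = sorted({a for a, _ in matrix} | {b for _, b in matrix})
    alphabet = "".join(letters)
    arr = np.zeros((len(letters), len(letters)))
    for (a, b), s in matrix.items():
        arr[letters.index(a), letters.index(b)] = s
    return alphabet, arr


def _encode(seq: str, alphabet: str, label: str) -> np.ndarray:
    index = {c: i for i, c in enumerate(alphabet)}
    codes = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        try:
            codes[i] = index[c]
        except KeyError:
            raise ValueError(
                f"residue {c!r} at position {i} of {label} is not in the "
                f"substitution-matrix alphabet"
            ) from None
    return codes


def local_align(
    a: str,
    b: str,
    matrix: MatrixLike = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Exact Smith-Waterman local alignment with affine gaps.

    A gap of length k costs ``gap_open + k*gap_extend`` (both <= 0).
    Identity is matches / aligned columns, gap columns included.  Ties
    between co-optimal alignments go to the smallest query start, then
    the smallest subject start.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if gap_open > 0 or gap_extend > 0:
        raise ValueError("gap penalties must be <= 0")
    alphabet, sub = _resolve_matrix(matrix)
    a_codes = _encode(a, alphabet, "the query")
    b_codes = _encode(b, alphabet, "the subject")
    score, qs, qe, ss, se, moves = local_align_codes(
        a_codes, b_codes, sub, gap_open, gap_extend
    )
    if not moves:
        return AlignmentResult(0.0, 0.0, (0, 0), (0, 0), "", "")
    top, bot = render_gapped(a, b, moves)
    matches = sum(1 for x, y in zip(top, bot) if x == y and x != "-")
    return AlignmentResult(
        score=score,
        identity=matches / len(top),
        query_interval=(qs, qe),
        subject_interval=(ss, se),
        aligned_query=top,
        aligned_subject=bot,
    )


def global_identity(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Identity fraction of the optimal global alignment (convenience check).

    Uses Biopython's pairwise aligner; identity is matches over aligned
    columns including gap columns, the same convention as local_align.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    top, bot = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(top, bot) if x == y and x != "-")
    return matches / len(top)


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def best_hits(
    query_proteome: Iterable[GeneFeature],
    subject_proteome: Iterable[GeneFeature],
    matrix: MatrixLike = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    prefilter: bool = False,
) -> dict[str, tuple[str, float]]:
    """Best subject hit (by local-alignment score) for every query protein.

    Ties go to the lexicographically smallest subject locus_tag.  With
    ``prefilter=True`` pairs sharing no 4-mer are skipped entirely.
    """
    queries = list(query_proteome)
    subjects = list(subject_proteome)
    if not queries or not subjects:
        raise ValueError("empty proteome")
    for f in queries + subjects:
        if not f.translation:
            raise ValueError(f"{f.locus_tag} has no translation")
    subjects = sorted(subjects, key=lambda f: f.locus_tag)
    sub_kmers = {f.locus_tag: _kmer_set(f.translation) for f in subjects} if prefilter else None
    out: dict[str, tuple[str, float]] = {}
    for q in queries:
        q_kmers = _kmer_set(q.translation) if prefilter else None
        best: Optional[tuple[str, float]] = None
        for s in subjects:
            if prefilter and not (q_kmers & sub_kmers[s.locus_tag]):
                continue
            score = local_align(
                q.translation, s.translation, matrix, gap_open, gap_extend
            ).score
            if best is None or score > best[1]:
                best = (s.locus_tag, score)
        if best is not None and best[1] > 0:
            out[q.locus_tag] = best
    return out


def reciprocal_best_hits(
    proteome_a: Iterable[GeneFeature],
    proteome_b: Iterable[GeneFeature],
    matrix: MatrixLike = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    prefilter: bool = False,
) -> list[OrthologPair]:
    """Ortholog pairs by the reciprocal best-hit criterion, sorted by query locus."""
    a_list, b_list = list(proteome_a), list(proteome_b)
    ab = best_hits(a_list, b_list, matrix, gap_open, gap_extend, prefilter)
    ba = best_hits(b_list, a_list, matrix, gap_open, gap_extend, prefilter)
    pairs = []
    for qa, (sb, fwd) in ab.items():
        hit = ba.get(sb)
        if hit is not None and hit[0] == qa:
            pairs.append(OrthologPair(qa, sb, fwd, hit[1]))
    pairs.sort(key=lambda p: p.query_locus)
    return pairs


def write_rbh_tsv(pairs: list[OrthologPair], path, header_extra: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"#{header_extra}\n")
        fh.write("query\tsubject\tforward_score\treverse_score\n")
        for p in pairs:
            fh.write(
                f"{p.query_locus}\t{p.subject_locus}\t{p.forward_score:g}\t{p.reverse_score:g}\n"
            )
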