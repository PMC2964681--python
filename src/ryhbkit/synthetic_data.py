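"""Seeded generators that plant every structure the pipeline assumes.

``simulate_genome_pair`` builds a reference/query genome pair with one
diverged anchor-ortholog, an sRNA core planted in the query's downstream
intergenic region, a Fur box with a controlled number of substitutions
at a controlled TSS offset, optional primer sites with a controlled
product length, and decoy cores — everything recorded in a ``Truth``
object so discovery recall, motif-offset accuracy, amplicon length and
target rank can be scored with no other inputs.  ``simulate_ct_table``
generates nested biological/technical qRT-PCR noise around planted
log2 effects.  All generators are pure functions of their parameter
objects (seed included).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .expression_stats import CtTable
from .genome_model import GeneFeature, GenomeRecord, Interval, PrimerPair, reverse_complement

BASES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# one codon per amino acid, for reverse-translating simulated proteins
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"

FUR_BOX_CONSENSUS = "GATAATGATAATCATTATC"


@dataclass(frozen=True)
class GenomeSimParams:
    seed: int = 0
    genome_length: int = 50_000
    n_genes: int = 40
    gc_content: float = 0.46
    anchor_index: int = 20
    anchor_strand: str = "+"
    anchor_divergence: float = 0.2
    protein_length: tuple[int, int] = (80, 120)
    core_sequence: Optional[str] = None  # default: packaged synthetic core
    core_divergence: float = 0.0
    core_offset: int = 150  # nt downstream of the anchor 3' end
    furbox_mismatches: int = 4
    furbox_offset_start: int = -44
    primer_pair: Optional[PrimerPair] = None
    pcr_product_length: int = 119
    decoy_cores: int = 3
    decoy_core_divergence: float = 0.5

    def __post_init__(self):
        if not 0 <= self.furbox_mismatches <= 19:
            raise ValueError("furbox_mismatches must be in [0, 19]")
        if not 0 <= self.anchor_index < self.n_genes:
            raise ValueError("anchor_index out of range")
        if self.anchor_strand not in "+-":
            raise ValueError("anchor_strand must be '+' or '-'")


@dataclass
class Truth:
    srna_interval: Interval
    anchor_pair: tuple[str, str]  # (query locus, reference locus)
    furbox_interval: Interval
    furbox_matches: int
    pcr_product_length: Optional[int] = None
    target_gene: Optional[str] = None

    def to_json(self) -> str:
        def iv(i: Interval):
            return {"contig_id": i.contig_id, "start": i.start, "end": i.end,
                    "strand": i.strand}

        return json.dumps(
            {
                "srna_interval": iv(self.srna_interval),
                "anchor_pair": list(self.anchor_pair),
                "furbox_interval": iv(self.furbox_interval),
                "furbox_matches": self.furbox_matches,
                "pcr_product_length": self.pcr_product_length,
                "target_gene": self.target_gene,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass(frozen=True)
class CtSimParams:
    seed: int = 0
    genes: tuple[str, ...] = ("recA", "ryhB", "sdhA", "acnA", "sodB")
    reference_gene: str = "recA"
    strain_a: str = "MR-1"
    strain_b: str = "fur"
    log2_effects: dict = field(default_factory=dict)  # gene -> log2 FC in strain_b
    sigma_bio: float = 0.3
    sigma_tech: float = 0.2
    n_bio: int = 3
    n_tech: int = 4
    baseline_ct: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma_bio < 0 or self.sigma_tech < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.log2_effects.get(self.reference_gene, 0.0) != 0.0:
            raise ValueError("the reference gene cannot carry an effect")


# ---------------------------------------------------------------------------
# Sequence-level helpers


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def mutate_sequence(seq: str, sub_rate: float, seed: int) -> str:
    """Per-site substitution to a uniformly chosen *different* base."""
    if not 0 <= sub_rate <= 1:
        raise ValueError("sub_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = list(seq)
    hits = rng.random(len(seq)) < sub_rate
    for i in np.flatnonzero(hits):
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def _mutate_with_rng(seq: str, sub_rate: float, rng: np.random.Generator,
                     alphabet: str = BASES) -> str:
    out = list(seq)
    hits = rng.random(len(seq)) < sub_rate
    for i in np.flatnonzero(hits):
        choices = [c for c in alphabet if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def random_protein(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list(AMINO_ACIDS))
    return "M" + "".join(aas[rng.integers(20, size=length - 1)])


def back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + _STOP


def mutate_consensus(consensus: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """Substitute exactly n positions of the consensus to different bases."""
    out = list(consensus)
    for i in rng.choice(len(consensus), size=n_mismatches, replace=False):
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# Genome-pair simulation


def _default_core() -> str:
    from .srna_discovery import default_core_sequence

    return default_core_sequence()


def _plant(seq: list[str], start: int, insert: str, reserved: list[tuple[int, int]],
           label: str, genome_length: int) -> None:
    end = start + len(insert)
    if start < 0 or end > genome_length:
        raise ValueError(
            f"planted {label} does not fit in the genome; increase genome_length"
        )
    for s, e in reserved:
        if start < e and s < end:
            raise ValueError(
                f"planted {label} collides with another element; increase genome_length"
            )
    seq[start:end] = list(insert)
    reserved.append((start, end))


def _build_genome(
    contig_id: str,
    rng: np.random.Generator,
    params: GenomeSimParams,
    proteins: list[str],
    strands: list[str],
) -> tuple[GenomeRecord, list[tuple[int, int]], list[str]]:
    n = params.genome_length
    seq = list(random_sequence(rng, n, params.gc_content))
    spacing = n // (params.n_genes + 1)
    reserved: list[tuple[int, int]] = []
    features = []
    for i, prot in enumerate(proteins):
        cds = back_translate(prot)
        if strands[i] == "-":
            cds = reverse_complement(cds)
        start = (i + 1) * spacing - len(cds) // 2
        _plant(seq, start, cds, reserved, f"gene {i}", n)
        features.append(
            GeneFeature(
                locus_tag=f"{contig_id}_{i:04d}",
                contig_id=contig_id,
                start=start,
                end=start + len(cds),
                strand=strands[i],
                kind="CDS",
                translation=prot,
            )
        )
    genome = GenomeRecord(contig_id, "".join(seq), features=features)
    return genome, reserved, [f.locus_tag for f in features]


def simulate_genome_pair(
    params: GenomeSimParams,
) -> tuple[GenomeRecord, GenomeRecord, Truth]:
    """Simulate a (reference, query) genome pair with planted truth.

    The reference genome carries the anchor gene; the query carries a
    diverged copy of it, with the sRNA core planted in the intergenic
    region downstream of the anchor, a Fur box upstream of the planted
    sRNA 5' end, optional primer sites, and decoy cores elsewhere.
    """
    rng = np.random.default_rng(params.seed)
    core = params.core_sequence if params.core_sequence is not None else _default_core()

    lo, hi = params.protein_length
    lengths = rng.integers(lo, hi + 1, size=params.n_genes)
    ref_proteins = [random_protein(rng, int(L)) for L in lengths]
    # decoy proteins are independent between genomes; the anchor is a
    # diverged copy of the reference anchor
    qry_lengths = rng.integers(lo, hi + 1, size=params.n_genes)
    qry_proteins = [random_protein(rng, int(L)) for L in qry_lengths]
    ai = params.anchor_index
    qry_proteins[ai] = "M" + _mutate_with_rng(
        ref_proteins[ai][1:], params.anchor_divergence, rng, AMINO_ACIDS
    )

    ref_strands = ["+" if rng.random() < 0.5 else "-" for _ in range(params.n_genes)]
    qry_strands = ["+" if rng.random() < 0.5 else "-" for _ in range(params.n_genes)]
    ref_strands[ai] = params.anchor_strand
    qry_strands[ai] = params.anchor_strand

    reference, _, _ = _build_genome("REFCHR", rng, params, ref_proteins, ref_strands)

    # query genome: build genes first, then plant intergenic elements
    n = params.genome_length
    seq = list(random_sequence(rng, n, params.gc_content))
    spacing = n // (params.n_genes + 1)
    reserved: list[tuple[int, int]] = []
    features = []
    for i, prot in enumerate(qry_proteins):
        cds = back_translate(prot)
        if qry_strands[i] == "-":
            cds = reverse_complement(cds)
        start = (i + 1) * spacing - len(cds) // 2
        _plant(seq, start, cds, reserved, f"gene {i}", n)
        features.append(
            GeneFeature(
                locus_tag=f"QRYCHR_{i:04d}",
                contig_id="QRYCHR",
                start=start,
                end=start + len(cds),
                strand=qry_strands[i],
                kind="CDS",
                translation=prot,
            )
        )
    anchor = features[ai]

    planted_core = _mutate_with_rng(core, params.core_divergence, rng)
    if params.anchor_strand == "+":
        srna_start = anchor.end + params.core_offset
        srna_iv = Interval("QRYCHR", srna_start, srna_start + len(core), "+")
        _plant(seq, srna_start, planted_core, reserved, "sRNA core", n)
    else:
        srna_end = anchor.start - params.core_offset
        srna_iv = Interval("QRYCHR", srna_end - len(core), srna_end, "-")
        _plant(seq, srna_iv.start, reverse_complement(planted_core), reserved,
               "sRNA core", n)

    box = mutate_consensus(FUR_BOX_CONSENSUS, params.furbox_mismatches, rng)
    # the box occupies TSS offsets [furbox_offset_start, furbox_offset_start+18]
    # on the sRNA strand, with the sRNA 5' end as the TSS
    if params.anchor_strand == "+":
        box_start = srna_iv.start + params.furbox_offset_start
        box_iv = Interval("QRYCHR", box_start, box_start + 19, "+")
        _plant(seq, box_start, box, reserved, "Fur box", n)
    else:
        box_end = srna_iv.end - params.furbox_offset_start
        box_iv = Interval("QRYCHR", box_end - 19, box_end, "-")
        _plant(seq, box_iv.start, reverse_complement(box), reserved, "Fur box", n)

    pcr_len: Optional[int] = None
    if params.primer_pair is not None:
        pp = params.primer_pair
        length = params.pcr_product_length
        if length < len(pp.forward) + len(pp.reverse):
            raise ValueError("pcr_product_length shorter than the two primers")
        # plant the amplicon in the intergenic gap downstream of the last gene
        site = features[-1].end + 200
        amplicon = (
            pp.forward
            + random_sequence(rng, length - len(pp.forward) - len(pp.reverse), params.gc_content)
            + reverse_complement(pp.reverse)
        )
        _plant(seq, site, amplicon, reserved, "PCR amplicon", n)
        pcr_len = length

    # decoys go downstream of genes other than the anchor and the last gene
    # (whose gap may hold the planted amplicon)
    decoy_slots = [i for i in range(params.n_genes - 1) if i != ai]
    if params.decoy_cores > len(decoy_slots):
        raise ValueError("too many decoy cores for this gene count")
    for d in range(params.decoy_cores):
        decoy = _mutate_with_rng(core, params.decoy_core_divergence, rng)
        site = features[decoy_slots[d]].end + 300
        _plant(seq, site, decoy, reserved, f"decoy core {d}", n)

    query = GenomeRecord("QRYCHR", "".join(seq), features=features)
    truth = Truth(
        srna_interval=srna_iv,
        anchor_pair=(anchor.locus_tag, reference.features[ai].locus_tag),
        furbox_interval=box_iv,
        furbox_matches=19 - params.furbox_mismatches,
        pcr_product_length=pcr_len,
        target_gene=None,
    )
    return reference, query, truth


def plant_target_window(
    rng: np.random.Generator,
    srna: str,
    n_windows: int,
    window_len: int = 120,
    target_index: int = 0,
    gc: float = 0.46,
) -> tuple[list, str]:
    """Random mRNA start-codon windows with one perfect antiparallel target.

    Returns (windows, target_gene_name).  The target window contains the
    exact reverse complement of the sRNA, so the planted duplex pairs
    every sRNA base.
    """
    from .target_prediction import TargetWindow

    windows = []
    target_gene = f"gene{target_index:04d}"
    for i in range(n_windows):
        seq = random_sequence(rng, window_len, gc)
        if i == target_index:
            insert = reverse_complement(srna)
            if len(insert) > window_len:
                raise ValueError("sRNA longer than the target window")
            pos = (window_len - len(insert)) // 2
            seq = seq[:pos] + insert + seq[pos + len(insert):]
        windows.append(
            TargetWindow(
                gene=f"gene{i:04d}",
                sequence=seq,
                genome_interval=Interval("SIM", 1000 * i + 1, 1000 * i + 1 + window_len, "+"),
            )
        )
    return windows, target_gene


# ---------------------------------------------------------------------------
# Ct-table simulation


def simulate_ct_table(params: CtSimParams) -> tuple[CtTable, dict[str, float]]:
    """Nested-noise qRT-PCR simulation.

    ct = baseline - log2_effect(strain_b only) + bio_noise + tech_noise,
    with the biological draw shared by all genes of the same (strain,
    bio_rep) sample — so reference-gene normalization cancels it, as it
    does for genuine sample-to-sample variation.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    effects = {g: float(params.log2_effects.get(g, 0.0)) for g in params.genes}
    for strain in (params.strain_a, params.strain_b):
        for rep in range(1, params.n_bio + 1):
            bio = rng.normal(0.0, params.sigma_bio) if params.sigma_bio > 0 else 0.0
            for gene in params.genes:
                base = params.baseline_ct.get(gene, 20.0)
                eff = effects[gene] if strain == params.strain_b else 0.0
                for tech in range(1, params.n_tech + 1):
                    noise = (
                        rng.normal(0.0, params.sigma_tech)
                        if params.sigma_tech > 0
                        else 0.0
                    )
                    rows.append(
                        {
                            "gene": gene,
                            "strain": strain,
                            "bio_rep": rep,
                            "tech_rep": tech,
                            "ct": base - eff + bio + noise,
                        }
                    )
    return CtTable(pd.DataFrame(rows)), effects


# ---------------------------------------------------------------------------
# Dataset writer


def write_dataset(outdir, reference: GenomeRecord, query: GenomeRecord, truth: Truth,
                  primer_pair: Optional[PrimerPair] = None) -> None:
    """Serialize a simulated dataset as FASTA/GFF3/protein FASTA/TSV/JSON."""
    from pathlib import Path

    from .genome_model import write_genome_fasta, write_gff3, write_protein_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, g in (("reference", reference), ("query", query)):
        write_genome_fasta(g, outdir / f"{name}.fasta")
        write_gff3(g.features, outdir / f"{name}.gff3")
        write_protein_fasta(g.features, outdir / f"{name}_proteins.fasta")
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    if primer_pair is not None:
        with open(outdir / "primers.tsv", "w") as fh:
            fh.write("name\tforward\treverse\n")
            fh.write(f"{primer_pair.name}\t{primer_pair.forward}\t{primer_pair.reverse}\n")
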