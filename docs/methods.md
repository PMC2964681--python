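# Methods

`ryhbkit` implements the computational workflow used to find and
characterize an unannotated, Fur-repressed small regulatory RNA (an
*ryhB* homolog) in a bacterial genome where direct whole-gene homology
search fails. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Synteny-anchored discovery

Known *ryhB* genes in enterobacteria sit immediately 3′ of a conserved
flanking gene. The discovery procedure therefore (1) establishes the
anchor in the query genome by reciprocal best hit (RBH) against a
reference proteome, (2) takes the intergenic interval immediately
downstream of the anchor on its coding strand — up to the next annotated
feature boundary on either strand or `max_len` (default 1000 nt,
generous for bacterial intergenic spacing), and (3) aligns a conserved
sRNA "core" sequence against that interval on both strands. The core is
the segment of *ryhB* that stays recognizable across species (it carries
the mRNA-pairing sequence and the Hfq binding site); the rest of the
gene diverges too fast for BLAST-style search, which is the motivation
for anchoring on synteny in the first place.

Protein alignment is exact Smith–Waterman with affine gaps (BLOSUM62,
gap open −11, gap extend −1 — the standard protein-BLAST parameters; a
gap of length *k* costs `open + k·extend`). RBH requires each partner to
be the other's unique best score; ties resolve to the lexicographically
smallest locus tag so results are deterministic. An optional 4-mer
prefilter skips protein pairs sharing no 4-mer; this is safe for
conserved anchors and makes all-vs-all comparisons cheap, but it is off
by default because it can miss extremely diverged pairs.

Nucleotide core search uses match +2 / mismatch −3 / gap open −5 /
gap extend −2 (BLASTN-like) with a minimum reported score of 40 —
roughly 20 net matched bases, which on a 1 kb intergenic region keeps
the false-discovery rate of the search effectively zero (0/1000 random
regions in the packaged null simulation) while tolerating ~10–20%
core divergence. `N` never matches anything in any scan or alignment
(conservative for draft genomes). The annotated strand is searched
first and wins score ties; both strands are searched because the sRNA
strand is not generally known a priori.

The packaged default core (`data/ryhb_core_synthetic.fasta`) is a
randomly generated synthetic stand-in used only for self-consistent
demonstrations and tests; analyses of real genomes must supply a core
extracted from an alignment of known homologs. No test asserts anything
about the fixture's biological content.

### Alignment kernel and its verification

One Gotoh-style affine-gap local-alignment kernel (numba-compiled)
serves protein search, nucleotide core search and duplex scoring; only
the substitution table changes. It is verified two independent ways:
against a cubic-time DP that maximizes over explicit gap lengths (a
different recurrence, itself validated by exhaustive enumeration of all
alignment paths at tiny sizes), across all length combinations up to 8;
and against Biopython's `PairwiseAligner` scores on random proteins.
Co-optimal alignments are resolved deterministically (smallest query
start, then subject start; duplexes prefer the shortest duplex, then
the 5′-most sRNA position).

## Fur-box scanning

Fur binds a 19-bp inverted-repeat consensus `GATAATGATAATCATTATC`. The
scanner is a pure match counter — a window is a hit when at least
`min_matches` (default 15) of its 19 bases equal the consensus — because
that is the operational criterion used in the sRNA literature; no
position-weight matrix is fitted. Both strands are scanned by default:
although the consensus is an inverted repeat, it is not exactly
self-reverse-complementary, so orientation matters.

Offsets follow the upstream-position convention: the base immediately 5′
of the transcription start site is −1, and a window occupying upstream
bases 26..44 is printed as offsets −44 to −26. The anchor point is the
candidate's 5′ end by default but is exposed as a parameter
(`tss_genome_coord`), since a mapped transcription start and a predicted
promoter element need not coincide. Null behavior is analytically
checkable: on uniform random sequence each consensus base matches with
probability 1/4, so per-window match counts are Binomial(19, ¼); the
test suite verifies the empirical hit rate against this tail within
three standard errors, and that 15/19 hits essentially never occur by
chance in short promoters (expected ≈ 10⁻⁶ per window).

## Target prediction

Bacterial sRNAs act mostly around translation initiation, so each
annotated CDS contributes a window from 60 nt upstream to 60 nt
downstream of its start codon (mRNA sense, truncated and flagged at
contig edges). The sRNA is aligned antiparallel against each window
with a base-pairing score: Watson–Crick +1, G:U wobble +0.5 (wobbles
are real in sRNA–mRNA duplexes but weaker), mismatch −1, gap open −2,
gap extend −1. T and U are interchangeable; `N` never pairs.

Significance is the empirical rank among all scanned genes:
`p(gene) = (1 + #{other genes with score ≥ its score}) / N`. This is
assumption-free and exactly calibrated under exchangeability — the
expected fraction of genes at p ≤ 0.01 is 0.01, which the suite verifies
— unlike an extreme-value fit, which would buy resolution below 1/N at
the price of a parametric assumption. Two properties of this definition
matter for interpretation: the smallest attainable p is 1/N, and because
the score is discrete (half-integer steps) ties are common, making the
p-values *superuniform* (conservative), never anti-conservative. The
test suite checks exactly that: a one-sided Kolmogorov–Smirnov test that
the ECDF never exceeds uniform, and full two-sided uniformity after
exchangeable tie-randomization of the scores. A plain two-sided KS on
the tied p-values would reject by construction and would say nothing
about calibration.

## qRT-PCR fold-change inference

The design is nested: technical replicate wells inside biological
replicates, for each gene × strain. Normalization subtracts the mean
reference-gene Ct (default *recA*) of the same (strain, biological
replicate) sample — ΔCt, expression ∝ 2^−ΔCt — which cancels any
per-sample offset (RT efficiency, loading, plate effects). Technical
replicates are averaged inside each biological replicate and the
two-strain contrast is tested across biological replicates with a
two-sided t-test; the fold change is `2^(mean ΔCt_A − mean ΔCt_B)`, so
up-regulation in B gives FC > 1, and `fold_change(A,B)·fold_change(B,A)
= 1` by construction.

For a balanced nested design, averaging technical replicates and
testing across biological replicates is exactly the linear-mixed-model
contrast for biological + technical variance components, without
fitting REML — so the package uses that reduction as its canonical
path; a full variance-component fit is deliberately not implemented
(it adds nothing for balanced designs and would be under-determined at
n = 3). The default test pools the variance: with three biological
replicates per arm the pooled t-test holds its nominal 5% size exactly
under normality, whereas Welch's approximation is measurably
conservative at this depth (true size ≈ 0.035 in simulation), which
distorts power comparisons. `welch=True` is available for unbalanced or
variance-heterogeneous data. Undetermined Ct wells are dropped with a
logged warning, never imputed. The reference gene's own contrast has
zero variance by construction and is reported as FC 1 with p = NA
rather than an error.

## Synthetic data: what it emulates, what it does not

`simulate_genome_pair` plants, in an i.i.d. background at a chosen GC
content (default 0.46, a typical γ-proteobacterial value): ~40 genes
with random proteins; one anchor-ortholog pair at controlled protein
divergence (default 20%); the sRNA core at controlled divergence
planted 150 nt downstream of the query anchor; a Fur box with exactly
`furbox_mismatches` substitutions (default 4, i.e. a 15/19 box) whose
window spans TSS offsets −44..−26 relative to the planted sRNA 5′ end;
optional primer sites separated to give a chosen amplicon (default
119 bp); and decoy cores at 50% divergence in other intergenic gaps.
Every planted element is recorded in a `Truth` object, and identical
seeds give byte-identical outputs.

`simulate_ct_table` draws
`ct = baseline − log2_effect + bio_noise + tech_noise` with the
biological draw (σ = 0.3 cycles) shared by all genes of a sample — so
reference normalization cancels it, as it cancels genuine
sample-to-sample variation — and i.i.d. technical noise (σ = 0.2
cycles) per well; three biological × four technical replicates by
default.

What passing these benchmarks does **not** show: real intergenic
regions are not i.i.d. (repeats, terminators, skew), real ortholog
divergence is not uniform per site, real promoters have composition
bias that changes the motif null, real Ct noise has outliers and
amplification-efficiency differences that the log-linear model ignores,
and genuine sRNA targeting depends on structure/accessibility that the
pairing score does not model. The benchmarks verify the *machinery* —
coordinate arithmetic, alignment optimality, offset conventions,
statistical calibration — not biological sensitivity on real genomes.

## Problem sizes and determinism

Default benchmark sizes — 50 kb genomes with 40 genes, 50 discovery
replicates, 1000 target windows, 500 fold-change replicates and 5000
(script) / 10,000 (test) null replicates for test size — were chosen so
that every Monte-Carlo estimate has standard error well inside the
band it is checked against. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; there is no hidden global
state, and the pipeline's outputs embed a config hash and seed so a
reproduced run is byte-identical.

## Known limitations

- The single-best-candidate contract returns one locus per run; tandem
  duplicates are available via `find_all_core_homologs` (greedy,
  non-overlapping) but are lightly exercised.
- Empirical p-values cannot go below 1/N; genome-scale scans are needed
  for p < 0.01 claims.
- In-silico PCR is exact-match by default (an optional mismatch
  tolerance exists); no melting-temperature model.
- No covariance-model or secondary-structure-aware RNA search; no
  thermodynamic (nearest-neighbor ΔG) hybridization model.
- GenBank flat files are not parsed; inputs are FASTA + GFF3 (+
  optional protein FASTA keyed by locus_tag).
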