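# Methods

`orthostruct` re-implements, as a tested library, the comparative analysis
protocol used to characterise plant ABCB1 orthologs across monocots and
dicots: true-ortholog screening, gene-structure inference from cDNA/genomic
pairs, intron phase and protosplice statistics, consensus-protein similarity
scoring, ABC domain/motif annotation with an NBD1-vs-NBD2 comparison, and
neighbor-joining phylogeny with bootstrap support. Every stage is
exercisable end to end on a synthetic gene-family generator with full ground
truth, so the pipeline's behaviour is verifiable without any downloads.

## The synthetic gene-family generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream claim is checked.

**Ancestral gene.** A designed full-length ABCB-type protein of 1271 aa
organised TMD1–NBD1–linker–TMD2–NBD2:

- a 200-aa variable N-terminus carrying a 10-aa group-motif slot
  (aa 80–90);
- two transmembrane domains of six 21-aa strongly hydrophobic helices
  (drawn from L/I/V/F/A/M) separated by 15-aa loops;
- two 186-aa nucleotide-binding domains containing the six canonical
  motifs at realistic spacings — Walker A (`GPSGSGKST`), the Q-loop
  invariant Q 31 aa downstream, the ABC signature (`LSGGQ`), Walker B
  (`ILLLDE`), D-loop (`SALD`), and the H-loop invariant H 33 aa after
  Walker B;
- a 101-aa variable inter-half linker and 48-aa inter-domain spacers.

NBD2 is derived from NBD1's filler at 45 % per-site divergence with a
planted Walker A serine→proline change, so the two halves share descent
(inter-NBD identity near the ~50–60 % seen in real ABCB proteins) and the
NBD comparison has a known radical substitution to find. NBD filler is
drawn from an alphabet disjoint from every motif pattern so planted motif
coordinates are unambiguous ground truth.

The protein is reverse-translated with uniformly chosen synonymous codons
into a 3816-nt CDS split into 10 exons / 9 introns — the ancestral
angiosperm intron complement. The default exon split places junction
phases (0,1,2,0,0,1,2,0,2), a 44 % phase-0 bias matching the bias the
analysis is meant to detect. Default intron lengths total 1743 bp
(mean 194 bp), the dicot observation. Every intron begins `GT` and ends
`AG`.

**Evolution.** Substitutions are applied on a group branch and a terminal
branch, each carrying half the configured root→tip rate: core sites at
`substitution_rate_core` (default 0.03), variable regions (N-terminus,
linker) and introns at `substitution_rate_variable` (default 0.10).
Substitutions are codon-aware (a proposed in-frame stop is rejected) and
never touch motif codons, splice dinucleotides, or the start codon —
purifying selection in miniature. Monocot lineages additionally lose each
intron independently with probability `intron_loss_prob_monocot`
(default 0.65, giving the observed two–four retained introns); loss is
exact excision, preserving frame. Dicots retain all nine introns. Each
taxon finally receives a frame-preserving N-terminal deletion of
0–`terminal_indel_max` (default 13) codons inside exon 1. Monocots carry
the planted group-specific N-terminal motif `PELEAFHLPS`, invariant within
the group.

A single `numpy` Generator seeded from `config.seed` drives everything;
identical config ⇒ byte-identical bundle. Bundles are self-consistent by
construction: splicing the genomic sequence with the true model reproduces
the cDNA exactly, and translating the cDNA reproduces the protein.

**What the generator does not emulate.** No intron-length evolution (so
monocot mean intron size stays at the ancestral ~194 bp rather than the
~556 bp seen in real monocots), no codon usage or selection beyond
stop-avoidance, no UTRs (the cDNA is exactly the CDS), no intron gain, no
sequencing error. Passing tests therefore demonstrate correctness of the
algorithms under a clean, known history — not robustness to every artefact
of real annotation pipelines.

## Gene-structure inference

`infer_gene_model` is a seed-anchored spliced alignment. Exact 20-mer
matches between cDNA and genomic sequence are grouped by offset
(genomic − cDNA position), merged into runs, and chained colinearly by a
small DP that maximises covered cDNA length (overlaps up to 30 nt are
tolerated and not double-counted). Consecutive chain offsets delimit
introns; each junction is then refined by scanning candidate boundaries
within ±15 nt of the anchor limits, scoring candidates by exon match count
on each side. Candidates whose implied termini are `GT…AG` win outright;
among them (or among all, when no canonical candidate exists — the intron
is then flagged non-canonical) the maximal score wins, ties to the
smallest coordinate. A model whose reconstruction mismatches the cDNA by
more than 20 % raises a model-quality error; no anchors at all raise an
"unalignable" error.

Intron **phase** is the count of coding nucleotides 5′ of the junction,
mod 3; junctions outside the CDS are phased to the nearest CDS edge and
flagged non-coding. **Protosplice classification** uses the exonic
context: with T the last three exonic nt upstream, X its last nt and Y the
first exonic nt downstream — PROTOSPLICE iff T matches `(A/C)AG` and Y=G;
else N\_G iff X≠G and Y=G; else G\_N iff X=G; else N\_N. A `G|G` context
failing the `(A/C)AG` test classes as G\_N (the upstream G takes
precedence); this is configurable only by editing the classifier, and is
stated here because the class boundary is a genuine design choice.

**Exon correspondence** projects every species' junctions through a global
cDNA-to-reference-cDNA alignment; positions within ±6 nt (two codons) of a
reference junction are the same intron position. Reference-only positions
are losses in that species, species-only positions gains. The
phase-spectrum report carries two denominators — pooled introns and
distinct conserved positions — because summary percentages differ between
them whenever the same ancestral intron is counted in several taxa.

The phase spectrum's uniformity tests are a chi-square goodness-of-fit
against (⅓,⅓,⅓) and an exact one-sided binomial test for phase-0 excess,
both from `scipy.stats`.

## Alignment, consensus and similarity scoring

Pairwise alignment is global Needleman–Wunsch with affine gaps via
`Bio.Align.PairwiseAligner`: BLOSUM62 for protein, +2/−3 for DNA, gap
open 10 / extend 0.5 (a length-L gap costs open + (L−1)·extend). The
identity convention everywhere: identical residues over aligned columns
excluding dual-gap columns, with gap-vs-residue columns counted as
mismatches; every identity report repeats this in its footer.

The multiple alignment is guide-tree progressive profile alignment: NJ
agglomeration order on d = 1 − identity, profiles merged by sum-of-pairs
Needleman–Wunsch over a column-score matrix (profile count matrices
contracted through BLOSUM62), with the affine DP kernel JIT-compiled via
numba. Deterministic throughout.

Consensus rules: per column the modal non-gap residue; if all residues are
mutually distinct, the reference (maize-like) residue; if the reference is
gapped in such a column, the lexicographically smallest residue; among
equally-modal residues the reference wins when it is a mode, else the
lexicographically smallest mode. Insertion columns are retained.
Similarity tracks count group members matching the consensus per column —
0–6 for the six monocots and 0–2 for the two dicots under the default
design. Deletion tracks are maximal per-species gap runs in consensus
coordinates.

## Motif and domain annotation

Transmembrane helices: Kyte–Doolittle mean hydropathy over a 19-aa
window, threshold 1.6, maximal supra-threshold runs merged when separated
by <5 aa and reported when ≥15 aa. NBD motifs are found sequentially left
to right, which enforces the canonical order: Walker A by the pattern
`[AG]x{4}GK[ST]` (its absence means "not an NBD"), the Q-loop as the
leftmost Q 25–60 aa after Walker A, the ABC signature as `LSGGQ` with ≤1
mismatch, Walker B as `[ILVFMA]{4}DE`, the D-loop as `SALD` with ≤1
mismatch, and the H-loop as the leftmost H 25–45 aa after Walker B. All
patterns and windows are configurable; the defaults above are this
package's operationalisation of motifs that the literature names but does
not define as regular expressions.

The architecture is anchored on the two Walker A…H-loop spans (±30 aa
padding); TMD1 is the helix cluster before NBD1, TMD2 the cluster between
NBD1 and NBD2, and the linker the interval between NBD1's end and TMD2's
start. Inter-motif distance tables flag a gap "conserved" when its
cross-species range is ≤2 aa.

NBD1 vs NBD2: the two subsequences are globally aligned and every
mismatch classified **conservative** (BLOSUM62 score ≥ 1) or **radical**
(score ≤ 0) — an amino-acid-level reading of "synonymous/non-synonymous"
that reproduces the standard serine calls (S/A conservative; S/P and S/C
radical). Group-specific motif discovery reports maximal 6–15-column
windows where one group is gap-free and unanimous (up to a configurable
mismatch budget) while every member of the other group differs in more
than that budget.

## Ortholog screen

Criterion 1 (rank): the candidate is the top same-species hit of a
semi-global search (free end gaps; BLOSUM62; score-primary ranking with
identity then id tie-breaks) and covers ≥90 % of the query. Rank, score
and coverage replace web-BLAST E-values, which are meaningless at this
database scale. Criterion 2 (domains): the candidate's architecture
annotates completely with all six motifs in both NBDs. Criterion 3
(reciprocal): searching the candidate against the reference-species
database retrieves the reference at rank 1. Criterion 4 (spacing): the
maximal relative deviation of corresponding inter-feature gaps (domain
chain plus the ten inter-motif gaps) is ≤0.25. The 0.90 coverage floor
and 0.25 spacing tolerance are this package's defaults for thresholds the
protocol describes only qualitatively; both are parameters.

`walk_assemble` reproduces iterative sequence walking: each round merges
the contig with the longest suffix–prefix overlap ≥ `min_overlap` at
identity ≥ `min_identity` (both assembly ends attempted; ties to the
longer contig, then lexicographic id; assembly residues win at
mismatches — consensus voting is out of scope). Each round consumes a
contig, so termination is guaranteed; the procedure is fully
deterministic.

## Phylogeny

Distances are uncorrected p-distances (differing sites over
pairwise-comparable columns, gap columns excluded per pair). Tree building
is canonical Saitou–Nei neighbor joining with lowest-index tie-breaking;
negative branch estimates are clamped to 0 and flagged in the log and on
the tree object. NJ is exact on additive matrices, which the test suite
exploits with randomly generated additive trees. Bootstrap support
resamples alignment columns with replacement, rebuilds the NJ tree, and
scores each original internal bipartition by its replicate frequency;
replicates in which some pair loses all comparable columns are skipped.
When all sequences are identical, supports are defined as 100 on the
degenerate topology, by convention. Default replicates: 1000 for analysis,
200 in tests and the acceptance script, which is ample for the deep
monocot/dicot split the generator plants.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's own scale: families of
six monocots + two dicots with ~5.5-kb genomic loci, 50 seed-controlled
families for structure recovery, 200 random pairs for the alignment
oracle, 100 random additive matrices for NJ, 200 bootstrap replicates, 100
planted NBD constructs, and a 6-kb locus cut into 900-bp contigs with
300-bp overlaps for assembly. The whole suite completes in well under a
minute on one core. Floating-point comparisons in tests use exact
equality only where the arithmetic is exact (counts, closed forms on
integer-valued inputs) and 1e-9 absolute tolerance otherwise.

## Known limitations

- The spliced aligner assumes the cDNA lies colinearly on the forward
  strand within one locus; it does not handle trans-splicing, inversions,
  or alternative isoforms.
- Junction refinement can in principle tie between two canonical
  boundaries that reconstruct the same cDNA; ties resolve to the smaller
  coordinate, which may differ from an annotation's choice while being
  sequence-equivalent.
- The consensus and group-motif machinery assumes exactly two groups of
  interest (monocot/dicot); outgroup rows are carried but not scored.
- p-distance saturates for deep divergences; a Poisson or other
  correction would be needed beyond the ~20 % divergence regime the
  generator produces.
- E-value statistics, six-frame translated search, profile HMMs and 3-D
  structure analyses are intentionally out of scope.
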