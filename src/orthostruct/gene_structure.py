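"""Gene-structure inference and intron evolution statistics.

Exon/intron models are inferred by seed-anchored spliced alignment of a
cDNA against its genomic locus: exact k-mer anchors are chained colinearly,
and each inter-anchor junction is refined by scanning candidate offsets,
preferring canonical GT..AG intron termini and then maximal exon match
score.  Downstream statistics cover intron phases (position of the
junction within the reading frame), protosplice-site classes of the exonic
junction context, cross-species exon correspondence with gain/loss
polarity, and the pooled phase spectrum with tests against a uniform
phase distribution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import (
    GeneModel,
    Intron,
    OrthostructError,
    SequenceRecord,
    ValidationError,
)
from .protein_consensus import AlignParams, global_align

__all__ = [
    "GeneModel", "Intron", "ExonCorrespondence",
    "infer_gene_model", "annotate_introns", "compute_phases",
    "classify_protosplice", "map_exon_correspondence", "phase_spectrum",
    "UnalignableError", "ModelQualityError",
]


class UnalignableError(OrthostructError):
    """No colinear anchor chain between cDNA and genomic sequence."""


class ModelQualityError(OrthostructError):
    """Inferred model reconstructs the cDNA worse than the tolerance."""


# ---------------------------------------------------------------------------
# spliced alignment
# ---------------------------------------------------------------------------

def _anchor_blocks(cdna: str, genomic: str, k: int, max_hits: int = 20
                   ) -> list[tuple[int, int, int]]:
    """Merged exact-match runs as (offset, cdna_start, cdna_end) blocks.

    ``offset`` is genomic − cDNA position; within one exon the offset is
    constant, and each intron increases it by the intron length.
    """
    index: dict[str, list[int]] = {}
    for g in range(len(genomic) - k + 1):
        index.setdefault(genomic[g:g + k], []).append(g)
    by_offset: dict[int, list[int]] = {}
    for c in range(len(cdna) - k + 1):
        hits = index.get(cdna[c:c + k])
        if hits is None or len(hits) > max_hits:
            continue
        for g in hits:
            by_offset.setdefault(g - c, []).append(c)
    blocks = []
    for d, starts in by_offset.items():
        starts.sort()
        run_s = prev = starts[0]
        for c in starts[1:]:
            if c <= prev + k:      # overlapping/adjacent k-mers: same run
                prev = c
            else:
                blocks.append((d, run_s, prev + k))
                run_s = prev = c
        blocks.append((d, run_s, prev + k))
    return blocks


def _chain_blocks(blocks: list[tuple[int, int, int]],
                  max_overlap: int = 30) -> list[tuple[int, int, int]]:
    """Colinear chain of blocks maximizing covered cDNA length (DP).

    Blocks may overlap by up to ``max_overlap`` nt (coincidental matches
    around junctions); the overlap is not double-counted.
    """
    blocks = sorted(blocks, key=lambda b: (b[1], b[0]))
    n = len(blocks)
    best = [0.0] * n
    prev = [-1] * n
    for i, (d, cs, ce) in enumerate(blocks):
        best[i] = float(ce - cs)
        for j in range(i):
            dj, csj, cej = blocks[j]
            if dj <= d and csj <= cs and cej < ce and cs >= cej - max_overlap:
                cand = best[j] + (ce - max(cs, cej))
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    if n == 0:
        return []
    i = int(np.argmax(best))
    chain = []
    while i >= 0:
        chain.append(blocks[i])
        i = prev[i]
    return chain[::-1]


def _refine_junction(cdna: str, genomic: str, d_left: int, d_right: int,
                     lo: int, hi: int, window: int
                     ) -> tuple[int, bool]:
    """Pick the exon boundary (cDNA coordinate) between two anchored
    offsets: canonical GT..AG candidates win, then maximal match score,
    then the smallest coordinate.  Returns (boundary, canonical?)."""
    wl, wr = max(lo - window, 0), min(hi + window, len(cdna))
    span = range(max(lo, 1), min(hi, len(cdna) - 1) + 1)
    left_match = np.zeros(len(cdna), dtype=np.int32)
    right_match = np.zeros(len(cdna), dtype=np.int32)
    for p in range(wl, wr):
        gl = p + d_left
        if 0 <= gl < len(genomic) and cdna[p] == genomic[gl]:
            left_match[p] = 1
        gr = p + d_right
        if 0 <= gr < len(genomic) and cdna[p] == genomic[gr]:
            right_match[p] = 1
    left_cum = np.concatenate([[0], np.cumsum(left_match)])
    right_cum = np.concatenate([[0], np.cumsum(right_match)])

    def score(x: int) -> int:
        # positions [wl, x) spliced at the left offset, [x, wr) at the right
        return int((left_cum[x] - left_cum[wl])
                   + (right_cum[wr] - right_cum[x]))

    def canonical(x: int) -> bool:
        don = genomic[x + d_left:x + d_left + 2]
        acc = genomic[x + d_right - 2:x + d_right]
        return don == "GT" and acc == "AG"

    candidates = list(span)
    if not candidates:
        return max(lo, 1), False
    canon = [x for x in candidates if canonical(x)]
    pool = canon if canon else candidates
    best_x = max(pool, key=lambda x: (score(x), -x))
    return best_x, bool(canon)


def infer_gene_model(cdna: SequenceRecord, genomic: SequenceRecord,
                     min_exon: int = 10, k: int = 20,
                     refine_window: int = 15,
                     max_mismatch_frac: float = 0.2) -> GeneModel:
    """Infer the exon/intron model of ``genomic`` from its spliced cDNA.

    At zero cDNA/genomic divergence the returned model reconstructs the
    cDNA exactly; with divergence, reconstruction mismatch above
    ``max_mismatch_frac`` raises :class:`ModelQualityError`.  Junctions
    with no GT..AG offset within ``refine_window`` of the anchor boundary
    take the maximal-score boundary and are flagged non-canonical.
    """
    C, G = cdna.residues, genomic.residues
    if len(C) > len(G):
        raise UnalignableError(
            f"cDNA {cdna.id} longer than genomic {genomic.id}")
    chain = _chain_blocks(_anchor_blocks(C, G, k))
    if not chain:
        raise UnalignableError(
            f"no colinear anchor chain between {cdna.id} and {genomic.id}")
    # compress chain entries sharing an offset into segments
    segments: list[tuple[int, int, int]] = []
    for d, cs, ce in chain:
        if segments and segments[-1][0] == d:
            segments[-1] = (d, segments[-1][1], ce)
        else:
            segments.append((d, cs, ce))
    if segments[0][0] < 0 or len(C) + segments[-1][0] > len(G):
        raise UnalignableError(
            f"anchor chain maps {cdna.id} outside {genomic.id}")

    boundaries = [0]
    canonical_flags = []
    for (d1, _, e1), (d2, s2, _) in zip(segments, segments[1:]):
        lo = max(boundaries[-1] + min_exon, min(e1, s2) - refine_window)
        hi = min(max(e1, s2) + refine_window, len(C) - min_exon)
        x, canon = _refine_junction(C, G, d1, d2, lo, hi, refine_window)
        boundaries.append(x)
        canonical_flags.append(canon)
    boundaries.append(len(C))

    exons = []
    for (d, _, _), a, b in zip(segments, boundaries, boundaries[1:]):
        exons.append((a + d, b + d))
    model = GeneModel(seq_id=genomic.id, exons=exons,
                      cds_start=0, cds_end=len(C))
    for intron, canon in zip(model.introns, canonical_flags):
        intron.canonical = canon
    annotate_introns(model, genomic)

    spliced = "".join(G[s:e] for s, e in exons)
    mism = sum(1 for x, y in zip(spliced, C) if x != y)
    mism += abs(len(spliced) - len(C))
    if mism / len(C) > max_mismatch_frac:
        raise ModelQualityError(
            f"{genomic.id}: reconstruction mismatch {mism}/{len(C)} "
            f"exceeds tolerance {max_mismatch_frac}")
    return model


# ---------------------------------------------------------------------------
# intron annotation, phases, protosplice classes
# ---------------------------------------------------------------------------

def annotate_introns(model: GeneModel, genomic: SequenceRecord) -> None:
    """Fill donor/acceptor dinucleotides and exonic flanks on each intron."""
    G = genomic.residues
    for idx, intron in enumerate(model.introns):
        up_start = model.exons[idx][0]
        intron.donor_dinuc = G[intron.start:intron.start + 2]
        intron.acceptor_dinuc = G[intron.end - 2:intron.end]
        if intron.start - up_start >= 3:
            intron.flank_5prime = G[intron.start - 3:intron.start]
        down_s, down_e = model.exons[idx + 1]
        if down_e > down_s:
            intron.flank_3prime = G[down_s]


def compute_phases(model: GeneModel) -> list[int]:
    """Intron phases: coding nucleotides upstream of each junction, counted
    from ``cds_start``, mod 3.  Junctions outside the CDS are phased
    relative to the nearest CDS edge and flagged non-coding."""
    phases = []
    for intron, p in zip(model.introns, model.junctions_cdna()):
        if p < model.cds_start:
            phase = (model.cds_start - p) % 3
            coding = False
        elif p > model.cds_end:
            phase = (p - model.cds_end) % 3
            coding = False
        else:
            phase = (p - model.cds_start) % 3
            coding = True
        intron.phase = phase
        intron.coding = coding
        phases.append(phase)
    return phases


def classify_protosplice(model: GeneModel, genomic: SequenceRecord
                         ) -> list[str | None]:
    """Classify each intron's exonic insertion context.

    With T the last 3 exonic nt upstream, X its last nt and Y the first
    exonic nt downstream: PROTOSPLICE iff T matches (A/C)AG and Y is G;
    else N_G iff X≠G and Y is G; else G_N iff X is G; else N_N.  (A G|G
    context failing the (A/C)AG test classes as G_N: the upstream G takes
    precedence.)  Introns lacking a full flank are left unclassified.
    """
    annotate_introns(model, genomic)
    classes: list[str | None] = []
    for intron in model.introns:
        T, Y = intron.flank_5prime, intron.flank_3prime
        if len(T) < 3 or not Y:
            intron.proto_class = None
            classes.append(None)
            continue
        X = T[-1]
        if T[0] in "AC" and T[1] == "A" and T[2] == "G" and Y == "G":
            cls = "PROTOSPLICE"
        elif X != "G" and Y == "G":
            cls = "N_G"
        elif X == "G":
            cls = "G_N"
        else:
            cls = "N_N"
        intron.proto_class = cls
        classes.append(cls)
    return classes


# ---------------------------------------------------------------------------
# cross-species exon correspondence
# ---------------------------------------------------------------------------

@dataclass
class ExonCorrespondence:
    """Projection of every species' gene structure onto the reference cDNA.

    Positions are cDNA coordinates on the reference.  ``conserved``
    holds reference junctions shared (within the tolerance) by every
    species; per-species differences appear in ``gains`` (species-only
    junction, projected) and ``losses`` (reference junction absent from
    the species).
    """

    reference_species: str
    exon_map: dict[str, dict[int, list[int]]]
    conserved: set[int]
    gains: list[tuple[str, int]]
    losses: list[tuple[str, int]]


def _projection(aligned_sp: str, aligned_ref: str) -> list[int]:
    """Map each species-cDNA coordinate (0..len, junction semantics) to a
    reference-cDNA coordinate through the pairwise alignment."""
    proj = [0]
    ref_consumed = 0
    for a, b in zip(aligned_sp, aligned_ref):
        if b != "-":
            ref_consumed += 1
        if a != "-":
            proj.append(ref_consumed)
    return proj


def map_exon_correspondence(models: dict[str, GeneModel],
                            cdnas: dict[str, SequenceRecord],
                            reference_species: str,
                            tolerance: int = 6,
                            params: AlignParams | None = None
                            ) -> ExonCorrespondence:
    """Project intron positions of every species onto the reference cDNA.

    A species junction within ±``tolerance`` nt of a reference junction is
    the same intron position; reference-only positions are losses in that
    species, species-only positions are gains.
    """
    if reference_species not in models:
        raise ValidationError(f"{reference_species!r} not among models")
    ref_model = models[reference_species]
    ref_cdna = cdnas[reference_species]
    ref_junc = ref_model.junctions_cdna()
    ref_exon_spans = []
    acc = 0
    for s, e in ref_model.exons:
        ref_exon_spans.append((acc, acc + (e - s)))
        acc += e - s

    exon_map: dict[str, dict[int, list[int]]] = {}
    gains: list[tuple[str, int]] = []
    losses: list[tuple[str, int]] = []
    matched_by_species: dict[str, set[int]] = {}

    for species, model in models.items():
        if species == reference_species:
            proj = list(range(len(ref_cdna.residues) + 1))
        else:
            pw = global_align(cdnas[species], ref_cdna, params)
            proj = _projection(pw.aligned_a, pw.aligned_b)
        junctions = [proj[p] for p in model.junctions_cdna()]
        matched: set[int] = set()
        for jp in junctions:
            near = [rp for rp in ref_junc if abs(rp - jp) <= tolerance]
            if near:
                matched.add(min(near, key=lambda rp: abs(rp - jp)))
            else:
                gains.append((species, jp))
        matched_by_species[species] = matched
        for rp in ref_junc:
            if rp not in matched:
                losses.append((species, rp))
        # exon-to-reference-exon coverage
        spans = {}
        acc = 0
        for i, (s, e) in enumerate(model.exons):
            a, b = proj[acc], proj[acc + (e - s)]
            covered = [
                ri for ri, (rs, re) in enumerate(ref_exon_spans)
                if a < re and b > rs
            ]
            if not covered:
                covered = [min(
                    range(len(ref_exon_spans)),
                    key=lambda ri: abs(ref_exon_spans[ri][0] - a))]
            spans[i] = covered
            acc += e - s
        exon_map[species] = spans

    conserved = {
        rp for rp in ref_junc
        if all(rp in matched_by_species[sp] for sp in models)
    }
    # a position cannot be both gain and loss for the same species
    gains = [(sp, p) for sp, p in gains
             if all(not (sp == sp2 and abs(p - p2) <= tolerance)
                    for sp2, p2 in losses)]
    return ExonCorrespondence(
        reference_species=reference_species, exon_map=exon_map,
        conserved=conserved, gains=sorted(gains), losses=sorted(losses),
    )


# ---------------------------------------------------------------------------
# phase spectrum statistics
# ---------------------------------------------------------------------------

def phase_spectrum(models: list[GeneModel]) -> dict:
    """Pooled intron-phase spectrum with uniformity tests.

    Returns phase counts and proportions over all coding introns, the
    chi-square goodness-of-fit against (1/3, 1/3, 1/3), and the one-sided
    exact binomial p-value for an excess of phase-0 introns.
    """
    counts = np.zeros(3, dtype=int)
    for model in models:
        if any(i.phase is None for i in model.introns):
            compute_phases(model)
        for intron in model.introns:
            if intron.coding:
                counts[intron.phase] += 1
    n = int(counts.sum())
    if n == 0:
        raise ValidationError("phase_spectrum: no coding introns")
    chi2_stat, chi2_p = stats.chisquare(counts)
    binom_p = stats.binomtest(int(counts[0]), n, 1 / 3,
                              alternative="greater").pvalue
    return {
        "counts": counts.tolist(),
        "proportions": (counts / n).tolist(),
        "n_introns": n,
        "chi2_stat": float(chi2_stat),
        "chi2_p": float(chi2_p),
        "binom_p_phase0": float(binom_p),
    }
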