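"""ABC-transporter domain architecture and motif annotation.

Annotates the canonical TMD1-NBD1-linker-TMD2-NBD2 organisation of a
full-length ABCB protein, locates the six nucleotide-binding-domain motifs
(Walker A, Q-loop, ABC signature, Walker B, D-loop, H-loop) in each half,
tabulates inter-motif distances across species, and classifies the
amino-acid substitutions between the two NBDs as conservative or radical
using the substitution-matrix sign convention (score ≥ 1 ⇒ conservative).

Transmembrane helices are detected by Kyte–Doolittle sliding-window
hydropathy; the NBDs are anchored on their Walker A .. H-loop spans.
Protein coordinates are 0-based half-open internally; report serializers
convert to the 1-based convention used in the field's tables.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import OrthostructError, SequenceRecord, ValidationError
from .protein_consensus import (
    MSA,
    AlignParams,
    _matrix,
    alignment_identity,
    global_align,
)


class NotAnNBDError(OrthostructError):
    """Walker A absent from the scanned interval."""


class ArchitectureError(OrthostructError):
    """Protein lacks the two-NBD ABCB architecture."""


# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0, "*": 0.0,
}

MOTIF_ORDER = ["WalkerA", "Qloop", "ABCsignature", "WalkerB", "Dloop", "Hloop"]

DEFAULT_PATTERNS = {
    "WalkerA": r"[AG].{4}GK[ST]",
    "ABCsignature": ("LSGGQ", 1),      # (string, max mismatches)
    "WalkerB": r"[ILVFMA]{4}DE",
    "Dloop": ("SALD", 1),
    "Qloop_window": (25, 60),          # aa downstream of Walker A end
    "Hloop_window": (25, 45),          # aa downstream of Walker B end
}


@dataclass
class MotifHit:
    name: str
    start: int
    end: int
    matched: str
    domain: str = ""


@dataclass
class DomainArchitecture:
    """TMD1-NBD1-linker-TMD2-NBD2 spans plus helices and motif hits."""

    tmd1: tuple[int, int]
    nbd1: tuple[int, int]
    linker: tuple[int, int]
    tmd2: tuple[int, int]
    nbd2: tuple[int, int]
    tm_helices: list[tuple[int, int]] = field(default_factory=list)
    nbd1_hits: list[MotifHit] = field(default_factory=list)
    nbd2_hits: list[MotifHit] = field(default_factory=list)

    def spans(self) -> list[tuple[str, tuple[int, int]]]:
        return [("tmd1", self.tmd1), ("nbd1", self.nbd1),
                ("linker", self.linker), ("tmd2", self.tmd2),
                ("nbd2", self.nbd2)]

    @property
    def complete(self) -> bool:
        names1 = {h.name for h in self.nbd1_hits}
        names2 = {h.name for h in self.nbd2_hits}
        return set(MOTIF_ORDER) <= names1 and set(MOTIF_ORDER) <= names2


@dataclass
class SubstitutionRecord:
    nbd1_pos: int
    nbd2_pos: int
    aa1: str
    aa2: str
    klass: str  # identical / conservative / radical


# ---------------------------------------------------------------------------
# transmembrane scan
# ---------------------------------------------------------------------------

def tm_scan(protein: SequenceRecord, window: int = 19,
            threshold: float = 1.6, min_len: int = 15,
            merge_gap: int = 5) -> list[tuple[int, int]]:
    """Kyte–Doolittle sliding-window transmembrane helix detection.

    Mean hydropathy over ``window`` residues; maximal supra-threshold runs
    become helix intervals, runs separated by < ``merge_gap`` aa are
    merged, intervals shorter than ``min_len`` dropped.
    """
    seq = protein.residues
    if len(seq) <= window:
        raise ValidationError(
            f"{protein.id}: length {len(seq)} ≤ window {window}")
    values = np.array([_KD[a] for a in seq])
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")
    above = means >= threshold
    intervals = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((start, i - 1 + window))
            start = None
    if start is not None:
        intervals.append((start, len(above) - 1 + window))
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_len]


# ---------------------------------------------------------------------------
# NBD motif scan
# ---------------------------------------------------------------------------

def _approx_find(seq: str, pattern: str, max_mismatch: int, start: int
                 ) -> int | None:
    """Leftmost position ≥ start where ``pattern`` matches with at most
    ``max_mismatch`` mismatching residues."""
    L = len(pattern)
    for p in range(start, len(seq) - L + 1):
        mism = 0
        for a, b in zip(seq[p:p + L], pattern):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return p
    return None


def scan_nbd_motifs(protein: SequenceRecord,
                    search_interval: tuple[int, int] | None = None,
                    patterns: dict | None = None) -> list[MotifHit]:
    """Locate the six NBD motifs within ``search_interval``.

    Motifs are found sequentially left to right (Walker A first; the
    Q-loop is the leftmost invariant Q in its window after Walker A, the
    H-loop the leftmost H in its window after Walker B), which guarantees
    the canonical ordering.  A missing Walker A raises
    :class:`NotAnNBDError`; any other missing motif yields a partial hit
    list.
    """
    patterns = {**DEFAULT_PATTERNS, **(patterns or {})}
    lo, hi = search_interval or (0, len(protein.residues))
    if lo < 0 or hi > len(protein.residues):
        raise ValidationError("search interval outside protein")
    seq = protein.residues
    region = seq[lo:hi]
    hits: list[MotifHit] = []

    m = re.search(patterns["WalkerA"], region)
    if m is None:
        raise NotAnNBDError(
            f"{protein.id}: no Walker A in [{lo},{hi}): not an NBD")
    wa = MotifHit("WalkerA", lo + m.start(), lo + m.end(), m.group())
    hits.append(wa)

    qlo, qhi = patterns["Qloop_window"]
    q_pos = None
    for p in range(wa.end + qlo, min(wa.end + qhi + 1, hi)):
        if seq[p] == "Q":
            q_pos = p
            break
    if q_pos is not None:
        hits.append(MotifHit("Qloop", q_pos, q_pos + 1, "Q"))
    cursor = (q_pos + 1) if q_pos is not None else wa.end

    sig, mm = patterns["ABCsignature"]
    p = _approx_find(seq[:hi], sig, mm, cursor)
    if p is not None:
        hits.append(MotifHit("ABCsignature", p, p + len(sig),
                             seq[p:p + len(sig)]))
        cursor = p + len(sig)

    m = re.compile(patterns["WalkerB"]).search(region, cursor - lo)
    wb = None
    if m is not None:
        wb = MotifHit("WalkerB", lo + m.start(), lo + m.end(), m.group())
        hits.append(wb)
        cursor = wb.end

    dl, dmm = patterns["Dloop"]
    p = _approx_find(seq[:hi], dl, dmm, cursor)
    if p is not None:
        hits.append(MotifHit("Dloop", p, p + len(dl), seq[p:p + len(dl)]))
        cursor = p + len(dl)

    if wb is not None:
        hlo, hhi = patterns["Hloop_window"]
        for p in range(wb.end + hlo, min(wb.end + hhi + 1, hi)):
            if seq[p] == "H":
                hits.append(MotifHit("Hloop", p, p + 1, "H"))
                break
    return hits


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def annotate_architecture(protein: SequenceRecord, nbd_pad: int = 30,
                          nbd_span: int = 400,
                          patterns: dict | None = None,
                          tm_kwargs: dict | None = None
                          ) -> DomainArchitecture:
    """Anchor NBD1/NBD2 on the two Walker A .. H-loop spans and place the
    TMDs and linker around them."""
    patterns = {**DEFAULT_PATTERNS, **(patterns or {})}
    wa_re = re.compile(patterns["WalkerA"])
    wa_starts = [m.start() for m in wa_re.finditer(protein.residues)]
    if len(wa_starts) < 2:
        raise ArchitectureError(
            f"{protein.id}: {len(wa_starts)} Walker A match(es); "
            "two NBDs required")

    def scan_from(start: int) -> list[MotifHit]:
        hi = min(start + nbd_span, len(protein.residues))
        return scan_nbd_motifs(protein, (start, hi), patterns)

    hits1 = scan_from(wa_starts[0])
    end1 = max(h.end for h in hits1)
    next_wa = [s for s in wa_starts if s >= end1]
    if not next_wa:
        raise ArchitectureError(f"{protein.id}: no second NBD after {end1}")
    hits2 = scan_from(next_wa[0])
    end2 = max(h.end for h in hits2)
    for h in hits1:
        h.domain = "NBD1"
    for h in hits2:
        h.domain = "NBD2"

    nbd1 = (max(hits1[0].start - nbd_pad, 0), min(end1 + nbd_pad,
                                                  len(protein.residues)))
    nbd2 = (max(hits2[0].start - nbd_pad, nbd1[1]),
            min(end2 + nbd_pad, len(protein.residues)))

    helices = tm_scan(protein, **(tm_kwargs or {}))
    before = [h for h in helices if h[1] <= nbd1[0]]
    between = [h for h in helices if h[0] >= nbd1[1] and h[1] <= nbd2[0]]
    if not before or not between:
        raise ArchitectureError(
            f"{protein.id}: missing TMD helices "
            f"({len(before)} before NBD1, {len(between)} before NBD2)")
    tmd1 = (before[0][0], before[-1][1])
    tmd2 = (between[0][0], between[-1][1])
    linker = (nbd1[1], tmd2[0])
    if linker[1] <= linker[0]:
        raise ArchitectureError(f"{protein.id}: no linker between NBD1 and TMD2")
    return DomainArchitecture(
        tmd1=tmd1, nbd1=nbd1, linker=linker, tmd2=tmd2, nbd2=nbd2,
        tm_helices=helices, nbd1_hits=hits1, nbd2_hits=hits2,
    )


# ---------------------------------------------------------------------------
# inter-motif distances
# ---------------------------------------------------------------------------

def motif_distance_table(hits_by_species: dict[str, list[MotifHit]],
                         conserved_range: int = 2
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inter-motif gaps (aa) per species with cross-species ranges.

    The gap between consecutive motifs is ``next.start − prev.end``.  A
    gap whose cross-species range is ≤ ``conserved_range`` aa (the small
    variation observed between orthologs) is flagged conserved.  Missing
    motifs yield absent (NaN) gaps.
    """
    rows = {}
    for species, hits in hits_by_species.items():
        by_key = {(h.domain, h.name): h for h in hits}
        row = {}
        for domain in ("NBD1", "NBD2"):
            for a, b in zip(MOTIF_ORDER, MOTIF_ORDER[1:]):
                ha, hb = by_key.get((domain, a)), by_key.get((domain, b))
                row[f"{domain}:{a}-{b}"] = (
                    hb.start - ha.end if ha and hb else np.nan)
        rows[species] = row
    table = pd.DataFrame(rows).T
    table.index.name = "species"
    summary = pd.DataFrame({
        "min": table.min(axis=0),
        "max": table.max(axis=0),
    })
    summary["range"] = summary["max"] - summary["min"]
    summary["conserved"] = summary["range"] <= conserved_range
    summary.index.name = "gap"
    return table, summary


# ---------------------------------------------------------------------------
# NBD1 vs NBD2 comparison
# ---------------------------------------------------------------------------

def classify_substitution(aa1: str, aa2: str,
                          matrix_name: str = "BLOSUM62") -> str:
    """identical / conservative (matrix score ≥ 1) / radical.

    This amino-acid-level rule reproduces the field's serine/alanine =
    conservative, serine/proline and serine/cysteine = radical calls.
    """
    if aa1 == aa2:
        return "identical"
    B = _matrix(matrix_name)
    return "conservative" if B[aa1, aa2] >= 1 else "radical"


def compare_nbd_halves(protein: SequenceRecord, arch: DomainArchitecture,
                       params: AlignParams | None = None
                       ) -> dict:
    """Globally align the two NBD subsequences and classify every mismatch."""
    s1, e1 = arch.nbd1
    s2, e2 = arch.nbd2
    nbd1 = SequenceRecord(id=f"{protein.id}.nbd1",
                          residues=protein.residues[s1:e1],
                          alphabet="protein")
    nbd2 = SequenceRecord(id=f"{protein.id}.nbd2",
                          residues=protein.residues[s2:e2],
                          alphabet="protein")
    pw = global_align(nbd1, nbd2, params)
    records: list[SubstitutionRecord] = []
    p1, p2 = s1, s2
    for a, b in zip(pw.aligned_a, pw.aligned_b):
        if a != "-" and b != "-" and a != b:
            records.append(SubstitutionRecord(
                nbd1_pos=p1, nbd2_pos=p2, aa1=a, aa2=b,
                klass=classify_substitution(a, b)))
        if a != "-":
            p1 += 1
        if b != "-":
            p2 += 1
    return {
        "identity": alignment_identity(pw.aligned_a, pw.aligned_b),
        "records": records,
    }


# ---------------------------------------------------------------------------
# group-specific conserved motifs
# ---------------------------------------------------------------------------

@dataclass
class GroupMotif:
    group: str
    start: int      # MSA column
    end: int
    consensus: str


def find_conserved_motifs(msa: MSA, min_len: int = 6, max_mismatch: int = 0,
                          max_len: int = 15) -> list[GroupMotif]:
    """Group-specific conserved windows in an aligned family.

    A window of ``min_len``..``max_len`` columns is reported for a group
    when every member of that group carries the same gap-free residues
    (at most ``max_mismatch`` disagreeing columns) while every member of
    the other group differs from the group consensus in more than
    ``max_mismatch`` columns.  Maximal windows only.
    """
    groups: dict[str, list[str]] = {}
    for rec, row in zip(msa.records, msa.aligned):
        groups.setdefault(rec.group.value, []).append(row)
    if len(groups) < 2:
        return []
    names = sorted(groups)
    out: list[GroupMotif] = []
    ncol = msa.n_columns
    for g in names:
        others = [o for o in names if o != g]
        rows = groups[g]
        if len(rows) < 2:
            continue
        cons = []
        agree = np.zeros(ncol, dtype=bool)
        for c in range(ncol):
            col = {row[c] for row in rows}
            ok = len(col) == 1 and "-" not in col
            agree[c] = ok
            cons.append(rows[0][c] if ok else "?")
        accepted: list[tuple[int, int]] = []
        for L in range(max_len, min_len - 1, -1):
            for s in range(0, ncol - L + 1):
                e = s + L
                if any(a <= s and e <= b for a, b in accepted):
                    continue
                if int((~agree[s:e]).sum()) > max_mismatch:
                    continue
                window = cons[s:e]
                absent = True
                for o in others:
                    for row in groups[o]:
                        mism = sum(
                            1 for c in range(s, e)
                            if row[c] != window[c - s])
                        if mism <= max_mismatch:
                            absent = False
                            break
                    if not absent:
                        break
                if absent:
                    accepted.append((s, e))
        for s, e in sorted(accepted):
            out.append(GroupMotif(group=g, start=s, end=e,
                                  consensus="".join(cons[s:e])))
    return out
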