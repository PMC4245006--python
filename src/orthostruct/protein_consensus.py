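"""Pairwise and progressive multiple alignment, identity matrices, and
consensus construction with group-wise similarity scoring.

Pairwise alignment is global Needleman–Wunsch with affine gaps
(BLOSUM62 for protein, +2/−3 for DNA, gap open 10 / extend 0.5 — a gap of
length L costs open + (L−1)·extend).  The multiple alignment is classic
guide-tree progressive profile alignment: neighbor-joining agglomeration
order on pairwise identity distances, profiles merged by sum-of-pairs
Needleman–Wunsch.

Identity convention used throughout: identical residues divided by aligned
columns excluding dual-gap columns; a gap aligned to a residue counts as a
mismatch.  This choice is repeated in every report footer the pipeline
writes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

from .core_io import Group, SequenceRecord, ValidationError

IDENTITY_FOOTNOTE = (
    "identity = identical residues / aligned columns excluding dual-gap "
    "columns; gap-vs-residue columns count as mismatches"
)


@dataclass
class AlignParams:
    """Scoring parameters for pairwise and profile alignment."""

    gap_open: float = 10.0
    gap_extend: float = 0.5
    dna_match: float = 2.0
    dna_mismatch: float = -3.0
    matrix_name: str = "BLOSUM62"


@dataclass
class PairwiseAlignment:
    a_id: str
    b_id: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


@dataclass
class MSA:
    """A multiple sequence alignment: parallel records and gapped rows."""

    records: list[SequenceRecord]
    aligned: list[str]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.aligned):
            raise ValidationError("records/aligned length mismatch")
        widths = {len(a) for a in self.aligned}
        if len(widths) > 1:
            raise ValidationError("ragged alignment")

    @property
    def n_columns(self) -> int:
        return len(self.aligned[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def row(self, species: str) -> str:
        for rec, a in zip(self.records, self.aligned):
            if rec.species == species or rec.id == species:
                return a
        raise KeyError(species)


_MATRICES: dict[str, object] = {}


def _matrix(name: str):
    if name not in _MATRICES:
        _MATRICES[name] = substitution_matrices.load(name)
    return _MATRICES[name]


def _aligner(alphabet: str, params: AlignParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    if alphabet == "protein":
        al.substitution_matrix = _matrix(params.matrix_name)
    else:
        al.match_score = params.dna_match
        al.mismatch_score = params.dna_mismatch
    al.open_gap_score = -params.gap_open
    al.extend_gap_score = -params.gap_extend
    return al


def alignment_identity(aligned_a: str, aligned_b: str) -> float:
    """Identity under the package convention (see module docstring)."""
    matches = denom = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            continue
        denom += 1
        if x == y:
            matches += 1
    if denom == 0:
        raise ValidationError("no comparable columns")
    return matches / denom


def global_align(a: SequenceRecord, b: SequenceRecord,
                 params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two same-alphabet records."""
    if a.alphabet != b.alphabet:
        raise ValidationError(
            f"alphabet mismatch: {a.id} is {a.alphabet}, {b.id} is {b.alphabet}"
        )
    params = params or AlignParams()
    al = _aligner(a.alphabet, params)
    best = al.align(a.residues, b.residues)[0]
    ga, gb = str(best[0]), str(best[1])
    return PairwiseAlignment(
        a_id=a.id, b_id=b.id, aligned_a=ga, aligned_b=gb,
        score=float(best.score), identity=alignment_identity(ga, gb),
    )


def identity_matrix(records: list[SequenceRecord],
                    params: AlignParams | None = None) -> pd.DataFrame:
    """Symmetric pairwise identity matrix (unit diagonal), aligned once per
    pair.  Indexed by record id."""
    if len(records) < 2:
        raise ValidationError("identity_matrix needs ≥ 2 records")
    ids = [r.id for r in records]
    m = np.eye(len(records))
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            ident = global_align(records[i], records[j], params).identity
            m[i, j] = m[j, i] = ident
    return pd.DataFrame(m, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

_PROFILE_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(_PROFILE_ALPHABET)}


@njit(cache=False)
def _gotoh(S, go, ge):  # pragma: no cover - exercised via progressive_msa
    """Affine-gap DP over a column-score matrix; returns traceback arrays."""
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)   # gap columns in B (A row consumed)
    Y = np.full((n + 1, m + 1), NEG)   # gap columns in A
    tM = np.zeros((n + 1, m + 1), dtype=np.int8)
    tX = np.zeros((n + 1, m + 1), dtype=np.int8)
    tY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + (i - 1) * ge)
        tX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -(go + (j - 1) * ge)
        tY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M
            best, arg = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, arg = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, arg = Y[i - 1, j - 1], 2
            M[i, j] = best + S[i - 1, j - 1]
            tM[i, j] = arg
            # X: consume A row i
            best, arg = M[i - 1, j] - go, 0
            if X[i - 1, j] - ge > best:
                best, arg = X[i - 1, j] - ge, 1
            if Y[i - 1, j] - go > best:
                best, arg = Y[i - 1, j] - go, 2
            X[i, j] = best
            tX[i, j] = arg
            # Y: consume B column j
            best, arg = M[i, j - 1] - go, 0
            if X[i, j - 1] - go > best:
                best, arg = X[i, j - 1] - go, 1
            if Y[i, j - 1] - ge > best:
                best, arg = Y[i, j - 1] - ge, 2
            Y[i, j] = best
            tY[i, j] = arg
    return M, X, Y, tM, tX, tY


def _profile_counts(rows: list[str]) -> np.ndarray:
    counts = np.zeros((len(rows[0]), len(_PROFILE_ALPHABET)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                counts[j, _AA_INDEX.get(ch, _AA_INDEX["X"])] += 1
    return counts


def _merge_profiles(rows_a: list[str], rows_b: list[str],
                    B: np.ndarray, params: AlignParams
                    ) -> tuple[list[str], list[str]]:
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    S = (ca @ B @ cb.T) / (len(rows_a) * len(rows_b))
    M, X, Y, tM, tX, tY = _gotoh(S, params.gap_open, params.gap_extend)
    n, m = S.shape
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    i, j = n, m
    moves = []  # 0 diag, 1 A-only, 2 B-only
    while i > 0 or j > 0:
        if state == 0:
            moves.append(0)
            state = tM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            moves.append(1)
            state = tX[i, j]
            i -= 1
        else:
            moves.append(2)
            state = tY[i, j]
            j -= 1
    moves.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for mv in moves:
        if mv in (0, 1):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if mv in (0, 2):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def _nj_join_order(d: np.ndarray) -> list[tuple[int, int]]:
    """Neighbor-joining agglomeration order (lowest-index tie-break).

    Returns successive (i, j) pairs over a working list in which the joined
    cluster replaces index min(i, j) and index max(i, j) is removed.
    """
    active = list(range(len(d)))
    dm = d.copy().astype(float)
    order = []
    while len(active) > 2:
        n = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        i, j = sorted(divmod(flat, n))
        ai, aj = active[i], active[j]
        # distance of the new cluster to the rest (standard NJ update)
        for k in range(n):
            if k in (i, j):
                continue
            ak = active[k]
            dm[ai, ak] = dm[ak, ai] = 0.5 * (
                sub[i, k] + sub[j, k] - sub[i, j])
        order.append((ai, aj))
        active.remove(aj)
    if len(active) == 2:
        order.append((active[0], active[1]))
    return order


def progressive_msa(records: list[SequenceRecord],
                    params: AlignParams | None = None) -> MSA:
    """Guide-tree progressive multiple alignment.

    The guide order is the NJ agglomeration sequence on pairwise identity
    distances (d = 1 − identity); profiles are merged by sum-of-pairs
    Needleman–Wunsch with affine gaps.  Deterministic for fixed input.
    """
    if len(records) < 2:
        raise ValidationError("progressive_msa needs ≥ 2 records")
    params = params or AlignParams()
    B = np.asarray(_matrix(params.matrix_name))

    n = len(records)
    d = np.zeros((n, n))
    pair_cache: dict[tuple[int, int], PairwiseAlignment] = {}
    for i in range(n):
        for j in range(i + 1, n):
            pw = global_align(records[i], records[j], params)
            pair_cache[(i, j)] = pw
            d[i, j] = d[j, i] = 1.0 - pw.identity

    if n == 2:
        pw = pair_cache[(0, 1)]
        return MSA(records=list(records),
                   aligned=[pw.aligned_a, pw.aligned_b])

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].residues]) for i in range(n)
    }
    for i, j in _nj_join_order(d):
        idx_a, rows_a = clusters[i]
        idx_b, rows_b = clusters[j]
        out_a, out_b = _merge_profiles(rows_a, rows_b, B, params)
        clusters[i] = (idx_a + idx_b, out_a + out_b)
        del clusters[j]
    (_, (index_order, rows)), = clusters.items()
    aligned = [""] * n
    for k, idx in enumerate(index_order):
        aligned[idx] = rows[k]
    return MSA(records=list(records), aligned=aligned)


# ---------------------------------------------------------------------------
# consensus and similarity tracks
# ---------------------------------------------------------------------------

@dataclass
class ConsensusProfile:
    """Per-column consensus residue and group similarity counts.

    ``monocot_similarity`` counts monocot taxa matching the consensus at
    each column (0..n_monocots; the study design has six), and likewise
    ``dicot_similarity`` for dicots (0..n_dicots; two in the study design).
    """

    consensus: str
    monocot_similarity: list[int]
    dicot_similarity: list[int]
    deletion_flags: dict[str, np.ndarray]
    reference_species: str
    msa: MSA = field(repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.consensus)

    def to_dataframe(self) -> pd.DataFrame:
        rows = {
            "column": np.arange(1, self.n_columns + 1),
            "consensus_aa": list(self.consensus),
            "monocot_score": self.monocot_similarity,
            "dicot_score": self.dicot_similarity,
        }
        for rec, aligned in zip(self.msa.records, self.msa.aligned):
            rows[rec.species or rec.id] = list(aligned)
        return pd.DataFrame(rows)


def build_consensus(msa: MSA, reference_species: str) -> ConsensusProfile:
    """Majority-rule consensus with reference-breaks-ties rules.

    Per column the consensus is the modal non-gap residue.  When all
    residues are mutually distinct the reference residue is used; if the
    reference is gapped in such a column, the lexicographically smallest
    residue.  Among equally-modal residues the reference residue wins when
    it is one of the modes, else the lexicographically smallest mode.
    Insertion columns (reference gapped, others not) are retained.
    """
    try:
        ref_row = msa.row(reference_species)
    except KeyError:
        raise ValidationError(
            f"reference species {reference_species!r} absent from MSA")
    groups = [rec.group for rec in msa.records]
    consensus: list[str] = []
    mono_scores: list[int] = []
    di_scores: list[int] = []
    for col in range(msa.n_columns):
        residues = [row[col] for row in msa.aligned]
        non_gap = [r for r in residues if r != "-"]
        counts: dict[str, int] = {}
        for r in non_gap:
            counts[r] = counts.get(r, 0) + 1
        if not counts:
            raise ValidationError(f"column {col}: all residues are gaps")
        top = max(counts.values())
        modes = sorted(r for r, c in counts.items() if c == top)
        ref_res = ref_row[col]
        if top == 1:
            cons = ref_res if ref_res != "-" else modes[0]
        elif ref_res in modes:
            cons = ref_res
        else:
            cons = modes[0]
        consensus.append(cons)
        mono_scores.append(sum(
            1 for r, g in zip(residues, groups)
            if g is Group.MONOCOT and r == cons))
        di_scores.append(sum(
            1 for r, g in zip(residues, groups)
            if g is Group.DICOT and r == cons))
    deletion_flags = {
        (rec.species or rec.id): np.array(
            [row[c] == "-" for c in range(msa.n_columns)])
        for rec, row in zip(msa.records, msa.aligned)
    }
    return ConsensusProfile(
        consensus="".join(consensus),
        monocot_similarity=mono_scores,
        dicot_similarity=di_scores,
        deletion_flags=deletion_flags,
        reference_species=reference_species,
        msa=msa,
    )


def deletion_tracks(msa: MSA, profile: ConsensusProfile
                    ) -> dict[str, list[tuple[int, int]]]:
    """Maximal per-species deletion runs vs the consensus.

    Returns, per species, a list of ``(start_column, length)`` intervals in
    consensus (column) coordinates.
    """
    tracks: dict[str, list[tuple[int, int]]] = {}
    for species, flags in profile.deletion_flags.items():
        runs = []
        start = None
        for c, is_gap in enumerate(flags):
            if is_gap and start is None:
                start = c
            elif not is_gap and start is not None:
                runs.append((start, c - start))
                start = None
        if start is not None:
            runs.append((start, len(flags) - start))
        tracks[species] = runs
    return tracks
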