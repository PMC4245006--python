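"""Distance-based phylogeny: p-distances, canonical neighbor joining, and
bootstrap support by column resampling.

The distance is the uncorrected p-distance (fraction of differing sites
among pairwise-comparable columns, gap columns excluded per pair), matching
the default of the distance-matrix NJ protocol the analysis reproduces.
Negative NJ branch-length estimates are clamped to 0 and flagged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import OrthostructError, ValidationError
from .protein_consensus import MSA

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("non-zero diagonal")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root node."""

    root: TreeNode
    taxa: list[str]
    negative_clamped: bool = False

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _encode_msa(msa: MSA) -> np.ndarray:
    """Rows as int8 codes; gaps encoded as -1."""
    arr = np.frombuffer("".join(msa.aligned).encode(), dtype=np.uint8)
    arr = arr.reshape(len(msa.aligned), msa.n_columns).astype(np.int16)
    arr[arr == ord("-")] = -1
    return arr


def _pdist_from_codes(codes: np.ndarray, taxa: list[str]) -> np.ndarray:
    n = codes.shape[0]
    d = np.zeros((n, n))
    valid_mask = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            valid = valid_mask[i] & valid_mask[j]
            nv = int(valid.sum())
            if nv == 0:
                raise OrthostructError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}")
            mism = int(np.count_nonzero(codes[i][valid] != codes[j][valid]))
            d[i, j] = d[j, i] = mism / nv
    return d


def p_distance(msa: MSA) -> DistanceMatrix:
    """Pairwise p-distances over an MSA (≥ 3 taxa)."""
    if len(msa.aligned) < 3:
        raise ValidationError("p_distance needs ≥ 3 taxa")
    codes = _encode_msa(msa)
    taxa = [r.species or r.id for r in msa.records]
    return DistanceMatrix(taxa=taxa, d=_pdist_from_codes(codes, taxa))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_build(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou–Nei neighbor joining.

    Deterministic: ties in the Q criterion resolve to the lowest index
    pair.  Negative branch estimates are clamped to 0 and flagged on the
    returned tree.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValidationError("nj_build needs ≥ 3 taxa")
    d = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    clamped = False

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = sorted(divmod(int(np.argmin(q)), m))
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamp(li)
        child_j.length = _clamp(lj)
        parent = TreeNode(children=[child_i, child_j])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d[i, :] = dk
        d[:, i] = dk
        d[i, i] = 0.0
        nodes[i] = parent
        d = np.delete(np.delete(d, j, axis=0), j, axis=1)
        del nodes[j]

    l0 = _clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    l1 = _clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    l2 = _clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = ln
    root = TreeNode(children=list(nodes))
    return PhyloTree(root=root, taxa=list(dm.taxa), negative_clamped=clamped)


# ---------------------------------------------------------------------------
# bipartitions and bootstrap
# ---------------------------------------------------------------------------

def bipartitions(tree: PhyloTree) -> dict[frozenset[str], TreeNode]:
    """Non-trivial bipartitions keyed by their normalized leaf-name side.

    Normalization: the side not containing the first taxon, making the
    keys orientation-invariant for comparison across replicate trees.
    """
    all_taxa = frozenset(tree.taxa)
    anchor = tree.taxa[0]
    out: dict[frozenset[str], TreeNode] = {}

    def visit(node: TreeNode) -> None:
        for child in node.children:
            if not child.is_leaf:
                side = child.leaf_names()
                if anchor in side:
                    side = all_taxa - side
                if 2 <= len(side) <= len(all_taxa) - 2:
                    out[side] = child
                visit(child)

    visit(tree.root)
    return out


def bootstrap_support(msa: MSA, n_reps: int = 1000, seed: int = 0,
                      ) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Support on each internal edge is the percentage of replicate NJ trees
    (columns resampled with replacement) containing the original
    bipartition.  Deterministic for a fixed seed.  When all sequences are
    identical (zero distances throughout) supports are defined as 100 on
    the degenerate star topology, by convention.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be ≥ 1")
    codes = _encode_msa(msa)
    taxa = [r.species or r.id for r in msa.records]
    base = nj_build(DistanceMatrix(taxa=taxa,
                                   d=_pdist_from_codes(codes, taxa)))
    base_bip = bipartitions(base)
    if np.all(_pdist_from_codes(codes, taxa) == 0.0):
        for node in base_bip.values():
            node.support = 100.0
        return base
    counts = {key: 0 for key in base_bip}
    rng = np.random.default_rng(seed)
    ncol = codes.shape[1]
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rep_codes = codes[:, idx]
        try:
            rep_d = _pdist_from_codes(rep_codes, taxa)
        except OrthostructError:
            continue  # a pair lost all comparable columns in this draw
        rep = nj_build(DistanceMatrix(taxa=taxa, d=rep_d))
        rep_bip = bipartitions(rep)
        for key in counts:
            if key in rep_bip:
                counts[key] += 1
    for key, node in base_bip.items():
        node.support = 100.0 * counts[key] / n_reps
    return base


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def to_newick(tree: PhyloTree) -> str:
    """Newick string with 6-significant-digit branch lengths and bootstrap
    supports as internal node labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:g}"
        return f"({inner}){label}:{node.length:.6g}"

    inner = ",".join(fmt(c) for c in tree.root.children)
    return f"({inner});"
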