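"""Neighbor-joining trees, nonparametric bootstrap supports, monophyly tests.

The Saitou–Nei agglomeration is run on the Q-criterion

    Q_ij = (n - 2) d_ij - r_i - r_j,      r_i = sum_k d_ik

joining the pair minimising Q at each step (ties broken toward the
lowest (i, j) index pair, so results are deterministic).  Negative branch
lengths, an artefact NJ can produce on non-additive matrices, are clamped
to zero by default.

Bootstrap supports are classic Felsenstein bipartition supports: columns
of the (complete-deletion filtered) alignment are resampled with
replacement, the K2P + NJ estimate recomputed, and each internal edge of
the point-estimate tree scored by the percentage of replicates whose
tree contains the same bipartition.  Replicates in which some pair
saturates are dropped (and counted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .distances import DistanceMatrix, _counts_complete, _k2p_array, _pair_index, distance_matrix
from .errors import LabelingError, TrivialTreeError
from .seqio import BarcodeAlignment


@dataclass
class Clade:
    """A node of the (unrooted, trifurcating-root) NJ tree."""

    name: Optional[str] = None            # leaf name; None for internal nodes
    length: float = 0.0                   # branch length to the parent
    support: Optional[float] = None       # bootstrap % on the edge above (internal only)
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class SupportTree:
    """Unrooted NJ topology with branch lengths and optional supports."""

    root: Clade                            # trifurcating for n >= 3
    ids: list[str]

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def _edges(self) -> list[Clade]:
        """All non-root clades (each defines the edge to its parent)."""
        out: list[Clade] = []

        def walk(node: Clade):
            for c in node.children:
                out.append(c)
                walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset, Clade]:
        """Internal-edge bipartitions, canonicalised to the side *not*
        containing the first taxon, keyed by that leaf set."""
        full = frozenset(self.ids)
        ref = self.ids[0]
        out: dict[frozenset, Clade] = {}
        for clade in self._edges():
            side = frozenset(clade.leaves())
            if len(side) < 2 or len(side) > len(full) - 2:
                continue  # trivial edge
            if ref in side:
                side = full - side
            out[side] = clade
        return out

    def edge_sides(self) -> list[frozenset]:
        """Leaf sets under every edge (including trivial leaf edges)."""
        return [frozenset(c.leaves()) for c in self._edges()]

    def distance_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length (patristic) distances."""
        ids = self.leaves()
        pos = {sid: k for k, sid in enumerate(ids)}
        n = len(ids)
        D = np.zeros((n, n))

        def walk(node: Clade) -> dict[int, float]:
            if node.is_leaf:
                return {pos[node.name]: 0.0}
            below: dict[int, float] = {}
            child_maps = []
            for c in node.children:
                cm = {k: v + c.length for k, v in walk(c).items()}
                child_maps.append(cm)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for ka, va in child_maps[a].items():
                        for kb, vb in child_maps[b].items():
                            D[ka, kb] = D[kb, ka] = va + vb
            for cm in child_maps:
                below.update(cm)
            return below

        walk(self.root)
        return DistanceMatrix(ids=ids, d=D)

    def to_newick(self, include_support: bool = True, decimals: int = 6) -> str:
        def fmt(node: Clade) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.{decimals}f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.{decimals}f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def write_newick(self, path, include_support: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(include_support=include_support) + "\n")

    def write_nexus(self, path, include_support: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write("#NEXUS\nbegin trees;\n")
            fh.write(f"  tree nj = [&U] {self.to_newick(include_support)}\n")
            fh.write("end;\n")


def nj(dm: DistanceMatrix, clamp: bool = True) -> SupportTree:
    """Saitou–Nei neighbor joining.

    Deterministic: Q ties resolve to the lowest (i, j) pair in current
    matrix order.  ``clamp=False`` keeps negative branch-length estimates.
    """
    n = dm.n
    if n < 3:
        raise TrivialTreeError("neighbor joining needs at least three taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")

    D = dm.d.astype(float).copy()
    nodes: list[Clade] = [Clade(name=sid) for sid in dm.ids]

    def _clip(x: float) -> float:
        return max(x, 0.0) if clamp else x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin -> lowest i, then lowest j on exact ties
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clip(li)
        child_j.length = _clip(lj)
        new = Clade(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = new
        del nodes[j]

    # final three-way join via the three-point equations
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    nodes[0].length = _clip(0.5 * (d01 + d02 - d12))
    nodes[1].length = _clip(0.5 * (d01 + d12 - d02))
    nodes[2].length = _clip(0.5 * (d02 + d12 - d01))
    root = Clade(children=list(nodes))
    return SupportTree(root=root, ids=list(dm.ids))


def _nj_bipartitions_from_matrix(ids: list[str], D: np.ndarray, clamp: bool) -> set[frozenset]:
    tree = nj(DistanceMatrix(ids=ids, d=D), clamp=clamp)
    return set(tree.bipartitions().keys())


def bootstrap(
    aln: BarcodeAlignment,
    deletion_mode: str = "complete",
    B: int = 1000,
    seed: int | None = None,
    clamp: bool = True,
) -> SupportTree:
    """NJ point tree with bipartition bootstrap supports.

    Columns of the complete-deletion filtered matrix are resampled with
    replacement ``B`` times so that every replicate shares the point
    estimate's site scope; supports are percentages of non-dropped
    replicates containing each internal bipartition.  Randomness attaches
    to column draws only, so supports are invariant to taxon order given
    the same seed.  A warning is emitted when more than 5% of replicates
    are dropped for saturation.

    The returned tree carries ``n_replicates`` and ``n_dropped``
    attributes for reporting.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    dm = distance_matrix(aln, deletion_mode=deletion_mode)
    tree = nj(dm, clamp=clamp)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}

    X = aln.codes()
    ts, tv, m, keep = _counts_complete(X)
    Xc = X[:, keep]
    ii, jj = _pair_index(aln.n)
    xor = Xc[ii] ^ Xc[jj]
    TS = (xor == 1).astype(np.float64)
    TV = (xor >= 2).astype(np.float64)

    rng = np.random.default_rng(seed)
    n = aln.n
    dropped = 0
    for _ in range(B):
        w = np.bincount(rng.integers(0, m, size=m), minlength=m).astype(float)
        dr = _k2p_array(TS @ w / m, TV @ w / m)
        if np.isnan(dr).any():
            dropped += 1
            continue
        D = np.zeros((n, n))
        D[ii, jj] = dr
        D[jj, ii] = dr
        reps = _nj_bipartitions_from_matrix(list(aln.ids), D, clamp)
        for bp in counts:
            if bp in reps:
                counts[bp] += 1
    valid = B - dropped
    if dropped > 0.05 * B:
        warnings.warn(
            f"{dropped}/{B} bootstrap replicates dropped for saturated distances"
        )
    if valid == 0:
        raise TrivialTreeError("every bootstrap replicate saturated")
    for bp, clade in target.items():
        clade.support = 100.0 * counts[bp] / valid
    tree.n_replicates = B
    tree.n_dropped = dropped
    return tree


@dataclass(frozen=True)
class MonophylyResult:
    is_monophyletic: bool
    clade_size: int                       # smallest edge-side containing the species


def monophyly(
    tree: SupportTree, labels: Mapping[str, str]
) -> dict[str, MonophylyResult]:
    """Per-species monophyly on the unrooted tree.

    A species is monophyletic iff some edge separates exactly its leaf
    set from everything else (species with a single specimen are
    monophyletic by convention).  ``clade_size`` is the size of the
    smallest edge-side containing all the species' specimens — equal to
    the species' sample size exactly when monophyletic.
    """
    leafset = set(tree.leaves())
    missing = [sid for sid in labels if sid not in leafset]
    if missing:
        raise LabelingError(f"labelled specimens absent from tree: {missing}")
    unlabelled = [sid for sid in leafset if sid not in labels]
    if unlabelled:
        raise LabelingError(f"tree leaves without labels: {unlabelled}")

    by_species: dict[str, set] = {}
    for sid, sp in labels.items():
        by_species.setdefault(sp, set()).add(sid)

    sides = [set(s) for s in tree.edge_sides()]
    all_sides = sides + [leafset - s for s in sides] + [leafset]
    out = {}
    for sp, members in by_species.items():
        mono = len(members) == 1 or any(
            s == members for s in all_sides
        )
        enclosing = min(
            (len(s) for s in all_sides if members <= s), default=len(leafset)
        )
        out[sp] = MonophylyResult(is_monophyletic=mono, clade_size=enclosing)
    return out
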