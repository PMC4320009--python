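"""Kimura two-parameter distances and barcode-gap summaries.

The K2P model separates transitions (purine<->purine, pyrimidine<->
pyrimidine) from transversions.  With P the proportion of sites differing
by a transition and Q the proportion differing by a transversion, the
distance in expected substitutions per site is

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites carrying a gap or an ambiguity code are treated as missing.  Under
``complete`` deletion every column containing any missing state anywhere
in the study is dropped before any pair is compared (so all pairs share
one site scope); under ``pairwise`` deletion exclusion is decided pair by
pair.

Standard errors, where requested, come from a nonparametric site
bootstrap: the retained columns are resampled with replacement, the
distance recomputed, and the standard deviation across replicates
reported.  The barcode-gap summary aggregates all conspecific
(within-species) and congeneric (between-species) pairs on the percent
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    EmptyComparisonError,
    LabelingError,
    SaturatedDistanceError,
)
from .seqio import BarcodeAlignment, SpecimenRecord

_MISSING = 4


@dataclass(frozen=True)
class PairCounts:
    """Transition/transversion difference proportions over m compared sites."""

    P: float
    Q: float
    m: int

    def __post_init__(self):
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError(f"invalid proportions P={self.P} Q={self.Q}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with optional bootstrap SEs."""

    ids: list[str]
    d: np.ndarray
    se: Optional[np.ndarray] = None
    deletion_mode: str = "complete"

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        try:
            return self.ids.index(specimen_id)
        except ValueError:
            raise LabelingError(f"unknown specimen id {specimen_id!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in ids]
        return DistanceMatrix(
            ids=list(ids),
            d=self.d[np.ix_(idx, idx)],
            se=None if self.se is None else self.se[np.ix_(idx, idx)],
            deletion_mode=self.deletion_mode,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path) -> None:
        """Square PHYLIP distance format."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for sid, row in zip(self.ids, self.d):
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{sid:<10s} {vals}\n")


@dataclass(frozen=True)
class GapBlock:
    min: Optional[float]
    mean: Optional[float]
    max: Optional[float]
    se: Optional[float]
    n_pairs: int


@dataclass(frozen=True)
class GapSummary:
    """Conspecific vs congeneric K2P divergence on the percent scale."""

    conspecific: GapBlock
    congeneric: GapBlock

    @property
    def has_gap(self) -> Optional[bool]:
        """True when the largest conspecific distance is below the smallest congeneric one."""
        if self.conspecific.n_pairs == 0 or self.congeneric.n_pairs == 0:
            return None
        return self.conspecific.max < self.congeneric.min


@dataclass
class GroupMeanMatrix:
    """Between-group mean K2P distances (within-group means on the diagonal)."""

    labels: list[str]
    mean: np.ndarray
    se: Optional[np.ndarray] = None

    def write_tsv(self, path) -> None:
        """Layout mirroring published distance tables: means below the
        diagonal, SEs above (blank when unavailable), within-group means
        on the diagonal."""
        k = len(self.labels)
        with open(path, "w") as fh:
            fh.write("group\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                cells = []
                for j in range(k):
                    if j < i or i == j:
                        cells.append(f"{self.mean[i, j]:.4f}")
                    elif self.se is not None:
                        cells.append(f"{self.se[i, j]:.4f}")
                    else:
                        cells.append("")
                fh.write(lab + "\t" + "\t".join(cells) + "\n")


def k2p(P, Q: float | None = None) -> float:
    """K2P distance from transition/transversion proportions.

    Accepts either a :class:`PairCounts` or the two proportions.  Raises
    :class:`SaturatedDistanceError` when a log argument is non-positive
    (1 - 2P - Q <= 0 or 1 - 2Q <= 0), i.e. the pair is beyond the model's
    resolvable divergence.
    """
    if isinstance(P, PairCounts):
        P, Q = P.P, P.Q
    if Q is None:
        raise TypeError("k2p requires Q when P is given as a float")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(
            f"saturated distance: P={P:.4f} Q={Q:.4f} "
            f"(1-2P-Q={w1:.4f}, 1-2Q={w2:.4f})"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # +0.0 kills -0.0


def _k2p_array(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Vectorised K2P; returns NaN where saturated (caller decides policy)."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(
            (w1 > 0) & (w2 > 0),
            -0.5 * np.log(np.maximum(w1, 1e-300))
            - 0.25 * np.log(np.maximum(w2, 1e-300)),
            np.nan,
        )
    return d + 0.0  # normalise -0.0


def _encode_pair(seq: str) -> np.ndarray:
    table = np.full(128, _MISSING, dtype=np.uint8)
    for b, c in zip("AGCT", range(4)):
        table[ord(b)] = c
    return table[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def pair_counts(seq_a: str, seq_b: str, deletion_mode: str = "pairwise") -> PairCounts:
    """Count transition/transversion difference proportions for one pair.

    For two sequences the ``complete`` and ``pairwise`` scopes coincide;
    the argument exists for interface symmetry with
    :func:`distance_matrix`.
    """
    if len(seq_a) != len(seq_b):
        raise EmptyComparisonError("sequences differ in length")
    if deletion_mode not in ("complete", "pairwise"):
        raise ConfigError(f"unknown deletion mode {deletion_mode!r}")
    a = _encode_pair(seq_a)
    b = _encode_pair(seq_b)
    valid = (a < _MISSING) & (b < _MISSING)
    m = int(valid.sum())
    if m == 0:
        raise EmptyComparisonError("no comparable sites after gap/ambiguity exclusion")
    xa, xb = a[valid], b[valid]
    xor = xa ^ xb
    ts = int(np.count_nonzero(xor == 1))
    tv = int(np.count_nonzero(xor >= 2))
    return PairCounts(P=ts / m, Q=tv / m, m=m)


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _counts_complete(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Transition/transversion counts for all pairs under complete deletion.

    Returns (ts_counts, tv_counts, m, kept_column_mask)."""
    keep = (X < _MISSING).all(axis=0)
    m = int(keep.sum())
    if m == 0:
        raise EmptyComparisonError(
            "complete deletion removed every column; use pairwise deletion"
        )
    Xc = X[:, keep]
    ii, jj = _pair_index(X.shape[0])
    xor = Xc[ii] ^ Xc[jj]
    ts = (xor == 1).sum(axis=1)
    tv = (xor >= 2).sum(axis=1)
    return ts, tv, m, keep


def distance_matrix(
    aln: BarcodeAlignment,
    deletion_mode: str = "complete",
    se_reps: int = 0,
    seed: int | None = None,
) -> DistanceMatrix:
    """All-pairs K2P distance matrix with optional site-bootstrap SEs.

    ``se_reps > 0`` activates the bootstrap: under complete deletion the
    shared retained columns are resampled jointly once per replicate
    (so all pairs see the same pseudo-alignment, as a column bootstrap
    of the study should); under pairwise deletion each pair's own
    retained sites are resampled.  Replicates in which a pair saturates
    are dropped for that pair's SE.  The same seed reproduces SEs
    bit-identically.
    """
    if aln.n < 2:
        raise EmptyComparisonError("need at least two sequences")
    if deletion_mode not in ("complete", "pairwise"):
        raise ConfigError(f"unknown deletion mode {deletion_mode!r}")

    n = aln.n
    X = aln.codes()
    ii, jj = _pair_index(n)
    D = np.zeros((n, n), dtype=float)

    if deletion_mode == "complete":
        ts, tv, m, keep = _counts_complete(X)
        P = ts / m
        Q = tv / m
        dvals = _k2p_array(P, Q)
        bad = np.flatnonzero(np.isnan(dvals))
        if bad.size:
            k = bad[0]
            raise SaturatedDistanceError(
                f"saturated distance between {aln.ids[ii[k]]!r} and {aln.ids[jj[k]]!r}",
                pair=(aln.ids[ii[k]], aln.ids[jj[k]]),
            )
        D[ii, jj] = dvals
        D[jj, ii] = dvals
        SE = None
        if se_reps > 0:
            rng = np.random.default_rng(seed)
            Xc = X[:, keep]
            xor = Xc[ii] ^ Xc[jj]
            TS = (xor == 1).astype(np.float64)
            TV = (xor >= 2).astype(np.float64)
            acc = np.zeros((len(ii),))
            acc2 = np.zeros((len(ii),))
            cnt = np.zeros((len(ii),))
            for _ in range(se_reps):
                w = np.bincount(rng.integers(0, m, size=m), minlength=m).astype(float)
                Pr = TS @ w / m
                Qr = TV @ w / m
                dr = _k2p_array(Pr, Qr)
                ok = ~np.isnan(dr)
                acc[ok] += dr[ok]
                acc2[ok] += dr[ok] ** 2
                cnt[ok] += 1
            with np.errstate(invalid="ignore", divide="ignore"):
                var = (acc2 - acc**2 / np.maximum(cnt, 1)) / np.maximum(cnt - 1, 1)
            sevals = np.sqrt(np.maximum(var, 0.0))
            sevals[cnt < 2] = np.nan
            SE = np.zeros((n, n))
            SE[ii, jj] = sevals
            SE[jj, ii] = sevals
        return DistanceMatrix(ids=list(aln.ids), d=D, se=SE, deletion_mode=deletion_mode)

    # pairwise deletion: loop pairs (site scope differs per pair)
    rng = np.random.default_rng(seed) if se_reps > 0 else None
    SE = np.zeros((n, n)) if se_reps > 0 else None
    for i, j in zip(ii, jj):
        a, b = X[i], X[j]
        valid = (a < _MISSING) & (b < _MISSING)
        m = int(valid.sum())
        if m == 0:
            raise EmptyComparisonError(
                f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        xa, xb = a[valid], b[valid]
        xor = xa ^ xb
        P = np.count_nonzero(xor == 1) / m
        Q = np.count_nonzero(xor >= 2) / m
        try:
            dij = k2p(P, Q)
        except SaturatedDistanceError:
            raise SaturatedDistanceError(
                f"saturated distance between {aln.ids[i]!r} and {aln.ids[j]!r}",
                pair=(aln.ids[i], aln.ids[j]),
            ) from None
        D[i, j] = D[j, i] = dij
        if se_reps > 0:
            ts_mask = (xor == 1).astype(float)
            tv_mask = (xor >= 2).astype(float)
            reps = []
            for _ in range(se_reps):
                idx = rng.integers(0, m, size=m)
                Pr = ts_mask[idx].sum() / m
                Qr = tv_mask[idx].sum() / m
                dr = _k2p_array(np.array([Pr]), np.array([Qr]))[0]
                if not np.isnan(dr):
                    reps.append(dr)
            SE[i, j] = SE[j, i] = (
                float(np.std(reps, ddof=1)) if len(reps) > 1 else np.nan
            )
    return DistanceMatrix(ids=list(aln.ids), d=D, se=SE, deletion_mode=deletion_mode)


def _block(values: np.ndarray) -> GapBlock:
    if values.size == 0:
        return GapBlock(min=None, mean=None, max=None, se=None, n_pairs=0)
    pct = values * 100.0
    spread = float(np.std(pct, ddof=1)) if pct.size > 1 else 0.0
    return GapBlock(
        min=float(pct.min()),
        mean=float(pct.mean()),
        max=float(pct.max()),
        se=spread,
        n_pairs=int(values.size),
    )


def gap_summary(dm: DistanceMatrix, records: Sequence[SpecimenRecord]) -> GapSummary:
    """Barcode-gap summary: conspecific vs congeneric distance blocks (%).

    Conspecific aggregates every within-species specimen pair (species
    sampled once contribute none); congeneric aggregates every
    between-species pair.  The ``se`` field is the standard deviation of
    the block's pairwise distances.  An empty block is reported as empty,
    not as zero.
    """
    species = {r.specimen_id: r.species for r in records}
    missing = [i for i in dm.ids if i not in species]
    if missing:
        raise LabelingError(f"specimens without species labels: {missing}")
    labels = np.array([species[i] for i in dm.ids])
    ii, jj = _pair_index(dm.n)
    same = labels[ii] == labels[jj]
    vals = dm.d[ii, jj]
    return GapSummary(
        conspecific=_block(vals[same]), congeneric=_block(vals[~same])
    )


def group_mean_matrix(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    aln: BarcodeAlignment | None = None,
    se_reps: int = 0,
    seed: int | None = None,
) -> GroupMeanMatrix:
    """Mean between-group K2P distances, within-group means on the diagonal.

    Group order follows first occurrence in ``dm.ids``.  Singleton groups
    get a within-group mean of 0 by convention.  When an alignment is
    supplied with ``se_reps > 0``, cell SEs are estimated by a joint site
    bootstrap of the complete-deletion columns (group means recomputed per
    replicate).
    """
    missing = [i for i in dm.ids if i not in groups]
    if missing:
        raise LabelingError(f"specimens without group labels: {missing}")
    labels = [groups[i] for i in dm.ids]
    order: list[str] = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    k = len(order)
    lab_idx = {lab: g for g, lab in enumerate(order)}
    gvec = np.array([lab_idx[lab] for lab in labels])
    ii, jj = _pair_index(dm.n)
    vals = dm.d[ii, jj]
    gi, gj = gvec[ii], gvec[jj]

    def _means(pair_vals: np.ndarray) -> np.ndarray:
        M = np.zeros((k, k))
        for a in range(k):
            for b in range(a, k):
                if a == b:
                    sel = (gi == a) & (gj == a)
                    M[a, a] = float(pair_vals[sel].mean()) if sel.any() else 0.0
                else:
                    sel = ((gi == a) & (gj == b)) | ((gi == b) & (gj == a))
                    M[a, b] = M[b, a] = float(pair_vals[sel].mean())
        return M

    mean = _means(vals)
    SE = None
    if se_reps > 0:
        if aln is None:
            raise ConfigError("group SE estimation requires the alignment")
        X = aln.subset(dm.ids).codes()
        ts, tv, m, keep = _counts_complete(X)
        Xc = X[:, keep]
        xor = Xc[ii] ^ Xc[jj]
        TS = (xor == 1).astype(np.float64)
        TV = (xor >= 2).astype(np.float64)
        rng = np.random.default_rng(seed)
        reps = np.empty((se_reps, k, k))
        for r in range(se_reps):
            w = np.bincount(rng.integers(0, m, size=m), minlength=m).astype(float)
            dr = _k2p_array(TS @ w / m, TV @ w / m)
            reps[r] = _means(np.nan_to_num(dr, nan=np.nanmax(dr) if np.isnan(dr).any() else 0.0))
        SE = reps.std(axis=0, ddof=1)
    return GroupMeanMatrix(labels=order, mean=mean, se=SE)
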