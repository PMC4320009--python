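"""Haplotype collapsing and polymorphism statistics.

A haplotype is a unique sequence variant: specimens with byte-identical
(uppercased) sequences share one.  Gaps and ambiguity codes are
significant by default, matching the convention of the classic
population-genetics tools; a compatibility-matching mode is available
for studies with scattered ambiguity calls.

Site statistics follow the usual definitions: a site is *variable* when
it carries at least two distinct unambiguous bases, and
*parsimony-informative* when at least two of those bases each occur in
two or more sequences.  Base composition is computed per sequence over
unambiguous calls and then averaged over sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LabelingError, UndefinedStatisticError
from .seqio import AMBIGUITY_SETS, BarcodeAlignment


@dataclass
class HaplotypeSet:
    """Collapsed unique sequences with specimen membership."""

    haplotypes: list[str]                 # sequence strings, first-occurrence order
    members: list[list[str]]              # haplotype index -> specimen ids
    ids: list[str]                        # haplotype labels H1..Hk

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def freqs(self) -> list[int]:
        return [len(m) for m in self.members]

    @property
    def n(self) -> int:
        return sum(self.freqs)

    def assignment(self) -> dict[str, str]:
        """specimen id -> haplotype label."""
        return {sid: self.ids[h] for h, mem in enumerate(self.members) for sid in mem}

    def species_of(self, species: Mapping[str, str]) -> list[set[str]]:
        """Per haplotype, the set of species labels among its members."""
        out = []
        for mem in self.members:
            missing = [s for s in mem if s not in species]
            if missing:
                raise LabelingError(f"specimens without species labels: {missing}")
            out.append({species[s] for s in mem})
        return out

    def to_dataframe(self, species: Mapping[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for h in range(self.k):
            row = {
                "haplotype": self.ids[h],
                "count": self.freqs[h],
                "members": ",".join(self.members[h]),
            }
            if species is not None:
                row["species"] = ",".join(sorted({species[s] for s in self.members[h]}))
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path, species: Mapping[str, str] | None = None) -> None:
        self.to_dataframe(species).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SiteStats:
    n_variable: int
    n_parsimony_informative: int
    base_composition: dict[str, float]    # mean percent A/C/G/T per sequence

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("statistic\tvalue\n")
            fh.write(f"n_variable\t{self.n_variable}\n")
            fh.write(f"n_parsimony_informative\t{self.n_parsimony_informative}\n")
            for b in "ACGT":
                fh.write(f"composition_{b}_pct\t{self.base_composition[b]:.4f}\n")


def collapse(aln: BarcodeAlignment, match: str = "exact") -> HaplotypeSet:
    """Collapse specimens into haplotypes.

    ``match="exact"`` (default): identical strings define a haplotype.
    ``match="compatible"``: a specimen joins the first existing haplotype
    whose sequence is IUPAC-compatible at every site (ambiguity codes act
    as wildcards).  Compatibility is not transitive, so this mode is a
    deterministic greedy assignment in input order — documented, not a
    partition into equivalence classes.
    """
    haplotypes: list[str] = []
    members: list[list[str]] = []
    if match == "exact":
        index: dict[str, int] = {}
        for sid, seq in zip(aln.ids, aln.seqs):
            h = index.get(seq)
            if h is None:
                h = len(haplotypes)
                index[seq] = h
                haplotypes.append(seq)
                members.append([])
            members[h].append(sid)
    elif match == "compatible":
        for sid, seq in zip(aln.ids, aln.seqs):
            for h, hseq in enumerate(haplotypes):
                if all(
                    AMBIGUITY_SETS[a] & AMBIGUITY_SETS[b]
                    for a, b in zip(seq, hseq)
                ):
                    members[h].append(sid)
                    break
            else:
                haplotypes.append(seq)
                members.append([sid])
    else:
        raise ValueError(f"unknown match mode {match!r}")
    labels = [f"H{h + 1}" for h in range(len(haplotypes))]
    return HaplotypeSet(haplotypes=haplotypes, members=members, ids=labels)


def haplotype_diversity(freqs: Sequence[int]) -> float:
    """Nei's haplotype diversity Hd = n (1 - sum p_i^2) / (n - 1).

    The probability that two specimens drawn without replacement carry
    different haplotypes: 0 when all share one haplotype, 1 when all are
    unique.
    """
    freqs = [int(f) for f in freqs if f > 0]
    n = sum(freqs)
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity undefined for n < 2")
    p2 = sum((f / n) ** 2 for f in freqs)
    return n * (1.0 - p2) / (n - 1)


def site_stats(aln: BarcodeAlignment) -> SiteStats:
    """Variable/parsimony-informative site counts and base composition."""
    n_var = 0
    n_pi = 0
    for col in range(aln.L):
        counts: dict[str, int] = {}
        for seq in aln.seqs:
            ch = seq[col]
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                n_pi += 1
    comp = {b: [] for b in "ACGT"}
    for seq in aln.seqs:
        tot = sum(seq.count(b) for b in "ACGT")
        if tot == 0:
            continue
        for b in "ACGT":
            comp[b].append(100.0 * seq.count(b) / tot)
    composition = {b: float(np.mean(v)) if v else 0.0 for b, v in comp.items()}
    return SiteStats(
        n_variable=n_var,
        n_parsimony_informative=n_pi,
        base_composition=composition,
    )
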