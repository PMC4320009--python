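"""Alignment and specimen-table I/O plus pseudogene/quality screening.

A barcode study here is an aligned matrix of equal-length COI sequences
(FASTA) paired with a delimited specimen table (specimen_id, species,
site, basin).  Quality screening checks the properties expected of a
functional protein-coding mitochondrial fragment: no alignment gaps
(indels) and no internal stop codons under the vertebrate mitochondrial
code in the best-supported reading frame.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlignmentError, ConfigError, MetadataError, ParseError

#: IUPAC nucleotide codes (including ambiguity codes) plus the gap character.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: Map of IUPAC code -> set of unambiguous bases it may represent.
AMBIGUITY_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
    "-": {"-"},
}

# Numeric encoding used throughout: purines 0/1, pyrimidines 2/3 so that
# (a ^ b) == 1 identifies a transition and (a ^ b) >= 2 a transversion.
_BASE_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}
_MISSING = 4  # gaps and ambiguity codes: excluded from distance comparisons
_CODE_TO_BASE = "AGCT"

_GENETIC_CODE_ALIASES = {
    "standard": 1,
    "vertebrate_mitochondrial": 2,
    "invertebrate_mitochondrial": 5,
}


@dataclass(frozen=True)
class SpecimenRecord:
    """One row of the specimen table."""

    specimen_id: str
    species: str
    site: str = ""
    basin: str = ""

    def __post_init__(self):
        if not self.specimen_id:
            raise MetadataError("specimen_id must be non-empty")
        if not self.species:
            raise MetadataError(
                f"species label for specimen {self.specimen_id!r} must be non-empty"
            )


@dataclass
class BarcodeAlignment:
    """Equal-length specimen sequences with ordered ids.

    Sequences are stored uppercase; the alphabet is restricted to IUPAC
    nucleotide codes plus ``-``.  The alignment length ``L`` is data-driven.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(self.ids) == 0:
            raise ParseError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate specimen ids: {dupes}")
        self.seqs = [s.upper() for s in self.seqs]
        L = len(self.seqs[0])
        if L == 0:
            raise AlignmentError("zero-length sequences")
        bad = [i for i, s in zip(self.ids, self.seqs) if len(s) != L]
        if bad:
            raise AlignmentError(
                f"unequal sequence lengths (expected {L}): offending ids {bad}"
            )
        for sid, s in zip(self.ids, self.seqs):
            for pos, ch in enumerate(s):
                if ch not in IUPAC_CHARS:
                    raise ParseError(
                        f"non-IUPAC character {ch!r} in sequence {sid!r} at position {pos}"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    def codes(self) -> np.ndarray:
        """(n, L) uint8 matrix: A=0 G=1 C=2 T=3, gaps/ambiguities=4."""
        table = np.full(128, _MISSING, dtype=np.uint8)
        for b, c in _BASE_CODE.items():
            table[ord(b)] = c
        arr = np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.L)
        return table[arr]

    def subset(self, ids: Sequence[str]) -> "BarcodeAlignment":
        index = {sid: k for k, sid in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise AlignmentError(f"ids not in alignment: {missing}")
        return BarcodeAlignment(
            ids=list(ids), seqs=[self.seqs[index[i]] for i in ids]
        )

    def reorder(self, permutation: Sequence[int]) -> "BarcodeAlignment":
        return BarcodeAlignment(
            ids=[self.ids[k] for k in permutation],
            seqs=[self.seqs[k] for k in permutation],
        )


@dataclass(frozen=True)
class QCRow:
    specimen_id: str
    has_gap: bool
    has_stop_codon: bool
    n_stop_codons: int
    ambiguous_fraction: float


@dataclass
class QCReport:
    """Per-specimen quality flags plus the frame/code they were evaluated under."""

    frame: int
    genetic_code: int
    rows: list[QCRow]

    @property
    def all_clean(self) -> bool:
        return all(
            not r.has_gap and not r.has_stop_codon for r in self.rows
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        df.attrs["frame"] = self.frame
        df.attrs["genetic_code"] = self.genetic_code
        return df

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# frame={self.frame}\tgenetic_code={self.genetic_code}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


def read_alignment(path) -> BarcodeAlignment:
    """Read an aligned FASTA file.

    Ids are the first whitespace-delimited header token; input order is
    preserved and sequences are uppercased.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return BarcodeAlignment(
        ids=[r.id for r in records], seqs=[str(r.seq) for r in records]
    )


def write_alignment(aln: BarcodeAlignment, path) -> None:
    """Write FASTA with one sequence per line (round-trip exact)."""
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


def read_metadata(path, sep: str | None = None) -> list[SpecimenRecord]:
    """Read the specimen table (TSV/CSV with header).

    Requires columns ``specimen_id`` and ``species``; ``site`` and
    ``basin`` are optional.  Duplicate specimen ids are rejected.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    for col in ("specimen_id", "species"):
        if col not in df.columns:
            raise MetadataError(f"metadata missing required column {col!r}")
    dupes = df["specimen_id"][df["specimen_id"].duplicated()].tolist()
    if dupes:
        raise MetadataError(f"duplicate specimen ids in metadata: {sorted(set(dupes))}")
    return [
        SpecimenRecord(
            specimen_id=row["specimen_id"],
            species=row["species"],
            site=row.get("site", ""),
            basin=row.get("basin", ""),
        )
        for _, row in df.iterrows()
    ]


def write_metadata(records: Iterable[SpecimenRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


def cross_reference(aln: BarcodeAlignment, records: Sequence[SpecimenRecord]) -> dict[str, str]:
    """Map alignment ids -> species, erroring on ids absent from the table."""
    table = {r.specimen_id: r.species for r in records}
    missing = [i for i in aln.ids if i not in table]
    if missing:
        raise MetadataError(f"alignment ids missing from metadata: {missing}")
    return {i: table[i] for i in aln.ids}


def _resolve_code(code) -> int:
    if isinstance(code, int):
        code_id = code
    else:
        code_id = _GENETIC_CODE_ALIASES.get(str(code).lower())
        if code_id is None:
            raise ConfigError(
                f"unknown genetic code {code!r}; known: {sorted(_GENETIC_CODE_ALIASES)} or an NCBI table id"
            )
    try:
        CodonTable.unambiguous_dna_by_id[code_id]
    except KeyError:
        raise ConfigError(f"unknown NCBI genetic code id {code_id}") from None
    return code_id


def _count_stops(seq: str, frame: int, stops: frozenset[str]) -> int:
    s = seq.replace("-", "")
    n = 0
    for k in range(frame, len(s) - 2, 3):
        if s[k : k + 3] in stops:
            n += 1
    return n


def qc_screen(
    aln: BarcodeAlignment,
    code: int | str = "vertebrate_mitochondrial",
    frame: int | str = "auto",
) -> QCReport:
    """Screen every specimen for gaps, stop codons, and ambiguity content.

    Stop codons are counted on the gap-stripped sequence in a single
    reading frame shared by the whole study.  ``frame="auto"`` picks the
    frame minimising the total stop count over all sequences (ties broken
    toward the lowest frame index) — a functional barcode region should
    have a stop-free frame.  Codons containing ambiguity codes never
    count as stops.
    """
    if aln.L < 3:
        raise AlignmentError("alignment too short for codon screening (L < 3)")
    code_id = _resolve_code(code)
    stops = frozenset(CodonTable.unambiguous_dna_by_id[code_id].stop_codons)

    if frame == "auto":
        totals = [
            sum(_count_stops(s, f, stops) for s in aln.seqs) for f in (0, 1, 2)
        ]
        chosen = int(np.argmin(totals))  # argmin returns the lowest index on ties
    else:
        chosen = int(frame)
        if chosen not in (0, 1, 2):
            raise ConfigError(f"frame must be 0, 1, 2 or 'auto', got {frame!r}")

    rows = []
    for sid, s in zip(aln.ids, aln.seqs):
        n_stop = _count_stops(s, chosen, stops)
        n_ambig = sum(1 for ch in s if ch not in "ACGT-")
        rows.append(
            QCRow(
                specimen_id=sid,
                has_gap="-" in s,
                has_stop_codon=n_stop > 0,
                n_stop_codons=n_stop,
                ambiguous_fraction=n_ambig / aln.L,
            )
        )
    return QCReport(frame=chosen, genetic_code=code_id, rows=rows)
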