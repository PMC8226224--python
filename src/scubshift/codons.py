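"""Codon extraction and third-position usage summaries for CDS collections.

The synonymous-codon (SC) universe is the 59 codons remaining after removing
the three stop codons (TAA, TAG, TGA) and the two non-degenerate codons ATG
(Met) and TGG (Trp).  The 18 amino acids covered each retain at least two
codons, so every SC has a same-amino-acid alternative.  All frequencies here
are taken relative to the SC pool: adding stops or ATG/TGG to a pool never
moves any reported number.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_SYMBOL = "*"
ALL_CODONS = tuple("".join(p) for p in itertools.product(BASES, repeat=3))
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NON_DEGENERATE_CODONS = frozenset({"ATG", "TGG"})


class EmptyInputError(ValueError):
    """Raised when a sequence is too short to contain a single codon."""


class EmptyPoolError(ValueError):
    """Raised when an operation needs a nonempty synonymous-codon pool."""


class InvalidAminoAcidError(ValueError):
    """Raised when an amino acid has no degenerate codon family."""


@dataclass(frozen=True)
class GeneticCodeTable:
    """Standard genetic code with the 59-codon synonymous subset singled out."""

    codon_to_aa: Mapping[str, str]
    sc_set: frozenset
    sc_amino_acids: frozenset

    @classmethod
    def standard(cls) -> "GeneticCodeTable":
        fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
        codon_to_aa = {c: fwd.get(c, STOP_SYMBOL) for c in ALL_CODONS}
        sc = frozenset(
            c
            for c in ALL_CODONS
            if c not in STOP_CODONS and c not in NON_DEGENERATE_CODONS
        )
        aas = frozenset(codon_to_aa[c] for c in sc)
        return cls(codon_to_aa, sc, aas)

    def is_sc(self, codon: str) -> bool:
        return codon in self.sc_set

    def synonymous_codons(self, aa: str) -> tuple:
        """All SC-set codons encoding ``aa`` (one-letter symbol)."""
        if aa not in self.sc_amino_acids:
            raise InvalidAminoAcidError(
                f"{aa!r} has no synonymous-codon family (Met, Trp and stops are excluded)"
            )
        return tuple(c for c in sorted(self.sc_set) if self.codon_to_aa[c] == aa)


#: Module-wide standard code instance.
STANDARD_CODE = GeneticCodeTable.standard()


@dataclass
class CdsRecord:
    """One coding sequence, assumed in frame at ``frame_offset`` (no ORF search)."""

    id: str
    sequence: str
    sample: str = ""
    frame_offset: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError(f"frame_offset must be 0-2, got {self.frame_offset}")
        if len(self.sequence) < self.frame_offset + 3:
            raise EmptyInputError(
                f"record {self.id!r}: sequence holds no complete codon"
            )


def extract_codons(record: CdsRecord) -> list:
    """In-frame codons of a record; a trailing partial codon is dropped."""
    seq = record.sequence
    if len(seq) < record.frame_offset + 3:
        raise EmptyInputError(f"record {record.id!r}: no complete codon")
    n = (len(seq) - record.frame_offset) // 3
    return [seq[record.frame_offset + 3 * i : record.frame_offset + 3 * i + 3] for i in range(n)]


@dataclass
class CodonCounts:
    """Counts over the 64-codon alphabet with the SC-restricted total cached.

    Codons containing a character outside ACGT (ambiguity codes in EST data)
    are dropped from all tallies and only recorded in ``n_invalid``.
    """

    counts: Counter = field(default_factory=Counter)
    n_invalid: int = 0

    @classmethod
    def from_codons(
        cls, codons: Iterable, code: GeneticCodeTable = STANDARD_CODE
    ) -> "CodonCounts":
        counts: Counter = Counter()
        n_invalid = 0
        valid = code.codon_to_aa
        for codon in codons:
            if codon in valid:
                counts[codon] += 1
            else:
                n_invalid += 1
        if n_invalid:
            logger.info("dropped %d codons with non-ACGT characters", n_invalid)
        return cls(counts=counts, n_invalid=n_invalid)

    def n_sc(self, code: GeneticCodeTable = STANDARD_CODE) -> int:
        return sum(self.counts[c] for c in code.sc_set if c in self.counts)

    def n_stops(self) -> int:
        return sum(self.counts[c] for c in STOP_CODONS)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        return CodonCounts(
            counts=self.counts + other.counts,
            n_invalid=self.n_invalid + other.n_invalid,
        )

    def __radd__(self, other):  # allows sum(...) with start=0
        if other == 0:
            return self
        return NotImplemented


def count_synonymous_codons(
    codons: Iterable, code: GeneticCodeTable = STANDARD_CODE
) -> CodonCounts:
    """Tally a codon list; stops/ATG/TGG are counted but excluded from n_sc."""
    return CodonCounts.from_codons(codons, code=code)


def count_record(record: CdsRecord, code: GeneticCodeTable = STANDARD_CODE) -> CodonCounts:
    counts = count_synonymous_codons(extract_codons(record), code=code)
    internal = [
        c for c in extract_codons(record)[:-1] if c in STOP_CODONS
    ]
    if internal:
        logger.warning(
            "record %s: %d internal stop codon(s) kept out of the SC pool",
            record.id,
            len(internal),
        )
    return counts


def ending_counts(
    counts: CodonCounts, code: GeneticCodeTable = STANDARD_CODE
) -> dict:
    """Raw SC counts keyed by third-position base."""
    out = {b: 0 for b in BASES}
    for codon in code.sc_set:
        n = counts.counts.get(codon, 0)
        if n:
            out[codon[2]] += n
    return out


@dataclass(frozen=True)
class EndingFrequencies:
    """Third-position composition of a synonymous-codon pool."""

    n_A: int
    n_T: int
    n_C: int
    n_G: int
    f_A: float
    f_T: float
    f_C: float
    f_G: float

    @classmethod
    def from_counts(
        cls, counts: CodonCounts, code: GeneticCodeTable = STANDARD_CODE
    ) -> "EndingFrequencies":
        by_base = ending_counts(counts, code)
        total = sum(by_base.values())
        if total == 0:
            raise EmptyPoolError("no synonymous codons in pool")
        return cls(
            n_A=by_base["A"],
            n_T=by_base["T"],
            n_C=by_base["C"],
            n_G=by_base["G"],
            f_A=by_base["A"] / total,
            f_T=by_base["T"] / total,
            f_C=by_base["C"] / total,
            f_G=by_base["G"] / total,
        )

    @property
    def n_sc(self) -> int:
        return self.n_A + self.n_T + self.n_C + self.n_G

    def as_row(self) -> dict:
        return {
            "n_A": self.n_A,
            "n_T": self.n_T,
            "n_C": self.n_C,
            "n_G": self.n_G,
            "f_A": self.f_A,
            "f_T": self.f_T,
            "f_C": self.f_C,
            "f_G": self.f_G,
        }


def total_ending_frequencies(
    counts: CodonCounts, code: GeneticCodeTable = STANDARD_CODE
) -> EndingFrequencies:
    """Pool-level NNA/NNT/NNC/NNG frequencies over the SC set."""
    return EndingFrequencies.from_counts(counts, code)


def per_aa_scub_frequency(
    counts: CodonCounts, aa: str, code: GeneticCodeTable = STANDARD_CODE
) -> Optional[float]:
    """C/G-ending over A/T-ending SC counts for one amino acid.

    Returns ``None`` (undefined) when the amino acid has no A/T-ending
    codons in the pool.  All codons of the amino acid are counted together,
    including both families of six-codon amino acids.
    """
    num = 0
    den = 0
    for codon in code.synonymous_codons(aa):
        n = counts.counts.get(codon, 0)
        if codon[2] in "CG":
            num += n
        else:
            den += n
    if den == 0:
        return None
    return num / den


def per_aa_ending_counts(
    counts: CodonCounts, aa: str, code: GeneticCodeTable = STANDARD_CODE
) -> dict:
    """(n_AT, n_CG) raw counts behind :func:`per_aa_scub_frequency`."""
    n_at = 0
    n_cg = 0
    for codon in code.synonymous_codons(aa):
        n = counts.counts.get(codon, 0)
        if codon[2] in "CG":
            n_cg += n
        else:
            n_at += n
    return {"n_AT": n_at, "n_CG": n_cg}


def cg_to_at_ratio(
    counts: CodonCounts, code: GeneticCodeTable = STANDARD_CODE
) -> Optional[float]:
    """(NNC + NNG) / (NNA + NNT) over the SC pool; ``None`` if undefined."""
    by_base = ending_counts(counts, code)
    den = by_base["A"] + by_base["T"]
    if den == 0:
        return None
    return (by_base["C"] + by_base["G"]) / den
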