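"""CpG-deamination signature ratios over synonymous codons.

Deamination of methylated cytosine converts CpG to TpG on the strand carrying
the C and to CpA on the opposite strand.  At degenerate third positions this
leaves two measurable marks: within a codon, NCG shifts toward NCA (third
base G->A next to a second-position C); across a codon boundary, a
third-position C followed by a G-starting codon shifts toward T (NC|G ->
NT|G).  The ratios computed here compare those marked combinations with the
unmarked ones (other second bases, other successor bases) so that a pooled
elevation specific to the CpG-context ratio is evidence of a
methylation-driven shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

from .codons import BASES, STANDARD_CODE, CodonCounts, GeneticCodeTable, InvalidAminoAcidError

logger = logging.getLogger(__name__)

#: Amino acids encoded by SC pairs with both A and G at the third position.
AG_PAIR_AMINO_ACIDS = ("A", "R", "Q", "E", "G", "L", "K", "P", "S", "T", "V")

#: First-two-base family used for the A/G pair ratio of each amino acid.
#: Six-codon amino acids default to the four-codon family (CTn for Leu,
#: CGn for Arg, TCn for Ser); their two-codon families are reported
#: separately via ``family="alt"``.
PRIMARY_FAMILY = {
    "A": "GC",
    "R": "CG",
    "Q": "CA",
    "E": "GA",
    "G": "GG",
    "L": "CT",
    "K": "AA",
    "P": "CC",
    "S": "TC",
    "T": "AC",
    "V": "GT",
}
ALT_FAMILY = {"R": "AG", "L": "TT"}


@dataclass
class DinucleotideEndingCounts:
    """Counts of A/G-ending SCs keyed by (second base, third base)."""

    n: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {x: {"A": 0, "G": 0} for x in BASES}
    )

    @classmethod
    def from_codon_counts(
        cls, counts: CodonCounts, code: GeneticCodeTable = STANDARD_CODE
    ) -> "DinucleotideEndingCounts":
        out = cls()
        for codon in code.sc_set:
            if codon[2] in "AG":
                k = counts.counts.get(codon, 0)
                if k:
                    out.n[codon[1]][codon[2]] += k
        return out

    def __add__(self, other: "DinucleotideEndingCounts") -> "DinucleotideEndingCounts":
        out = DinucleotideEndingCounts()
        for x in BASES:
            for y in "AG":
                out.n[x][y] = self.n[x][y] + other.n[x][y]
        return out


def second_third_counts(
    counts: CodonCounts, code: GeneticCodeTable = STANDARD_CODE
) -> DinucleotideEndingCounts:
    """Tally A/G-ending SCs by their second-third base combination."""
    return DinucleotideEndingCounts.from_codon_counts(counts, code)


def nxa_nxg_ratio(d: DinucleotideEndingCounts, x: str) -> Optional[float]:
    """NXA/NXG for second base ``x``; ``None`` when NXG is absent."""
    if x not in BASES:
        raise ValueError(f"second base must be one of ACGT, got {x!r}")
    den = d.n[x]["G"]
    if den == 0:
        return None
    return d.n[x]["A"] / den


@dataclass
class BoundaryPairCounts:
    """Counts of (focal third base C/T) x (next codon's first base).

    Focal codons are restricted to the SC set; the successor may be any codon
    since only its first base matters.  The last codon of a CDS contributes
    no pair, and pairs never span CDS records.
    """

    m: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {z: {x: 0 for x in BASES} for z in "CT"}
    )

    @classmethod
    def from_codons(
        cls, codons: Iterable, code: GeneticCodeTable = STANDARD_CODE
    ) -> "BoundaryPairCounts":
        out = cls()
        sc = code.sc_set
        m = out.m
        codons = list(codons)
        for i in range(len(codons) - 1):
            focal = codons[i]
            if focal in sc and focal[2] in "CT":
                nxt = codons[i + 1][0]
                if nxt in "ACGT":
                    m[focal[2]][nxt] += 1
        return out

    def __add__(self, other: "BoundaryPairCounts") -> "BoundaryPairCounts":
        out = BoundaryPairCounts()
        for z in "CT":
            for x in BASES:
                out.m[z][x] = self.m[z][x] + other.m[z][x]
        return out

    def total(self) -> int:
        return sum(self.m[z][x] for z in "CT" for x in BASES)


def boundary_pair_counts(
    codons: Iterable, code: GeneticCodeTable = STANDARD_CODE
) -> BoundaryPairCounts:
    """Adjacent-codon pair counts for one CDS's in-order codon list."""
    return BoundaryPairCounts.from_codons(codons, code)


def ntx_ncx_ratio(b: BoundaryPairCounts, x: str) -> Optional[float]:
    """NT|X / NC|X for successor first base ``x``; ``None`` when NC|X is 0.

    The source text alternates between "NT|X/NG|X" and "NT|X/NC|X"; the
    biochemistry described (third-position C->T conversion) dictates a
    T-over-C ratio, which is what is computed here.
    """
    if x not in BASES:
        raise ValueError(f"first base must be one of ACGT, got {x!r}")
    den = b.m["C"][x]
    if den == 0:
        return None
    return b.m["T"][x] / den


def per_aa_ag_pair_counts(
    counts: CodonCounts,
    aa: str,
    family: str = "primary",
    code: GeneticCodeTable = STANDARD_CODE,
) -> dict:
    """Raw (n_A, n_G) counts of the XYA/XYG codon pair of one amino acid."""
    if aa not in AG_PAIR_AMINO_ACIDS:
        raise InvalidAminoAcidError(
            f"{aa!r} has no A/G-ending synonymous codon pair"
        )
    if family == "primary":
        prefix = PRIMARY_FAMILY[aa]
    elif family == "alt":
        if aa not in ALT_FAMILY:
            raise InvalidAminoAcidError(f"{aa!r} has a single codon family")
        prefix = ALT_FAMILY[aa]
    else:
        raise ValueError(f"family must be 'primary' or 'alt', got {family!r}")
    codon_a, codon_g = prefix + "A", prefix + "G"
    assert codon_a in code.sc_set and codon_g in code.sc_set
    return {
        "n_A": counts.counts.get(codon_a, 0),
        "n_G": counts.counts.get(codon_g, 0),
        "codon_A": codon_a,
        "codon_G": codon_g,
    }


def per_aa_ag_pair_ratio(
    counts: CodonCounts,
    aa: str,
    family: str = "primary",
    code: GeneticCodeTable = STANDARD_CODE,
) -> Optional[float]:
    """A-ending over G-ending count within one codon family; ``None`` if G count is 0."""
    c = per_aa_ag_pair_counts(counts, aa, family=family, code=code)
    if c["n_G"] == 0:
        return None
    return c["n_A"] / c["n_G"]


def cross_sample_ratio(
    r_hybrid: Optional[float], r_recipient: Optional[float]
) -> Optional[float]:
    """Hybrid-over-recipient ratio of ratios; undefined flags propagate."""
    if r_hybrid is None or r_recipient is None or r_recipient == 0:
        return None
    return r_hybrid / r_recipient


def signature_tables(
    recipient: tuple,
    hybrid: tuple,
    code: GeneticCodeTable = STANDARD_CODE,
) -> Dict[str, list]:
    """The eight 2x2 count tables behind the cross-sample ratio tests.

    ``recipient`` and ``hybrid`` are (CodonCounts, BoundaryPairCounts) pairs.
    Keys ``NXA/NXG`` use within-codon second-third counts; keys ``NT|X/NC|X``
    use boundary pairs.  Each value is ``[[num_r, den_r], [num_h, den_h]]``.
    """
    cc_r, bp_r = recipient
    cc_h, bp_h = hybrid
    d_r = second_third_counts(cc_r, code)
    d_h = second_third_counts(cc_h, code)
    tables: Dict[str, list] = {}
    for x in BASES:
        tables[f"N{x}A/N{x}G"] = [
            [d_r.n[x]["A"], d_r.n[x]["G"]],
            [d_h.n[x]["A"], d_h.n[x]["G"]],
        ]
    for x in BASES:
        tables[f"NT|{x}/NC|{x}"] = [
            [bp_r.m["T"][x], bp_r.m["C"][x]],
            [bp_h.m["T"][x], bp_h.m["C"][x]],
        ]
    return tables
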