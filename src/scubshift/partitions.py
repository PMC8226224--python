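"""Chromosome-derived grouping of CDS records.

Bread wheat is allohexaploid: 21 chromosomes named 1A-7D, where the digit is
the homoeologous (allelic) group and the letter the sub-genome.  Arm suffixes
(L/S) are accepted on input and stripped; introgression status is tracked at
whole-chromosome resolution via a configurable chromosome set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

import pandas as pd

from .codons import CodonCounts

WHEAT_CHROMOSOMES = tuple(f"{g}{s}" for g in "1234567" for s in "ABD")

#: Chromosomes carrying introgressed fragments in the default configuration.
DEFAULT_INTROGRESSED = frozenset({"1B", "1D", "2A", "2D", "5B", "6D"})

UNMAPPED = "unmapped"

_CHROM_RE = re.compile(r"([1-7])([ABD])([LS]?)$")

SCHEMES = ("all", "mapped", "introgression", "allelic_group", "subgenome")


class ChromosomeParseError(ValueError):
    pass


@dataclass(frozen=True)
class ChromosomeAssignment:
    record_id: str
    chromosome: Optional[str]  # normalized "1A".."7D", or None for unmapped
    allelic_group: Optional[int]
    subgenome: Optional[str]
    introgressed: bool

    @classmethod
    def from_name(
        cls,
        record_id: str,
        name: str,
        introgressed_set: Iterable[str] = DEFAULT_INTROGRESSED,
    ) -> "ChromosomeAssignment":
        name = name.strip()
        if name.lower() == UNMAPPED:
            return cls(record_id, None, None, None, False)
        m = _CHROM_RE.fullmatch(name.upper())
        if m is None:
            raise ChromosomeParseError(
                f"record {record_id!r}: malformed chromosome name {name!r}"
            )
        chrom = m.group(1) + m.group(2)
        return cls(
            record_id=record_id,
            chromosome=chrom,
            allelic_group=int(m.group(1)),
            subgenome=m.group(2),
            introgressed=chrom in set(introgressed_set),
        )

    @property
    def mapped(self) -> bool:
        return self.chromosome is not None


def load_chromosome_map(
    source,
    introgressed_set: Iterable[str] = DEFAULT_INTROGRESSED,
) -> Dict[str, ChromosomeAssignment]:
    """Read a record_id/chromosome TSV (path or DataFrame) into assignments."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    missing = {"record_id", "chromosome"} - set(df.columns)
    if missing:
        raise ValueError(f"chromosome map lacks column(s): {sorted(missing)}")
    dup = df["record_id"][df["record_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate record_id(s) in chromosome map: {sorted(set(dup))}")
    out = {}
    for _, row in df.iterrows():
        a = ChromosomeAssignment.from_name(
            str(row["record_id"]), str(row["chromosome"]), introgressed_set
        )
        out[a.record_id] = a
    return out


def partition_counts(
    counts_by_record: Mapping[str, CodonCounts],
    assignments: Mapping[str, ChromosomeAssignment],
    scheme: str,
) -> Dict[str, CodonCounts]:
    """Pool per-record counts under a partition scheme.

    Records with no assignment row contribute only to scheme ``all``.  Label
    sets are fixed per scheme (empty pools are kept) so downstream tables
    have a stable shape.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "all":
        pools: Dict[str, CodonCounts] = {"all": CodonCounts()}
    elif scheme == "mapped":
        pools = {"mapped": CodonCounts(), UNMAPPED: CodonCounts()}
    elif scheme == "introgression":
        pools = {"introgressed": CodonCounts(), "non_introgressed": CodonCounts()}
    elif scheme == "allelic_group":
        pools = {str(g): CodonCounts() for g in range(1, 8)}
    else:
        pools = {s: CodonCounts() for s in "ABD"}

    for rid, counts in counts_by_record.items():
        label = _scheme_label(rid, assignments, scheme)
        if label is not None:
            pools[label] += counts
    return pools


def _scheme_label(
    rid: str, assignments: Mapping[str, ChromosomeAssignment], scheme: str
) -> Optional[str]:
    if scheme == "all":
        return "all"
    a = assignments.get(rid)
    if a is None:
        return None
    if scheme == "mapped":
        return "mapped" if a.mapped else UNMAPPED
    if not a.mapped:
        return None
    if scheme == "introgression":
        return "introgressed" if a.introgressed else "non_introgressed"
    if scheme == "allelic_group":
        return str(a.allelic_group)
    return a.subgenome


def partition_ids(
    record_ids: Iterable[str],
    assignments: Mapping[str, ChromosomeAssignment],
    scheme: str,
) -> Dict[str, list]:
    """Record ids grouped by partition label (same rules as partition_counts)."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "all":
        labels = ["all"]
    elif scheme == "mapped":
        labels = ["mapped", UNMAPPED]
    elif scheme == "introgression":
        labels = ["introgressed", "non_introgressed"]
    elif scheme == "allelic_group":
        labels = [str(g) for g in range(1, 8)]
    else:
        labels = list("ABD")
    out: Dict[str, list] = {lab: [] for lab in labels}
    for rid in record_ids:
        label = _scheme_label(rid, assignments, scheme)
        if label is not None:
            out[label].append(rid)
    return out
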