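"""Indel detection in pairwise CDS alignments and flank/remote region codons.

Regions follow three distance rules, all measured in each sequence's own
ungapped coordinates: (i) only indels more than 45 nt from both CDS termini
are analyzed; (ii) each eligible indel contributes the 15 complete in-frame
codons immediately 5' and 3' of it; (iii) a segment shorter than 90 nt
between two indels contributes to no flank, and "remote" codons are those
whose every nucleotide lies more than 45 nt from every indel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .codons import STANDARD_CODE, CdsRecord, CodonCounts, EndingFrequencies, GeneticCodeTable

logger = logging.getLogger(__name__)

GAP = "-"

FLANK_NT = 45          # 15 codons
MIN_SEGMENT_NT = 90    # inter-indel segments shorter than this are dropped
MIN_TERMINAL_NT = 45   # indels must be strictly farther than this from termini


class ContractViolation(RuntimeError):
    """A window request on an indel that terminal filtering should have removed."""


@dataclass
class PairwiseAlignment:
    """Two equal-length gapped strings plus per-sequence frame offsets."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    frame_a: int = 0
    frame_b: int = 0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError(
                f"aligned strings differ in length for {self.id_a}/{self.id_b}"
            )
        for i, (x, y) in enumerate(zip(self.aligned_a, self.aligned_b)):
            if x == GAP and y == GAP:
                raise ValueError(f"column {i} is gap in both sequences")

    def seq(self, side: str) -> str:
        aligned = self.aligned_a if side == "a" else self.aligned_b
        return aligned.replace(GAP, "")

    def frame(self, side: str) -> int:
        return self.frame_a if side == "a" else self.frame_b

    def ungapped_pos(self, side: str, col: int) -> int:
        """Number of non-gap characters strictly before ``col`` on ``side``."""
        aligned = self.aligned_a if side == "a" else self.aligned_b
        return col - aligned.count(GAP, 0, col)


@dataclass(frozen=True)
class Indel:
    """A maximal gap run on one side of the alignment.

    ``interval_a``/``interval_b`` are half-open ungapped spans; the span is
    zero-width (a point between two positions) on the gapped side.
    """

    col_start: int
    col_end: int
    gapped_side: str  # 'a' or 'b'
    interval_a: Tuple[int, int]
    interval_b: Tuple[int, int]

    @property
    def length_nt(self) -> int:
        return self.col_end - self.col_start

    def interval(self, side: str) -> Tuple[int, int]:
        return self.interval_a if side == "a" else self.interval_b


def _gap_runs(aligned: str) -> List[Tuple[int, int]]:
    runs = []
    start = None
    for i, ch in enumerate(aligned):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(aligned)))
    return runs


def find_indels(aln: PairwiseAlignment) -> List[Indel]:
    """All maximal gap runs on either side, sorted by alignment column."""
    indels = []
    for side, aligned in (("a", aln.aligned_a), ("b", aln.aligned_b)):
        for cs, ce in _gap_runs(aligned):
            pa = (aln.ungapped_pos("a", cs), aln.ungapped_pos("a", ce))
            pb = (aln.ungapped_pos("b", cs), aln.ungapped_pos("b", ce))
            indels.append(
                Indel(
                    col_start=cs,
                    col_end=ce,
                    gapped_side=side,
                    interval_a=pa,
                    interval_b=pb,
                )
            )
    return sorted(indels, key=lambda d: (d.col_start, d.gapped_side))


def filter_eligible_indels(
    indels: Iterable[Indel],
    aln: PairwiseAlignment,
    min_terminal_nt: int = MIN_TERMINAL_NT,
) -> List[Indel]:
    """Keep indels strictly farther than ``min_terminal_nt`` from both CDS ends
    in both sequences."""
    len_a = len(aln.seq("a"))
    len_b = len(aln.seq("b"))
    out = []
    for d in indels:
        ok = True
        for side, length in (("a", len_a), ("b", len_b)):
            l, r = d.interval(side)
            if not (l > min_terminal_nt and length - r > min_terminal_nt):
                ok = False
                break
        if ok:
            out.append(d)
    return out


def _floor_boundary(pos: int, frame: int) -> int:
    """Largest in-frame codon boundary <= pos."""
    return frame + ((pos - frame) // 3) * 3


def _ceil_boundary(pos: int, frame: int) -> int:
    """Smallest in-frame codon boundary >= pos."""
    return frame + -((frame - pos) // 3) * 3


@dataclass
class FlankWindows:
    """Per-side nt spans of the 5' and 3' flanking windows of one indel.

    A span of ``None`` means the adjacent inter-indel segment was shorter
    than 90 nt and is excluded; ``truncated`` marks windows clipped below
    the full 45 nt.
    """

    span5: Dict[str, Optional[Tuple[int, int]]]
    span3: Dict[str, Optional[Tuple[int, int]]]
    truncated: Dict[str, bool]

    def codons(self, aln: PairwiseAlignment, side: str, which: str) -> List[str]:
        span = (self.span5 if which == "flank5" else self.span3)[side]
        if span is None:
            return []
        seq = aln.seq(side)
        s, e = span
        return [seq[p : p + 3] for p in range(s, e, 3)]


def extract_flanking_windows(
    aln: PairwiseAlignment,
    indel: Indel,
    indels: Optional[Iterable[Indel]] = None,
    window_nt: int = FLANK_NT,
    min_segment_nt: int = MIN_SEGMENT_NT,
) -> FlankWindows:
    """Complete-codon flanking windows of an eligible indel, per sequence.

    Codons broken by the indel boundary belong to neither flank; windows are
    clipped at neighboring indels (dropped entirely when the inter-indel
    segment is shorter than ``min_segment_nt``).
    """
    if indels is None:
        indels = [indel]
    others = [d for d in indels if d is not indel]
    span5: Dict[str, Optional[Tuple[int, int]]] = {}
    span3: Dict[str, Optional[Tuple[int, int]]] = {}
    truncated: Dict[str, bool] = {}
    for side in ("a", "b"):
        L = len(aln.seq(side))
        f = aln.frame(side)
        l, r = indel.interval(side)
        if not (l > MIN_TERMINAL_NT and L - r > MIN_TERMINAL_NT):
            raise ContractViolation(
                f"indel at [{l},{r}) of {aln.id_a}/{aln.id_b} side {side} "
                "is within the terminal exclusion zone"
            )
        prev_ends = [d.interval(side)[1] for d in others if d.interval(side)[1] <= l]
        next_starts = [d.interval(side)[0] for d in others if d.interval(side)[0] >= r]
        trunc = False

        # 5' window: ends at the last in-frame boundary at or before the indel
        prev_r = max(prev_ends) if prev_ends else None
        if prev_r is not None and l - prev_r < min_segment_nt:
            span5[side] = None
        else:
            end5 = _floor_boundary(l, f)
            lo = _ceil_boundary(prev_r, f) if prev_r is not None else f
            start5 = max(end5 - window_nt, lo)
            if start5 >= end5:
                span5[side] = None
                trunc = True
            else:
                span5[side] = (start5, end5)
                trunc = trunc or (end5 - start5 < window_nt)

        # 3' window: starts at the first in-frame boundary at or after the indel
        next_l = min(next_starts) if next_starts else None
        if next_l is not None and next_l - r < min_segment_nt:
            span3[side] = None
        else:
            start3 = _ceil_boundary(r, f)
            hi = _floor_boundary(next_l if next_l is not None else L, f)
            end3 = min(start3 + window_nt, hi)
            if end3 <= start3:
                span3[side] = None
                trunc = True
            else:
                span3[side] = (start3, end3)
                trunc = trunc or (end3 - start3 < window_nt)
        truncated[side] = trunc
        if trunc:
            logger.debug(
                "truncated flanking window for indel at [%d,%d) side %s", l, r, side
            )
    return FlankWindows(span5=span5, span3=span3, truncated=truncated)


def remote_codon_starts(
    aln: PairwiseAlignment,
    indels: Iterable[Indel],
    side: str,
    collar_nt: int = FLANK_NT,
) -> List[int]:
    """Start positions of complete in-frame codons >``collar_nt`` from all indels.

    A position at ungapped distance d from an indel span is excluded when
    d <= collar_nt; positions inside a span have distance 0.  With no indels
    the whole CDS is remote.
    """
    seq = aln.seq(side)
    L = len(seq)
    f = aln.frame(side)
    allowed = np.ones(L, dtype=bool)
    for d in indels:
        l, r = d.interval(side)
        lo = max(0, l - collar_nt)
        hi = min(L, r + collar_nt)
        allowed[lo:hi] = False
    starts = []
    for s in range(f, L - 2, 3):
        if allowed[s] and allowed[s + 1] and allowed[s + 2]:
            starts.append(s)
    return starts


def extract_remote_regions(
    aln: PairwiseAlignment,
    indels: Iterable[Indel],
    collar_nt: int = FLANK_NT,
) -> Dict[str, List[str]]:
    """Per-side codon lists of the indel-remote portion of the alignment."""
    indels = list(indels)
    out = {}
    for side in ("a", "b"):
        seq = aln.seq(side)
        out[side] = [
            seq[s : s + 3] for s in remote_codon_starts(aln, indels, side, collar_nt)
        ]
    return out


class RegionClass(str, Enum):
    WHOLE = "whole"
    FLANK5 = "flank5"
    FLANK3 = "flank3"
    TWO_SIDES = "two_sides"
    REMOTE = "remote"


@dataclass
class RegionCodons:
    """Pooled per-region codon lists for one sample side ('a' or 'b')."""

    codons: Dict[RegionClass, List[str]] = field(
        default_factory=lambda: {rc: [] for rc in RegionClass}
    )
    #: per-region codon lists grouped by source CDS, for boundary-pair counting
    per_record: Dict[RegionClass, List[List[str]]] = field(
        default_factory=lambda: {rc: [] for rc in RegionClass}
    )

    def add(self, region: RegionClass, codons: List[str]) -> None:
        if not codons:
            return
        self.codons[region].extend(codons)
        self.per_record[region].append(codons)


def classify_region_codons(
    alignments: Iterable[PairwiseAlignment],
    window_nt: int = FLANK_NT,
    min_segment_nt: int = MIN_SEGMENT_NT,
    min_terminal_nt: int = MIN_TERMINAL_NT,
) -> Dict[str, RegionCodons]:
    """Pool whole/flank5/flank3/two_sides/remote codons over an alignment set."""
    out = {"a": RegionCodons(), "b": RegionCodons()}
    for aln in alignments:
        indels = find_indels(aln)
        eligible = filter_eligible_indels(indels, aln, min_terminal_nt)
        for side in ("a", "b"):
            seq = aln.seq(side)
            f = aln.frame(side)
            whole = [seq[p : p + 3] for p in range(f, len(seq) - 2, 3)]
            out[side].add(RegionClass.WHOLE, whole)
        for d in eligible:
            windows = extract_flanking_windows(
                aln, d, indels=indels, window_nt=window_nt, min_segment_nt=min_segment_nt
            )
            for side in ("a", "b"):
                c5 = windows.codons(aln, side, "flank5")
                c3 = windows.codons(aln, side, "flank3")
                out[side].add(RegionClass.FLANK5, c5)
                out[side].add(RegionClass.FLANK3, c3)
                out[side].add(RegionClass.TWO_SIDES, c5 + c3)
        remote = extract_remote_regions(aln, indels, collar_nt=window_nt)
        for side in ("a", "b"):
            out[side].add(RegionClass.REMOTE, remote[side])
    return out


def regional_scub(
    regions: RegionCodons, code: GeneticCodeTable = STANDARD_CODE
) -> Dict[RegionClass, Optional[EndingFrequencies]]:
    """Ending frequencies per region class; ``None`` for empty regions."""
    out: Dict[RegionClass, Optional[EndingFrequencies]] = {}
    for rc in RegionClass:
        counts = CodonCounts.from_codons(regions.codons[rc], code=code)
        if counts.n_sc(code) == 0:
            logger.warning("region %s has no synonymous codons", rc.value)
            out[rc] = None
        else:
            out[rc] = EndingFrequencies.from_counts(counts, code)
    return out


def region_codon_counts(
    regions: RegionCodons, code: GeneticCodeTable = STANDARD_CODE
) -> Dict[RegionClass, CodonCounts]:
    return {
        rc: CodonCounts.from_codons(regions.codons[rc], code=code) for rc in RegionClass
    }


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap global alignment scores (BLAST-like defaults)."""

    match: float = 2.0
    mismatch: float = -3.0
    open_gap: float = -7.0
    extend_gap: float = -2.0


def align_pair(
    a: CdsRecord, b: CdsRecord, params: AlignParams = AlignParams()
) -> PairwiseAlignment:
    """Deterministic global pairwise alignment of two CDS records."""
    from Bio import Align

    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.open_gap
    aligner.extend_gap_score = params.extend_gap
    best = aligner.align(a.sequence, b.sequence)[0]
    logger.debug(
        "aligned %s/%s with match=%s mismatch=%s open=%s extend=%s",
        a.id, b.id, params.match, params.mismatch, params.open_gap, params.extend_gap,
    )
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        aligned_a=str(best[0]),
        aligned_b=str(best[1]),
        frame_a=a.frame_offset,
        frame_b=b.frame_offset,
    )
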