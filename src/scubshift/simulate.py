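"""Synthetic recipient/hybrid CDS pairs with known mutational structure.

The generator emulates a single hybridization event: an ancestral (recipient)
CDS set with C/G-ending codon dominance, and a derived (hybrid) set produced
by one round of point substitution and frame-preserving deletions.  The
substitution process carries two tunable biases: a CpG-context multiplier
whose excess mutations are deamination-targeted (C->T at the C, G->A at the
G of CpG), and a rate multiplier within a window around each indel.  Every
event is recorded so derived sequences can be replayed from the truth, and
gap-exact alignments are emitted without realignment.

Substitutions that would change the encoded amino acid (including stop
creation or loss) are rejected by default, emulating purifying selection on
coding sequence; rejection counts are logged since they perturb realized
rates.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .codons import STANDARD_CODE, CdsRecord, GeneticCodeTable
from .indels import PairwiseAlignment
from .partitions import DEFAULT_INTROGRESSED, UNMAPPED, WHEAT_CHROMOSOMES

logger = logging.getLogger(__name__)

_B2I = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _B2I[_b] = _i
_I2B = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    pass


@dataclass
class MutationParams:
    """Parameters of the single-generation mutation process."""

    sub_rate: float = 0.001
    cpg_multiplier: float = 1.0
    indel_rate: float = 0.0           # expected indels per CDS (Poisson)
    indel_lengths: Tuple[int, ...] = (3, 6, 9)
    flank_multiplier: float = 1.0
    flank_window: int = 45
    min_indel_separation: int = 90
    min_terminal_clearance: int = 46
    reject_nonsynonymous: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ConfigError(f"sub_rate must be in [0,1], got {self.sub_rate}")
        if self.indel_rate < 0:
            raise ConfigError(f"indel_rate must be >= 0, got {self.indel_rate}")
        if self.cpg_multiplier < 1 or self.flank_multiplier < 1:
            raise ConfigError("multipliers must be >= 1")
        if not self.indel_lengths or any(n < 1 for n in self.indel_lengths):
            raise ConfigError("indel_lengths must be positive")
        for n in self.indel_lengths:
            if n % 3:
                logger.warning("indel length %d is not a multiple of 3", n)


@dataclass
class SubEvent:
    pos: int
    ref: str
    alt: str
    context: str  # 'cpg_sense', 'cpg_antisense' or 'random'
    in_flank: bool


@dataclass
class IndelEvent:
    pos: int       # ancestral coordinate of the deletion start
    length: int
    kind: str = "deletion"


@dataclass
class RecordTruth:
    substitutions: List[SubEvent] = field(default_factory=list)
    indels: List[IndelEvent] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Full event log; replaying it on the ancestors reproduces the derived set."""

    params: MutationParams
    records: Dict[str, RecordTruth] = field(default_factory=dict)
    n_rejected: int = 0    # substitutions reverted by the selection filter
    n_clamped: int = 0     # sites whose effective rate was clamped to 1

    def replay(self, ancestral: Iterable[CdsRecord]) -> Dict[str, str]:
        out = {}
        for rec in ancestral:
            truth = self.records.get(rec.id, RecordTruth())
            seq = list(rec.sequence)
            for ev in truth.substitutions:
                if seq[ev.pos] != ev.ref:
                    raise ValueError(
                        f"truth mismatch at {rec.id}:{ev.pos} "
                        f"({seq[ev.pos]} != {ev.ref})"
                    )
                seq[ev.pos] = ev.alt
            deleted = np.zeros(len(seq), dtype=bool)
            for ev in truth.indels:
                deleted[ev.pos : ev.pos + ev.length] = True
            out[rec.id] = "".join(c for c, d in zip(seq, deleted) if not d)
        return out

    def to_json(self, path) -> None:
        payload = {
            "params": asdict(self.params),
            "n_rejected": self.n_rejected,
            "n_clamped": self.n_clamped,
            "records": {
                rid: {
                    "substitutions": [asdict(e) for e in t.substitutions],
                    "indels": [asdict(e) for e in t.indels],
                }
                for rid, t in self.records.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        params = dict(payload["params"])
        params["indel_lengths"] = tuple(params["indel_lengths"])
        truth = cls(
            params=MutationParams(**params),
            n_rejected=payload["n_rejected"],
            n_clamped=payload["n_clamped"],
        )
        for rid, t in payload["records"].items():
            truth.records[rid] = RecordTruth(
                substitutions=[SubEvent(**e) for e in t["substitutions"]],
                indels=[IndelEvent(**e) for e in t["indels"]],
            )
        return truth


def default_codon_usage(
    code: GeneticCodeTable = STANDARD_CODE,
    cg_weight: float = 2.0,
    at_weight: float = 1.0,
) -> Dict[str, float]:
    """C/G-ending-dominant usage over the SC set (normalized weights)."""
    codons = sorted(code.sc_set)
    w = np.array([cg_weight if c[2] in "CG" else at_weight for c in codons])
    w = w / w.sum()
    return dict(zip(codons, w))


def generate_ancestral_cds(
    n_records: int,
    length: int | Tuple[int, int] = 200,
    codon_usage: Optional[Dict[str, float]] = None,
    seed: int = 0,
    sample: str = "recipient",
    id_prefix: str = "cds",
    code: GeneticCodeTable = STANDARD_CODE,
) -> List[CdsRecord]:
    """Random CDS records: ATG start, SC-only body codons, TAA stop.

    ``length`` is the body length in codons, either fixed or a (lo, hi)
    inclusive range sampled uniformly per record.  Reproducible by seed.
    """
    if codon_usage is None:
        codon_usage = default_codon_usage(code)
    bad = set(codon_usage) - code.sc_set
    if bad:
        raise ConfigError(f"codon_usage has non-SC codons: {sorted(bad)}")
    codons = sorted(codon_usage)
    probs = np.array([codon_usage[c] for c in codons], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigError(f"codon usage sums to {probs.sum():.12f}, not 1")
    probs = probs / probs.sum()
    codon_arr = np.array(codons)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_records):
        if isinstance(length, tuple):
            n = int(rng.integers(length[0], length[1] + 1))
        else:
            n = int(length)
        body = codon_arr[rng.choice(len(codon_arr), size=n, p=probs)]
        seq = "ATG" + "".join(body) + "TAA"
        records.append(
            CdsRecord(id=f"{id_prefix}{i:05d}", sequence=seq, sample=sample)
        )
    return records


def _place_deletions(
    rng: np.random.Generator, L: int, params: MutationParams
) -> List[Tuple[int, int]]:
    """Uniform deletion spans honoring terminal clearance and separation."""
    k = rng.poisson(params.indel_rate)
    if k == 0:
        return []
    spans: List[Tuple[int, int]] = []
    clear = params.min_terminal_clearance
    sep = params.min_indel_separation
    attempts = 0
    while len(spans) < k and attempts < 20 * k:
        attempts += 1
        n = int(rng.choice(params.indel_lengths))
        lo, hi = clear, L - clear - n
        if hi < lo:
            break
        l = int(rng.integers(lo, hi + 1))
        r = l + n
        if all(l - r2 >= sep or l2 - r >= sep for l2, r2 in spans):
            spans.append((l, r))
    return sorted(spans)


@dataclass
class MutationResult:
    derived: List[CdsRecord]
    alignments: List[PairwiseAlignment]
    truth: SyntheticTruth


def mutate_genome(
    ancestral: Sequence[CdsRecord],
    params: MutationParams,
    sample: str = "hybrid",
    code: GeneticCodeTable = STANDARD_CODE,
) -> MutationResult:
    """One round of substitutions and deletions over an ancestral CDS set.

    CpG context is evaluated on the pre-mutation sequence; CpG-context sites
    get the base substitution channel (uniform random target) plus an excess
    channel at rate ``sub_rate * (cpg_multiplier - 1)`` whose target is the
    deamination product, so ``cpg_multiplier=1`` reduces exactly to the
    context-free process.  Sub-streams are derived from the global seed and
    each record id, so per-record output is order-independent.
    """
    truth = SyntheticTruth(params=params)
    derived: List[CdsRecord] = []
    alignments: List[PairwiseAlignment] = []
    codon_to_aa = code.codon_to_aa
    for rec in ancestral:
        rng = np.random.default_rng([params.seed, zlib.crc32(rec.id.encode())])
        seq_bytes = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        idx = _B2I[seq_bytes].astype(np.int64)
        if (idx < 0).any():
            raise ConfigError(f"record {rec.id} has non-ACGT characters")
        L = len(idx)
        rec_truth = RecordTruth()

        spans = _place_deletions(rng, L, params)
        deleted = np.zeros(L, dtype=bool)
        flank = np.zeros(L, dtype=bool)
        for l, r in spans:
            deleted[l:r] = True
            flank[max(0, l - params.flank_window) : l] = True
            flank[r : min(L, r + params.flank_window)] = True
            rec_truth.indels.append(IndelEvent(pos=l, length=r - l))

        # context masks on the ancestral sequence
        is_c = idx == 1
        is_g = idx == 2
        cpg_c = is_c.copy()
        cpg_c[:-1] &= is_g[1:]
        cpg_c[-1] = False
        cpg_g = is_g.copy()
        cpg_g[1:] &= is_c[:-1]
        cpg_g[0] = False
        cpg = cpg_c | cpg_g

        base_p = np.full(L, params.sub_rate)
        base_p[flank] *= params.flank_multiplier
        extra_p = np.where(cpg, base_p * (params.cpg_multiplier - 1.0), 0.0)
        clamped = int((base_p > 1).sum() + (extra_p > 1).sum())
        if clamped:
            truth.n_clamped += clamped
            logger.warning(
                "record %s: %d site rates clamped to 1", rec.id, clamped
            )
            base_p = np.minimum(base_p, 1.0)
            extra_p = np.minimum(extra_p, 1.0)
        base_p[deleted] = 0.0
        extra_p[deleted] = 0.0

        hit_random = rng.random(L) < base_p
        hit_deam = rng.random(L) < extra_p
        new_idx = idx.copy()
        rand_pos = np.nonzero(hit_random)[0]
        if rand_pos.size:
            shift = rng.integers(1, 4, size=rand_pos.size)
            new_idx[rand_pos] = (idx[rand_pos] + shift) % 4
        deam_pos = np.nonzero(hit_deam)[0]
        if deam_pos.size:
            # C->T (index 1 -> 3), G->A (index 2 -> 0); overrides random hits
            new_idx[deam_pos] = np.where(cpg_c[deam_pos], 3, 0)

        # purifying selection: revert codons with stop gain/loss or, by
        # default, any amino-acid change
        changed = np.nonzero(new_idx != idx)[0]
        if changed.size:
            seq = rec.sequence
            for j, pos in enumerate(changed):
                ci = (pos - rec.frame_offset) // 3
                if ci < 0:
                    continue
                start = rec.frame_offset + 3 * ci
                if start + 3 > L:
                    continue
                old_codon = seq[start : start + 3]
                new_codon = "".join(
                    "ACGT"[new_idx[q]] for q in range(start, start + 3)
                )
                old_aa = codon_to_aa[old_codon]
                new_aa = codon_to_aa[new_codon]
                reject = (new_aa != old_aa) if params.reject_nonsynonymous else (
                    new_aa == "*" and old_aa != "*"
                )
                if reject:
                    new_idx[start : start + 3] = idx[start : start + 3]
                    truth.n_rejected += 1

        final_pos = np.nonzero(new_idx != idx)[0]
        for pos in final_pos:
            ctx = "random"
            if hit_deam[pos] and cpg_c[pos]:
                ctx = "cpg_sense"
            elif hit_deam[pos] and cpg_g[pos]:
                ctx = "cpg_antisense"
            rec_truth.substitutions.append(
                SubEvent(
                    pos=int(pos),
                    ref="ACGT"[idx[pos]],
                    alt="ACGT"[new_idx[pos]],
                    context=ctx,
                    in_flank=bool(flank[pos]),
                )
            )

        mutated = _I2B[new_idx]
        derived_seq = mutated[~deleted].tobytes().decode("ascii")
        aligned_b = mutated.copy()
        aligned_b[deleted] = ord("-")
        derived.append(
            CdsRecord(
                id=rec.id,
                sequence=derived_seq,
                sample=sample,
                frame_offset=rec.frame_offset,
            )
        )
        alignments.append(
            PairwiseAlignment(
                id_a=rec.id,
                id_b=rec.id,
                aligned_a=rec.sequence,
                aligned_b=aligned_b.tobytes().decode("ascii"),
                frame_a=rec.frame_offset,
                frame_b=rec.frame_offset,
            )
        )
        truth.records[rec.id] = rec_truth
    if truth.n_rejected:
        logger.info(
            "selection filter reverted %d substitution-bearing codons",
            truth.n_rejected,
        )
    return MutationResult(derived=derived, alignments=alignments, truth=truth)


def assign_chromosomes(
    record_ids: Sequence[str],
    introgressed_set: Iterable[str] = DEFAULT_INTROGRESSED,
    unmapped_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform chromosome assignment over the 21 wheat chromosomes."""
    introgressed_set = set(introgressed_set)
    bad = introgressed_set - set(WHEAT_CHROMOSOMES)
    if bad:
        raise ConfigError(f"invalid introgressed chromosome names: {sorted(bad)}")
    if not 0.0 <= unmapped_frac <= 1.0:
        raise ConfigError("unmapped_frac must be in [0,1]")
    rng = np.random.default_rng(seed)
    chroms = []
    for _ in record_ids:
        if rng.random() < unmapped_frac:
            chroms.append(UNMAPPED)
        else:
            chroms.append(WHEAT_CHROMOSOMES[rng.integers(0, len(WHEAT_CHROMOSOMES))])
    return pd.DataFrame({"record_id": list(record_ids), "chromosome": chroms})
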