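"""FASTA and TSV plumbing shared by the CLI and the pipeline."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import CdsRecord
from .indels import PairwiseAlignment

logger = logging.getLogger(__name__)


def read_cds_fasta(path, sample: str = "", frame_offset: int = 0) -> List[CdsRecord]:
    """Load a CDS FASTA; record ids must be unique within the file."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            CdsRecord(
                id=rec.id,
                sequence=str(rec.seq),
                sample=sample,
                frame_offset=frame_offset,
            )
        )
    logger.info("read %d CDS records from %s (sample=%s)", len(records), path, sample)
    return records


def write_cds_fasta(records: Iterable[CdsRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.sample) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_aligned_fasta(path) -> List[PairwiseAlignment]:
    """Read gapped pairs: consecutive records form one (recipient, hybrid) pair."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise ValueError(f"{path}: aligned FASTA must hold an even record count")
    alignments = []
    for i in range(0, len(records), 2):
        a, b = records[i], records[i + 1]
        alignments.append(
            PairwiseAlignment(
                id_a=a.id,
                id_b=b.id,
                aligned_a=str(a.seq).upper(),
                aligned_b=str(b.seq).upper(),
            )
        )
    return alignments


def write_aligned_fasta(alignments: Iterable[PairwiseAlignment], path) -> None:
    seq_records = []
    for aln in alignments:
        seq_records.append(
            SeqRecord(Seq(aln.aligned_a), id=aln.id_a, description="recipient")
        )
        seq_records.append(
            SeqRecord(Seq(aln.aligned_b), id=aln.id_b, description="hybrid")
        )
    SeqIO.write(seq_records, str(path), "fasta")


def write_tsv(df: pd.DataFrame, path) -> None:
    """Deterministic TSV output with fixed float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
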