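"""Readers and writers for the standard formats the pipeline touches.

CCS reads come in as FASTA/FASTQ (per-read pass count encoded in the
description as ``np=<int>``) or as unaligned BAM with an integer pass-
count tag (the long-read convention).  Droplet and plate tables are CSV
with documented headers.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ddpcr import WELL_COLUMNS, DropletWell
from .msd import PLATE_COLUMNS, MsdWell
from .repeatcall import CcsRead

logger = logging.getLogger(__name__)

_NP_RE = re.compile(r"np=(\d+)")

_FORMAT_BY_SUFFIX = {
    ".fa": "fasta",
    ".fasta": "fasta",
    ".fna": "fasta",
    ".fq": "fastq",
    ".fastq": "fastq",
    ".bam": "bam",
    ".sam": "bam",
}


def _detect_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint:
        return format_hint.lower()
    fmt = _FORMAT_BY_SUFFIX.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer read format from {path.name!r}")
    return fmt


def read_reads(
    path: str | Path,
    format_hint: Optional[str] = None,
    pass_tag: str = "np",
) -> list[CcsRead]:
    """Read CCS reads from FASTA/FASTQ/BAM.

    Pass counts come from the ``np=`` description field (FASTA/FASTQ) or
    the integer ``pass_tag`` (BAM); records without one default to 1 pass
    with a warning.  Malformed records are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    reads: list[CcsRead] = []
    if fmt == "bam":
        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
            for rec in bam.fetch(until_eof=True):
                seq = rec.query_sequence
                if not seq:
                    logger.warning("skipping empty BAM record %s", rec.query_name)
                    continue
                if rec.has_tag(pass_tag):
                    passes = int(rec.get_tag(pass_tag))
                else:
                    passes = 1
                    logger.warning(
                        "read %s lacks %s tag; assuming 1 pass", rec.query_name, pass_tag
                    )
                reads.append(CcsRead(rec.query_name, seq, passes, source=path.name))
        return reads
    for rec in SeqIO.parse(str(path), fmt):
        seq = str(rec.seq)
        if not seq:
            logger.warning("skipping empty record %s", rec.id)
            continue
        m = _NP_RE.search(rec.description or "")
        if m:
            passes = int(m.group(1))
        else:
            passes = 1
            logger.warning("read %s lacks np= field; assuming 1 pass", rec.id)
        reads.append(CcsRead(rec.id, seq, passes, source=path.name))
    return reads


def write_fasta(reads: Iterable[CcsRead], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description=f"np={r.passes}")
        for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[CcsRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description=f"np={r.passes}")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_bam(reads: Iterable[CcsRead], path: str | Path, pass_tag: str = "np") -> None:
    """Write unaligned BAM with the integer pass-count tag."""
    header = {"HD": {"VN": "1.6", "SO": "unknown"}}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 4  # unmapped
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
            a.set_tag(pass_tag, r.passes, value_type="i")
            bam.write(a)


def read_droplet_csv(path: str | Path) -> list[DropletWell]:
    """CSV schema: sample_id,target,bio_replicate,tech_replicate,
    positive_droplets,total_droplets."""
    df = pd.read_csv(path)
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"droplet CSV missing columns: {sorted(missing)}")
    return [
        DropletWell(
            sample_id=str(row.sample_id),
            target=str(row.target),
            positive_droplets=int(row.positive_droplets),
            total_droplets=int(row.total_droplets),
            bio_replicate=int(row.bio_replicate),
            tech_replicate=int(row.tech_replicate),
        )
        for row in df.itertuples()
    ]


def write_droplet_csv(wells: Iterable[DropletWell], path: str | Path) -> None:
    pd.DataFrame([w.__dict__ for w in wells], columns=WELL_COLUMNS).to_csv(
        path, index=False
    )


def read_msd_csv(path: str | Path) -> list[MsdWell]:
    """CSV schema: capture_ab,detection_ab,sample_type,condition_id,
    replicate_id,signal (optional capture_lot)."""
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"MSD CSV missing columns: {sorted(missing)}")
    return [
        MsdWell(
            capture_ab=str(row.capture_ab),
            detection_ab=str(row.detection_ab),
            sample_type=str(row.sample_type),
            condition_id=str(row.condition_id),
            signal=float(row.signal),
            replicate_id=int(row.replicate_id),
            capture_lot=str(getattr(row, "capture_lot", "")),
        )
        for row in df.itertuples()
    ]


def write_msd_csv(wells: Iterable[MsdWell], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "capture_ab": w.capture_ab,
                "detection_ab": w.detection_ab,
                "sample_type": w.sample_type,
                "condition_id": w.condition_id,
                "replicate_id": w.replicate_id,
                "signal": w.signal,
            }
            for w in wells
        ],
        columns=PLATE_COLUMNS,
    ).to_csv(path, index=False)
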