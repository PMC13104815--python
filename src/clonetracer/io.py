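"""File formats: FASTQ, SAM with CB/UB tags, TSV tables, provenance records.

FASTQ goes through Biopython, SAM through pysam (unaligned records with
10x-style ``CB:Z:``/``UB:Z:`` tags), tables through pandas as tab-delimited
UTF-8 with Unix newlines and a header line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .extract import TaggedRead
from .stats import CloneCountTable


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        quals = r.qualities if r.qualities is not None else [40] * len(r.sequence)
        rec.letter_annotations["phred_quality"] = quals
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path, sample: str | None = None):
    sample = sample if sample is not None else Path(path).stem
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            TaggedRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=rec.letter_annotations.get("phred_quality"),
                sample=sample,
            )
        )
    return out


def write_sam(reads, path, reference_name: str = "barcode_vector") -> None:
    """Write reads as unmapped SAM records carrying CB/UB tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": reference_name, "LN": 10000}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 4  # unmapped; the extractor takes records, not alignments
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.qualities)
            ) if r.qualities is not None else None
            tags = []
            if r.cell_barcode is not None:
                tags.append(("CB", r.cell_barcode))
            if r.umi is not None:
                tags.append(("UB", r.umi))
            if tags:
                a.set_tags(tags)
            out.write(a)


def read_sam(path, sample: str | None = None):
    """Read SAM/BAM records (aligned or not) into TaggedReads, pulling CB/UB
    tags when present."""
    sample = sample if sample is not None else Path(path).stem
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.query_sequence is None:
                continue
            out.append(
                TaggedRead(
                    read_id=rec.query_name,
                    sequence=rec.query_sequence.upper(),
                    qualities=(
                        list(rec.query_qualities)
                        if rec.query_qualities is not None
                        else None
                    ),
                    cell_barcode=rec.get_tag("CB") if rec.has_tag("CB") else None,
                    umi=rec.get_tag("UB") if rec.has_tag("UB") else None,
                    sample=sample,
                )
            )
    return out


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_clone_table(table: CloneCountTable, path) -> None:
    write_tsv(table.to_frame(), path)


def read_clone_table(path, sample: str | None = None) -> CloneCountTable:
    df = read_tsv(path)
    required = {"sample", "clone_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if sample is not None:
        df = df[df["sample"] == sample]
    samples = df["sample"].unique()
    if len(samples) != 1:
        raise ValueError(f"{path}: expected one sample, found {list(samples)}")
    unit = df["unit"].iloc[0] if "unit" in df.columns else "cells"
    return CloneCountTable(
        sample=str(samples[0]),
        counts=dict(zip(df["clone_id"].astype(str), df["count"])),
        abundance_unit=str(unit),
    )


def file_checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir, config: dict, inputs=()) -> Path:
    """Machine-readable run record: config, tool version, input checksums."""
    from . import __version__

    record = {
        "tool": "clonetracer",
        "version": __version__,
        "config": config,
        "inputs": {str(p): file_checksum(p) for p in inputs},
    }
    path = Path(out_dir) / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path
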