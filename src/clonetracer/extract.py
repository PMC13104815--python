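"""Clone-barcode extraction from tagged or bulk sequencing reads.

The extractor scans each read for the fixed vector anchor, takes the
following bases as the clonal barcode, and pushes every read through a QC
cascade: no anchor, empty vector (anchor followed by fixed vector sequence
instead of a barcode), barcode truncated before the clone-ID region, and
clone IDs violating the degenerate pattern.  Passing hits are UMI-deduplicated
into molecules and resolved per cell; cells retaining more than one genuine
clone ID are rejected, so each retained cell maps to exactly one clone.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .patterns import BarcodePattern, reverse_complement


class HitStatus(str, Enum):
    PASS = "PASS"
    NO_ANCHOR = "NO_ANCHOR"
    EMPTY_VECTOR = "EMPTY_VECTOR"
    SHORT_BARCODE = "SHORT_BARCODE"
    BAD_PATTERN = "BAD_PATTERN"


@dataclass
class TaggedRead:
    """One sequencing read; CB/UB tags are both present (tagged single-cell
    mode) or both absent (bulk mode)."""

    read_id: str
    sequence: str
    qualities: list[int] | None = None
    cell_barcode: str | None = None
    umi: str | None = None
    sample: str = "sample"


@dataclass
class BarcodeHit:
    """Classified anchor/barcode extraction from one read."""

    read_id: str
    status: HitStatus
    anchor_position: int | None = None
    barcode_sequence: str = ""
    clone_id: str = ""
    cell_barcode: str | None = None
    umi: str | None = None
    sample: str = "sample"
    orientation: str = "+"


@dataclass
class CellQCThresholds:
    """Per-cell filtering thresholds for single-cell expression QC.

    Cells are kept when detected genes >= ``min_genes``, total UMIs <=
    ``max_umis``, mitochondrial read fraction <= ``max_mito_fraction`` and
    (for xenograft data) mouse-mapped read fraction <= ``max_mouse_fraction``.
    Boundary values are retained.
    """

    min_genes: int = 2000
    max_umis: int = 50000
    max_mito_fraction: float = 0.20
    max_mouse_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.min_genes <= 0 or self.max_umis <= 0:
            raise ValueError("count thresholds must be positive")
        for f in (self.max_mito_fraction, self.max_mouse_fraction):
            if not 0 < f <= 1:
                raise ValueError("fraction thresholds must lie in (0, 1]")


def find_anchor(sequence: str, anchor: str, max_mismatches: int = 2) -> int | None:
    """Leftmost 0-based position where ``anchor`` aligns to ``sequence`` with
    Hamming distance <= ``max_mismatches``; ``None`` if no window qualifies
    (including when the anchor is longer than the read)."""
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    m, n = len(anchor), len(sequence)
    if m > n:
        return None
    if max_mismatches == 0:
        pos = sequence.find(anchor)
        return pos if pos >= 0 else None
    a = np.frombuffer(sequence.encode(), dtype=np.uint8)
    b = np.frombuffer(anchor.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(a, m)
    mm = (windows != b).sum(axis=1)
    hits = np.nonzero(mm <= max_mismatches)[0]
    return int(hits[0]) if hits.size else None


def _classify(seq: str, start: int, pattern: BarcodePattern, max_mismatches: int):
    """Classify the post-anchor region of ``seq`` with the anchor at ``start``.
    Returns (status, barcode_sequence, clone_id)."""
    tail = seq[start + len(pattern.anchor) :]
    if len(tail) < pattern.id_length:
        return HitStatus.SHORT_BARCODE, tail, ""
    # empty-vector call: the post-anchor window resembles the fixed vector
    # sequence at least as well as a pattern-conformant barcode would
    w = min(len(pattern.downstream_fixed), len(tail))
    if w >= pattern.id_length:
        window = tail[:w]
        mm_fixed = sum(x != y for x, y in zip(window, pattern.downstream_fixed))
        mm_pattern = pattern.count_mismatches(window)
        if mm_fixed <= max_mismatches and mm_fixed <= mm_pattern:
            return HitStatus.EMPTY_VECTOR, window, ""
    clone_id = tail[: pattern.id_length]
    if pattern.count_mismatches(clone_id) > 0:
        return HitStatus.BAD_PATTERN, tail[: pattern.length], ""
    return HitStatus.PASS, tail[: pattern.length], clone_id


def extract_barcode(
    read: TaggedRead,
    pattern: BarcodePattern | None = None,
    max_mismatches: int = 2,
) -> BarcodeHit:
    """Locate the anchor in ``read`` and classify the downstream barcode.

    Every read yields exactly one classified hit.  In bulk mode (no CB/UB
    tags) the reverse complement is scanned as well when the forward strand
    carries no anchor, and the orientation is recorded.
    """
    if pattern is None:
        pattern = BarcodePattern()
    seq = read.sequence.upper()
    pos = find_anchor(seq, pattern.anchor, max_mismatches)
    orientation = "+"
    if pos is None and read.cell_barcode is None and read.umi is None:
        rc = reverse_complement(seq)
        pos_rc = find_anchor(rc, pattern.anchor, max_mismatches)
        if pos_rc is not None:
            seq, pos, orientation = rc, pos_rc, "-"
    base = dict(
        read_id=read.read_id,
        cell_barcode=read.cell_barcode,
        umi=read.umi,
        sample=read.sample,
        orientation=orientation,
    )
    if pos is None:
        return BarcodeHit(status=HitStatus.NO_ANCHOR, **base)
    status, bc_seq, clone_id = _classify(seq, pos, pattern, max_mismatches)
    return BarcodeHit(
        status=status,
        anchor_position=pos,
        barcode_sequence=bc_seq,
        clone_id=clone_id,
        **base,
    )


def extract_hits(
    reads,
    pattern: BarcodePattern | None = None,
    max_mismatches: int = 2,
) -> list[BarcodeHit]:
    """Vector version of :func:`extract_barcode` over an iterable of reads."""
    if pattern is None:
        pattern = BarcodePattern()
    return [extract_barcode(r, pattern, max_mismatches) for r in reads]


def hits_to_frame(hits) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            read_id=h.read_id,
            sample=h.sample,
            status=h.status.value,
            anchor_position=h.anchor_position,
            barcode_sequence=h.barcode_sequence,
            clone_id=h.clone_id,
            cell_barcode=h.cell_barcode,
            umi=h.umi,
            orientation=h.orientation,
        )
        for h in hits
    )


def dedup_umis(hits) -> pd.DataFrame:
    """Collapse PASS hits to molecules: one row per distinct
    (sample, cell_barcode, umi, clone_id), exact string match only, with the
    collapsed read count.

    Tagged mode requires both CB and UB on every hit; hits missing either are
    excluded and surface in the returned frame's ``attrs['excluded']``.
    """
    rows = []
    excluded = []
    for h in hits:
        if h.status is not HitStatus.PASS:
            continue
        if h.cell_barcode is None and h.umi is None:
            # bulk: each read is its own molecule observation
            rows.append((h.sample, h.read_id, h.read_id, h.clone_id))
        elif h.cell_barcode is None or h.umi is None:
            excluded.append(h.read_id)
        else:
            rows.append((h.sample, h.cell_barcode, h.umi, h.clone_id))
    df = pd.DataFrame(rows, columns=["sample", "cell_barcode", "umi", "clone_id"])
    mol = (
        df.groupby(["sample", "cell_barcode", "umi", "clone_id"], sort=True)
        .size()
        .rename("read_count")
        .reset_index()
    )
    mol.attrs["excluded"] = excluded
    return mol


@dataclass
class CellCloneTable:
    """High-confidence cell -> clone assignments plus rejected cells.

    ``assignments`` columns: sample, cell_barcode, clone_id, umi_count.
    ``rejected`` columns: sample, cell_barcode, reason.
    """

    assignments: pd.DataFrame
    rejected: pd.DataFrame


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


def _directional_merge(counts: dict[str, int], max_dist: int) -> dict[str, int]:
    """Collapse sequencing-error clone IDs into their parent within a cell:
    id ``a`` merges into the more abundant ``b`` when Hamming(a, b) <=
    ``max_dist`` and 2 * count_a <= count_b (directional adjacency rule)."""
    if max_dist <= 0 or len(counts) < 2:
        return dict(counts)
    order = sorted(counts, key=lambda c: (-counts[c], c))
    merged: dict[str, int] = {}
    for cid in order:
        target = None
        for parent in merged:
            if _hamming(cid, parent) <= max_dist and 2 * counts[cid] <= counts[parent]:
                target = parent
                break
        if target is None:
            merged[cid] = counts[cid]
        else:
            merged[target] += counts[cid]
    return merged


def resolve_cells(
    molecules: pd.DataFrame,
    noise_min_umis: int = 2,
    noise_min_fraction: float = 0.1,
    merge_hamming: int = 1,
) -> CellCloneTable:
    """Resolve each cell to a single clone ID or reject it.

    Per (sample, cell_barcode): error-derived IDs are first collapsed into
    their abundant Hamming neighbours (``merge_hamming``; 0 disables), then
    clone IDs supported by fewer than ``noise_min_umis`` UMIs AND by less
    than ``noise_min_fraction`` of the cell's barcode UMIs are discarded as
    ambient/chimeric noise.  A cell retaining exactly one clone ID is kept;
    >= 2 is rejected MULTI_BARCODE; zero is rejected NO_BARCODE.
    """
    kept, rejected = [], []
    if len(molecules) == 0:
        return CellCloneTable(
            assignments=pd.DataFrame(
                columns=["sample", "cell_barcode", "clone_id", "umi_count"]
            ),
            rejected=pd.DataFrame(columns=["sample", "cell_barcode", "reason"]),
        )
    grouped = molecules.groupby(["sample", "cell_barcode"], sort=True)
    for (sample, cb), grp in grouped:
        counts = grp.groupby("clone_id").size().to_dict()
        counts = _directional_merge(counts, merge_hamming)
        total = sum(counts.values())
        genuine = {
            cid: n
            for cid, n in counts.items()
            if not (n < noise_min_umis and n / total < noise_min_fraction)
        }
        if len(genuine) == 1:
            (cid, n), = genuine.items()
            kept.append((sample, cb, cid, n))
        elif len(genuine) >= 2:
            rejected.append((sample, cb, "MULTI_BARCODE"))
        else:
            rejected.append((sample, cb, "NO_BARCODE"))
    return CellCloneTable(
        assignments=pd.DataFrame(
            kept, columns=["sample", "cell_barcode", "clone_id", "umi_count"]
        ),
        rejected=pd.DataFrame(rejected, columns=["sample", "cell_barcode", "reason"]),
    )


def cell_qc_filter(
    metrics: pd.DataFrame, thresholds: CellQCThresholds | None = None
) -> tuple[set, pd.DataFrame]:
    """Filter cells on expression QC metrics.

    ``metrics`` requires columns cell_id, n_genes, n_umis, mito_fraction;
    mouse_fraction is optional (xenograft host-read filter).  Returns the set
    of retained cell_ids and a frame of rejections with semicolon-joined
    reasons (LOW_GENES, HIGH_UMIS, HIGH_MITO, MOUSE).
    """
    if thresholds is None:
        thresholds = CellQCThresholds()
    required = {"cell_id", "n_genes", "n_umis", "mito_fraction"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    reasons = []
    for _, row in metrics.iterrows():
        why = []
        if row["n_genes"] < thresholds.min_genes:
            why.append("LOW_GENES")
        if row["n_umis"] > thresholds.max_umis:
            why.append("HIGH_UMIS")
        if row["mito_fraction"] > thresholds.max_mito_fraction:
            why.append("HIGH_MITO")
        if (
            "mouse_fraction" in metrics.columns
            and pd.notna(row.get("mouse_fraction"))
            and row["mouse_fraction"] > thresholds.max_mouse_fraction
        ):
            why.append("MOUSE")
        reasons.append(";".join(why))
    metrics = metrics.assign(_reason=reasons)
    retained = set(metrics.loc[metrics["_reason"] == "", "cell_id"])
    rejected = (
        metrics.loc[metrics["_reason"] != "", ["cell_id", "_reason"]]
        .rename(columns={"_reason": "reason"})
        .reset_index(drop=True)
    )
    return retained, rejected
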