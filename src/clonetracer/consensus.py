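"""Full-length barcode reconstruction by position-wise plurality consensus.

Reads sharing a clone ID (the first bases after the vector anchor) are
stacked at their anchor offset — they are co-linear by construction, no
indel handling — and each barcode position is called from the plurality
base when coverage and majority-fraction floors are met.  Ambiguous or
under-covered positions are emitted as ``N``.  The resulting 265-bp sequence
is what probe design (e.g. barcode RNA-FISH) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extract import BarcodeHit, HitStatus
from .patterns import BarcodePattern

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_IDX_BASE = "ACGT"


@dataclass
class ReadStack:
    """Per-position base counts for one clone's reads.

    ``counts`` has shape (max_length, 4) over A/C/G/T; non-ACGT read bases
    contribute to neither counts nor depth.
    """

    clone_id: str
    counts: np.ndarray
    n_reads: int

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ConsensusResult:
    clone_id: str
    consensus: str
    per_position_support: list  # (depth, majority_fraction) per called position
    ambiguous_positions: list


def collect_reads_for_clone(
    hits: list[BarcodeHit],
    clone_id: str,
    max_length: int | None = None,
) -> ReadStack:
    """Stack the barcode sequences of PASS hits whose clone ID matches.

    Reads shorter than the full barcode contribute only their covered
    positions.  Raises ``NO_READS`` when nothing matches.
    """
    if max_length is None:
        max_length = BarcodePattern().length
    counts = np.zeros((max_length, 4), dtype=np.int64)
    n = 0
    for h in hits:
        if h.status is not HitStatus.PASS or h.clone_id != clone_id:
            continue
        n += 1
        for pos, base in enumerate(h.barcode_sequence[:max_length]):
            j = _BASE_IDX.get(base)
            if j is not None:
                counts[pos, j] += 1
    if n == 0:
        raise ValueError(f"NO_READS: no PASS reads carry clone ID {clone_id!r}")
    return ReadStack(clone_id=clone_id, counts=counts, n_reads=n)


def build_consensus(
    stack: ReadStack,
    min_depth: int = 3,
    min_majority: float = 0.6,
) -> ConsensusResult:
    """Position-wise plurality consensus over a read stack.

    A base is called where depth >= ``min_depth`` and the plurality fraction
    >= ``min_majority``; ties and failed majorities yield ``N`` and are
    recorded as ambiguous.  The consensus is truncated at the last position
    with depth >= ``min_depth``; interior positions below the depth floor are
    also ``N``.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0.5 < min_majority <= 1:
        raise ValueError("min_majority must lie in (0.5, 1]")
    depth = stack.depth
    if int(depth.sum()) == 0:
        raise ValueError("empty read stack")
    covered = np.nonzero(depth >= min_depth)[0]
    if covered.size == 0:
        raise ValueError(
            f"no position reaches min_depth={min_depth} (max depth {int(depth.max())})"
        )
    end = int(covered[-1]) + 1
    bases = []
    support = []
    ambiguous = []
    for pos in range(end):
        d = int(depth[pos])
        row = stack.counts[pos]
        top = int(row.max())
        frac = top / d if d else 0.0
        support.append((d, frac))
        if d < min_depth:
            bases.append("N")
            ambiguous.append(pos)
            continue
        winners = np.nonzero(row == top)[0]
        if winners.size != 1 or frac < min_majority:
            bases.append("N")
            ambiguous.append(pos)
        else:
            bases.append(_IDX_BASE[int(winners[0])])
    return ConsensusResult(
        clone_id=stack.clone_id,
        consensus="".join(bases),
        per_position_support=support,
        ambiguous_positions=ambiguous,
    )
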