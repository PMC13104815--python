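"""Clonal composition, diversity and metastatic-fate statistics.

Works on per-sample clone abundance tables (clone ID -> cells, UMIs or
reads).  Diversity is the Shannon index in natural log units,
``H = -sum p_i ln p_i``, with the Hutcheson variance estimator

    var(H) = [sum p_i (ln p_i)^2 - H^2] / N + (S - 1) / (2 N^2)

which supports a Welch-style two-sample t-test between the Shannon indices
of two samples (Hutcheson 1970).  Fate classification labels every clone
detected in the primary tumor by the set of metastatic sites where its
barcode reappears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CloneCountTable:
    """Per-sample clone abundances."""

    sample: str
    counts: dict  # clone_id -> nonnegative abundance
    abundance_unit: str = "cells"  # or "umis", "reads"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("abundances must be nonnegative")
        if self.abundance_unit not in ("cells", "umis", "reads"):
            raise ValueError(f"unknown abundance unit {self.abundance_unit!r}")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def nonzero(self) -> dict:
        return {c: v for c, v in self.counts.items() if v > 0}

    @classmethod
    def from_assignments(
        cls, assignments: pd.DataFrame, sample: str | None = None
    ) -> "CloneCountTable":
        """Cells-per-clone table from a cell->clone assignment frame."""
        df = assignments
        if sample is not None:
            df = df[df["sample"] == sample]
        elif df["sample"].nunique() == 1:
            sample = df["sample"].iloc[0]
        else:
            raise ValueError("multiple samples present; specify one")
        counts = df.groupby("clone_id").size().to_dict()
        return cls(sample=sample, counts=counts, abundance_unit="cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample,
                "clone_id": list(self.counts),
                "count": list(self.counts.values()),
                "unit": self.abundance_unit,
            }
        )


@dataclass
class DiversityStat:
    H: float
    var_H: float
    N: float
    S: int


@dataclass
class HutchesonResult:
    t: float
    df: float
    p_two_tailed: float


def clone_frequencies(table: CloneCountTable) -> list[tuple[str, float]]:
    """Relative clone frequencies, descending; ties broken lexicographically
    by clone ID.  Frequencies sum to 1."""
    nz = table.nonzero()
    total = sum(nz.values())
    if total <= 0:
        raise ValueError(f"sample {table.sample!r} has zero total abundance")
    return sorted(
        ((cid, v / total) for cid, v in nz.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )


def topk_share(table: CloneCountTable, k: int) -> float:
    """Cumulative relative frequency of the ``k`` most abundant clones."""
    if k < 1:
        raise ValueError("k must be >= 1")
    freqs = clone_frequencies(table)
    return float(sum(f for _, f in freqs[:k]))


def shannon_index(table: CloneCountTable) -> DiversityStat:
    """Shannon diversity (nats) with the Hutcheson variance estimator."""
    counts = np.array(list(table.nonzero().values()), dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError(f"sample {table.sample!r} has zero total abundance")
    n = counts.sum()
    p = counts / n
    logp = np.log(p)
    h = float(-(p * logp).sum())
    s = int(counts.size)
    var = float((np.sum(p * logp**2) - h**2) / n + (s - 1) / (2 * n**2))
    return DiversityStat(H=h, var_H=max(var, 0.0), N=float(n), S=s)


def hutcheson_test(a: CloneCountTable, b: CloneCountTable) -> HutchesonResult:
    """Two-tailed Hutcheson t-test comparing two Shannon indices.

    t = (H_a - H_b) / sqrt(var_a + var_b), with Welch-Satterthwaite degrees
    of freedom (var_a + var_b)^2 / (var_a^2 / N_a + var_b^2 / N_b).
    """
    da, db = shannon_index(a), shannon_index(b)
    vsum = da.var_H + db.var_H
    if vsum == 0:
        if math.isclose(da.H, db.H, abs_tol=1e-12):
            return HutchesonResult(t=0.0, df=float("inf"), p_two_tailed=1.0)
        raise ValueError(
            "zero estimator variance with unequal Shannon indices; input is "
            "inconsistent with the abundance model"
        )
    t = (da.H - db.H) / math.sqrt(vsum)
    df = vsum**2 / (da.var_H**2 / da.N + db.var_H**2 / db.N)
    p = float(2 * sps.t.sf(abs(t), df))
    return HutchesonResult(t=float(t), df=float(df), p_two_tailed=min(p, 1.0))


FATE_TUMOR_ONLY = "tumor_only"
FATE_SHARED = "shared"
FATE_MET_ONLY = "metastasis_only"


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (printed-precision rule)."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


@dataclass
class FateTable:
    """Per-clone metastatic fate plus per-fate lineage/cell summaries.

    ``clone_fates`` columns: clone_id, fate.  ``summary`` columns: fate,
    lineage_count, lineage_pct, cell_count, cell_pct; percentages are over
    primary-detected clones/cells only (metastasis-only clones are excluded
    from both denominators) and rounded to one decimal.
    """

    clone_fates: pd.DataFrame
    summary: pd.DataFrame


def classify_fates(
    primary: CloneCountTable,
    mets: dict[str, CloneCountTable],
    min_count: float = 1,
) -> FateTable:
    """Label each primary-tumor clone by the metastatic sites where it is
    detected (abundance >= ``min_count``).

    With two sites named ``lung`` and ``liver`` the fates are tumor_only,
    lung_only, liver_only and shared; with other site sets, singleton fates
    are ``<site>_only``, the all-sites fate is ``shared`` and intermediate
    subsets are '+'-joined site names.  Clones seen only in a metastasis are
    labeled metastasis_only and excluded from the primary denominators.
    """
    prim = {c for c, v in primary.counts.items() if v >= min_count}
    if not prim:
        raise ValueError("primary table has no detected clones")
    site_sets = {
        site: {c for c, v in t.counts.items() if v >= min_count}
        for site, t in mets.items()
    }
    all_sites = set(site_sets)

    def label(sites: set) -> str:
        if not sites:
            return FATE_TUMOR_ONLY
        if sites == all_sites and len(all_sites) > 1:
            return FATE_SHARED
        if len(sites) == 1:
            return f"{next(iter(sites))}_only"
        return "+".join(sorted(sites))

    rows = [
        (cid, label({s for s, members in site_sets.items() if cid in members}))
        for cid in sorted(prim)
    ]
    met_only = sorted(set().union(*site_sets.values()) - prim) if site_sets else []
    rows += [(cid, FATE_MET_ONLY) for cid in met_only]
    clone_fates = pd.DataFrame(rows, columns=["clone_id", "fate"])

    n_lineages = len(prim)
    n_cells = sum(v for c, v in primary.counts.items() if c in prim)
    fate_order = (
        [FATE_SHARED]
        + [f"{s}_only" for s in sorted(all_sites)]
        + [FATE_TUMOR_ONLY, FATE_MET_ONLY]
    )
    summary_rows = []
    for fate in fate_order:
        members = set(clone_fates.loc[clone_fates["fate"] == fate, "clone_id"])
        if fate == FATE_MET_ONLY:
            if not members:
                continue
            summary_rows.append((fate, len(members), float("nan"), 0, float("nan")))
            continue
        cells = sum(primary.counts.get(c, 0) for c in members)
        summary_rows.append(
            (
                fate,
                len(members),
                _round1(100 * len(members) / n_lineages),
                cells,
                _round1(100 * cells / n_cells) if n_cells else float("nan"),
            )
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=["fate", "lineage_count", "lineage_pct", "cell_count", "cell_pct"],
    )
    return FateTable(clone_fates=clone_fates, summary=summary)


def shared_across_samples(
    tables: list[CloneCountTable],
) -> tuple[set, pd.DataFrame]:
    """Clones detected (count > 0) in every table, with their per-sample
    relative frequencies (long-format bubble-plot table)."""
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    shared = set(tables[0].nonzero())
    for t in tables[1:]:
        shared &= set(t.nonzero())
    rows = []
    for t in tables:
        freqs = dict(clone_frequencies(t))
        for cid in sorted(shared):
            rows.append((t.sample, cid, freqs.get(cid, 0.0)))
    return shared, pd.DataFrame(rows, columns=["sample", "clone_id", "frequency"])


def dominant_clone_track(
    tables: list[CloneCountTable], clone_id: str | None = None
) -> pd.DataFrame:
    """Relative frequency of one clone across samples (0 where absent).

    Defaults to the most abundant clone of the first table, mirroring how a
    dominant primary-tumor clone is followed into the metastases.
    """
    if not tables:
        raise ValueError("need at least one table")
    if clone_id is None:
        clone_id = clone_frequencies(tables[0])[0][0]
    rows = []
    for t in tables:
        freqs = dict(clone_frequencies(t))
        rows.append((t.sample, clone_id, freqs.get(clone_id, 0.0)))
    return pd.DataFrame(rows, columns=["sample", "clone_id", "frequency"])
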