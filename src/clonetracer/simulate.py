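"""Generative model for barcoded lineage-tracing experiments.

The simulator reproduces the statistical structure the extractor and the
clonal statistics assume, end to end:

* a library of semi-random barcodes drawn from a degenerate pattern;
* Poisson transduction at a configurable MOI (integrations per cell);
* skewed clonal expansion in the primary tumor (Dirichlet-multinomial or
  lognormal-fitness birth/death weights);
* organ-specific bottlenecks (sampling cells or whole clones without
  replacement) founding each metastatic site;
* tagged (10x-style CB/UB) or bulk sequencing reads carrying the vector
  anchor followed by the clone barcode, with UMI duplication, empty-vector
  molecules and uniform substitution errors;
* truth tables (cell -> clone, molecule counts) for exact precision/recall
  accounting downstream.

Every function is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .patterns import (
    BarcodePattern,
    DEFAULT_UPSTREAM_CONTEXT,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the full generative model.

    Defaults describe a typical experiment of this design: transduction at
    MOI 0.3 (< 0.4 so most barcoded cells carry a single integration), a
    library far larger than the founder population, a skewed primary tumor
    and two metastatic sites founded through strong bottlenecks, and a
    highly expressed barcode transcript (about a dozen captured molecules
    per cell at modest sequencing saturation).
    """

    n_cells: int = 2000
    moi: float = 0.3
    library_size: int = 10000
    growth_model: str = "neutral_dirichlet"  # or "birth_death"
    growth_params: dict = field(
        default_factory=lambda: {"concentration": 0.3, "population_size": 20000}
    )
    bottleneck_sizes: dict = field(
        default_factory=lambda: {"lung": 400, "liver": 400}
    )
    bottleneck_unit: str = "cells"  # or "clones"
    sampled_cells_per_site: int = 300
    molecules_per_cell: float = 12.0
    reads_per_molecule: float = 2.0
    prefix_length: int = 20  # vector context 5' of the anchor in each read
    read_length: int = 318  # prefix + 33 bp anchor + full 265 bp barcode
    umi_length: int = 12
    cb_length: int = 16
    substitution_error_rate: float = 0.0
    empty_vector_fraction: float = 0.0
    tagged: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.library_size < 1:
            raise ValueError("n_cells and library_size must be positive")
        if self.moi < 0:
            raise ValueError("moi must be >= 0")
        for name in ("substitution_error_rate", "empty_vector_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.reads_per_molecule < 1 or self.molecules_per_cell < 1:
            raise ValueError("per-cell molecule and per-molecule read means must be >= 1")
        if self.growth_model not in ("neutral_dirichlet", "birth_death"):
            raise ValueError(f"unknown growth_model {self.growth_model!r}")
        if self.bottleneck_unit not in ("cells", "clones"):
            raise ValueError(f"unknown bottleneck_unit {self.bottleneck_unit!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls(**json.loads(text))


@dataclass
class ClonePopulation:
    """Clone abundances at one anatomical site."""

    site: str
    clone_barcodes: list  # full-length barcode per clone index (shared across sites)
    abundances: dict  # clone index -> cell count at this site

    @property
    def total(self) -> int:
        return int(sum(self.abundances.values()))

    def counts_array(self, n_clones: int | None = None) -> np.ndarray:
        n = n_clones if n_clones is not None else len(self.clone_barcodes)
        out = np.zeros(n, dtype=np.int64)
        for idx, c in self.abundances.items():
            out[idx] = c
        return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_library(pattern: BarcodePattern, n: int, seed: int) -> list[str]:
    """Draw ``n`` unique barcodes from the degenerate pattern.

    Each base is sampled uniformly from its IUPAC code's allowed set;
    duplicates are redrawn.  Raises if the pattern cannot produce ``n``
    distinct sequences.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if pattern.n_possible() < n:
        raise ValueError(
            f"pattern admits only {pattern.n_possible()} distinct sequences, "
            f"cannot draw {n} unique barcodes"
        )
    rng = np.random.default_rng(seed)
    allowed = [sorted(s) for s in pattern.allowed_sets]

    def draw(k: int) -> list[str]:
        cols = [rng.choice(np.frombuffer("".join(a).encode(), dtype=np.uint8), size=k)
                for a in allowed]
        mat = np.stack(cols, axis=1)
        return [row.tobytes().decode() for row in mat]

    out: list[str] = []
    seen: set[str] = set()
    need = n
    while need > 0:
        for bc in draw(need):
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
        need = n - len(out)
    return out


def simulate_transduction(
    n_cells: int, library: list[str], moi: float, seed: int
) -> dict[int, list[int]]:
    """Poisson(MOI) lentiviral integrations per cell, barcodes drawn uniformly
    with replacement from the library.  Returns cell index -> library indices
    (empty list for untransduced cells)."""
    if moi < 0:
        raise ValueError("moi must be >= 0")
    if moi > 0 and len(library) == 0:
        raise ValueError("cannot transduce from an empty library")
    rng = np.random.default_rng(seed)
    k = rng.poisson(moi, size=n_cells)
    total = int(k.sum())
    idx = rng.integers(0, len(library), size=total) if total else np.empty(0, int)
    out: dict[int, list[int]] = {}
    pos = 0
    for cell, ki in enumerate(k):
        out[cell] = [int(j) for j in idx[pos : pos + ki]]
        pos += ki
    return out


def _primary_counts(
    n_founders: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    params = config.growth_params
    pop = int(params.get("population_size", 20000))
    if config.growth_model == "neutral_dirichlet":
        conc = float(params.get("concentration", 0.3))
        p = rng.dirichlet(np.full(n_founders, conc))
    else:  # birth_death: lognormal per-clone fitness weights
        sigma = float(params.get("fitness_sigma", 1.0))
        w = rng.lognormal(mean=0.0, sigma=sigma, size=n_founders)
        p = w / w.sum()
    # multinomial keeps the configured population size exactly; founders that
    # draw zero cells have gone extinct during expansion
    return rng.multinomial(pop, p)


def simulate_growth_and_seeding(
    founders: dict[int, list[int]],
    config: SimulationConfig,
    library: list[str] | None = None,
) -> dict[str, ClonePopulation]:
    """Expand founder clones in the primary site and seed each metastatic site
    through its configured bottleneck.

    ``founders`` maps founder-cell index -> integrated library indices (the
    output of :func:`simulate_transduction`); untransduced cells are ignored.
    Each barcoded founder cell defines one clone; clone identity is preserved
    across sites.  Returns site name -> :class:`ClonePopulation`, with the
    primary under key ``"primary"``.
    """
    founder_items = [(c, bcs) for c, bcs in sorted(founders.items()) if bcs]
    if not founder_items:
        raise ValueError("no barcoded founder clones")
    rng = np.random.default_rng(config.seed + 1)
    if library is None:
        # barcodes referenced by index only; synthesize placeholders lazily
        raise ValueError("library of barcode strings is required")
    # clone i carries the (possibly multiple) barcodes of founder cell i
    clone_barcode_lists = [[library[j] for j in bcs] for _, bcs in founder_items]
    n_clones = len(clone_barcode_lists)

    primary = _primary_counts(n_clones, config, rng)
    pops = {
        "primary": ClonePopulation(
            site="primary",
            clone_barcodes=clone_barcode_lists,
            abundances={i: int(c) for i, c in enumerate(primary) if c > 0},
        )
    }
    for site, size in config.bottleneck_sizes.items():
        size = int(size)
        if config.bottleneck_unit == "cells":
            if size > primary.sum():
                raise ValueError(
                    f"bottleneck for {site!r} ({size}) exceeds primary population "
                    f"({int(primary.sum())})"
                )
            seeded = rng.multivariate_hypergeometric(primary, size, method="marginals")
        else:
            alive = np.nonzero(primary)[0]
            if size > alive.size:
                raise ValueError(
                    f"bottleneck for {site!r} ({size} clones) exceeds surviving "
                    f"clone count ({alive.size})"
                )
            p = primary[alive] / primary[alive].sum()
            chosen = alive[rng.choice(alive.size, size=size, replace=False, p=p)]
            seeded = np.zeros(n_clones, dtype=np.int64)
            seeded[chosen] = primary[chosen]
        pops[site] = ClonePopulation(
            site=site,
            clone_barcodes=clone_barcode_lists,
            abundances={i: int(c) for i, c in enumerate(seeded) if c > 0},
        )
    return pops


@dataclass
class SimulatedReads:
    """Reads plus ground truth emitted by :func:`simulate_reads`.

    ``cell_truth`` rows: site, cell_id, cell_barcode, clone_index,
    n_integrations, full_barcode (first integration).  ``molecule_truth``
    rows: site, cell_barcode, umi, clone_index.
    """

    reads: list  # list[TaggedRead]
    cell_truth: "object"  # pandas.DataFrame
    molecule_truth: "object"  # pandas.DataFrame


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # substitute with one of the three other bases
        orig = arr[hit]
        subs = _BASES[rng.integers(0, 4, size=hit.size)]
        clash = subs == orig
        while clash.any():
            subs[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
            clash = subs == orig
        arr[hit] = subs
    return arr.tobytes().decode()


def simulate_reads(
    populations: dict[str, ClonePopulation] | list[ClonePopulation],
    config: SimulationConfig,
    pattern: BarcodePattern | None = None,
) -> SimulatedReads:
    """Generate anchor+barcode sequencing reads for sampled cells of each site.

    Per site, ``sampled_cells_per_site`` cells are captured (without
    replacement) from the clone abundance distribution.  Each cell yields a
    truncated-Poisson number of barcode molecules per integrated barcode, a
    configured fraction of molecules are empty vectors (anchor followed by
    fixed vector sequence), and each molecule is sequenced in >= 1 reads
    (1 + Poisson duplicates).  Tagged mode attaches CB/UB strings; bulk mode
    omits them and emits ~half the reads reverse-complemented.
    """
    from .extract import TaggedRead  # local import to avoid a cycle
    import pandas as pd

    if pattern is None:
        pattern = BarcodePattern()
    if isinstance(populations, list):
        populations = {p.site: p for p in populations}
    rng = np.random.default_rng(config.seed + 2)

    reads: list[TaggedRead] = []
    cell_rows = []
    mol_rows = []
    upstream = (
        DEFAULT_UPSTREAM_CONTEXT[-config.prefix_length:]
        if config.prefix_length > 0
        else ""
    )
    seen_cbs: set[str] = set()

    for site, pop in populations.items():
        clones = sorted(pop.abundances)
        counts = np.array([pop.abundances[i] for i in clones], dtype=np.int64)
        n_cap = min(config.sampled_cells_per_site, int(counts.sum()))
        captured = rng.multivariate_hypergeometric(counts, n_cap, method="marginals")
        cell_no = 0
        for clone_idx, n_cells_clone in zip(clones, captured):
            barcodes = pop.clone_barcodes[clone_idx]
            for _ in range(int(n_cells_clone)):
                cell_id = f"{site}_c{cell_no:05d}"
                cell_no += 1
                if config.tagged:
                    cb = _random_seq(rng, config.cb_length)
                    while cb in seen_cbs:
                        cb = _random_seq(rng, config.cb_length)
                    seen_cbs.add(cb)
                else:
                    cb = None
                cell_rows.append(
                    dict(
                        site=site,
                        cell_id=cell_id,
                        cell_barcode=cb if cb is not None else cell_id,
                        clone_index=clone_idx,
                        n_integrations=len(barcodes),
                        full_barcode=barcodes[0],
                    )
                )
                for bc in barcodes:
                    n_mol = 1 + rng.poisson(config.molecules_per_cell - 1)
                    for _ in range(n_mol):
                        umi = _random_seq(rng, config.umi_length)
                        empty = rng.random() < config.empty_vector_fraction
                        if not empty:
                            mol_rows.append(
                                dict(
                                    site=site,
                                    cell_barcode=cb if cb is not None else cell_id,
                                    umi=umi,
                                    clone_index=clone_idx,
                                )
                            )
                        insert = pattern.downstream_fixed if empty else bc
                        base = (upstream + pattern.anchor + insert)[: config.read_length]
                        if len(base) < config.read_length:
                            filler = (DEFAULT_UPSTREAM_CONTEXT * 40)[
                                : config.read_length - len(base)
                            ]
                            base = base + filler
                        n_reads = 1 + rng.poisson(config.reads_per_molecule - 1)
                        for r in range(n_reads):
                            seq = _apply_errors(
                                base, config.substitution_error_rate, rng
                            )
                            if not config.tagged and rng.random() < 0.5:
                                seq = reverse_complement(seq)
                            reads.append(
                                TaggedRead(
                                    read_id=f"{cell_id}:{umi}:{r}",
                                    sequence=seq,
                                    cell_barcode=cb,
                                    umi=umi if config.tagged else None,
                                    sample=site,
                                )
                            )
    return SimulatedReads(
        reads=reads,
        cell_truth=pd.DataFrame(cell_rows),
        molecule_truth=pd.DataFrame(mol_rows),
    )
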