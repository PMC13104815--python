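# clonetracer

Clone calling and clonal-dynamics analysis for **expressed lentiviral lineage
barcodes** — the kind of high-complexity barcode library (a 265-bp semi-random
sequence transcribed in the 3′UTR of a reporter) used to trace tumor clones
through growth and metastasis in single-cell and bulk RNA-seq.

It is aimed at labs running barcode lineage tracing in xenograft models who
need to go from raw tagged reads to per-clone answers: which cell belongs to
which clone, how clonal diversity changes between a primary tumor and its
metastases, which clones disseminate to which organs, and what the full
barcode sequence of a clone of interest is (e.g. for designing RNA-FISH
probes).

## What it does

1. **Simulate** (`clonetracer.simulate`) — a seeded generative model:
   semi-random barcode libraries from IUPAC patterns, Poisson(MOI)
   transduction, Dirichlet-multinomial or lognormal-fitness clonal expansion,
   per-organ seeding bottlenecks (cells or whole clones), and tagged (CB/UB)
   or bulk reads with UMI duplicates, empty-vector molecules and substitution
   errors — plus ground-truth tables for every cell and molecule.
2. **Extract** (`clonetracer.extract`) — scans each read for the fixed 33-bp
   vector anchor (`CAGATCTTAGCCACTTTTTAAAAGAAAAGGGGG`, ≤ 2 mismatches by
   default), takes the following bases as the clonal barcode and the first
   10 as the clone ID, and applies the QC cascade: UMI deduplication, empty
   vectors, short barcodes, pattern violations, and removal of cells carrying
   multiple genuine barcodes. Also includes the standard per-cell expression
   QC filter (≥ 2,000 genes, ≤ 50,000 UMIs, ≤ 20 % mitochondrial, ≤ 20 %
   mouse-mapped reads).
3. **Quantify** (`clonetracer.stats`) — clone frequencies and top-*k*
   dominance, Shannon diversity H = −Σ pᵢ ln pᵢ with the Hutcheson variance
   estimator

   ```
   var(H) = [Σ pᵢ (ln pᵢ)² − H²] / N + (S − 1) / (2 N²)
   ```

   and the two-tailed Hutcheson *t*-test between two samples' Shannon
   indices (Welch–Satterthwaite degrees of freedom); metastatic-fate
   classification of primary-tumor clones (tumor-only / lung-only /
   liver-only / shared) with lineage and cell fractions; clones shared
   across replicates; dominant-clone tracking.
4. **Reconstruct** (`clonetracer.consensus`) — position-wise plurality
   consensus over all reads of one clone, recovering the full-length 265-bp
   barcode for probe design.

## Worked example

Simulate a primary tumor plus lung/liver metastases seeded through a
30-cell bottleneck, extract clones from the tagged reads, and compare sites:

```bash
clonetracer simulate --config demo_config.json --out-dir demo/sim
clonetracer extract --sam demo/sim/primary.sam --sam demo/sim/lung.sam \
    --sam demo/sim/liver.sam --write-hits --out-dir demo/ext
clonetracer diversity --tables demo/ext/clones_primary.tsv \
    --tables demo/ext/clones_lung.tsv --tables demo/ext/clones_liver.tsv \
    --out demo/diversity.tsv
```

prints the pairwise Hutcheson tests

```
primary  vs  lung   t=2.9330  df=42.2  p=0.00541
primary  vs  liver  t=3.7319  df=63.7  p=0.000407
lung     vs  liver  t=0.2733  df=46.6  p=0.786
```

and `demo/diversity.tsv` holds the per-site indices:

```
sample   shannon_H  var_H    N    S
primary  3.3469     0.00989  106  42
lung     2.7886     0.02634  23   18
liver    2.7315     0.01730  28   17
```

— the metastatic sites show the marked, mutually comparable loss of clonal
diversity that a tight seeding bottleneck produces (both p < 0.01 against
the primary; lung vs liver p ≈ 0.79). Fate classification of the same run:

```bash
clonetracer fate --primary demo/ext/clones_primary.tsv \
    --met lung=demo/ext/clones_lung.tsv --met liver=demo/ext/clones_liver.tsv \
    --out-dir demo/fate
```

```
           fate  lineage_count  lineage_pct  cell_count  cell_pct
         shared              6         14.3          26      24.5
     liver_only              6         14.3          14      13.2
      lung_only             10         23.8          41      38.7
     tumor_only             20         47.6          25      23.6
metastasis_only              7          NaN           0       NaN
```

Here 14.3 % of primary-detected lineages seeded both organs but account for
24.5 % of primary cells — dominant clones are over-represented among
disseminators. `metastasis_only` clones (detected in an organ but not the
primary sample) are reported but excluded from the primary denominators.
Finally, `clonetracer clones --table demo/ext/clones_lung.tsv --top-k 10`
reports `top10_share 0.6522`: the ten most abundant lineages hold ~65 % of
the lung barcodes.

All of this is equally available as a library:

```python
import clonetracer as ct

table = ct.CloneCountTable("primary", {"TCCTGCAGTA": 50, "ACGACCACAA": 25,
                                       "GGTTACGTTA": 25})
d = ct.shannon_index(table)       # H=1.0397, var_H=0.0013, N=100, S=3
```

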