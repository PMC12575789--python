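# repeatscape

Repeat-region genomic and epigenomic profiling for long-read tumor/normal
cohorts.

Long-read sequencing mapped to a complete (T2T-class) reference finally makes
centromeric satellite arrays, full-length transposable-element (TE)
insertions, and allele-specific promoter methylation analyzable in clinical
tumor samples. `repeatscape` packages the analysis stack such a study needs
as a tested, reusable library and pipeline, aimed at cancer-genomics
practitioners working with nanopore tumor/normal data (for example,
high-grade serous ovarian carcinoma cohorts with homologous-recombination
deficiency (HRD) scoring):

* **Consensus somatic SV calling** — merge call sets from multiple SV
  callers (e.g. Severus, SAVANA, nanomonsv, DELLY) by breakpoint-tolerant
  matching; retain events supported by ≥ 2 callers with size ≥ 50 bp
  (translocations exempt).
* **Mutational-signature refitting** — SBS96 and SV32 catalogs refit against
  a COSMIC-style reference matrix *S* by non-negative least squares:
  *ê = argmin‖c − S e‖₂, e ≥ 0*, reported as counts and percent
  contributions.
* **Binned repeat tracks** — per-1-kb-bin median read depth normalized to
  each sample's genome-wide median; full-length TE selection (L1HS > 6 kb,
  AluY > 300 bp, SVA > 1 kb, ERV > 1 kb); Levene's test for group
  differences in coverage dispersion.
* **Satellite methylome comparison** — average 5mC ratio
  (Σ modified reads / Σ total reads) per 1-kb bin over alpha-satellite
  higher-order-repeat (HOR) and pericentromeric satellite classes; PCA and
  Ward hierarchical clustering of the bin × sample matrix; tumor grouping by
  HRD score (cutoff 63) with t-tests between groups.
* **Haplotype-resolved THOR calling** — per-haplotype CpG methylation of the
  TERT-promoter-adjacent THOR block (≥ 3 reads per site per haplotype,
  100-bp sliding-window smoothing), classified as biallelic hypermethylation,
  monoallelic hypermethylation, or none.

Patient-level inputs of such studies are controlled-access, so the package
ships a first-class synthetic-data module that generates every input format
with planted truth — caller call sets with controlled sensitivity and
breakpoint jitter, beta-binomial methylomes with planted group effects,
gamma-Poisson depth tracks with TE-specific dispersion inflation, multinomial
mutation catalogs, and phased promoter loci — making every downstream stage
testable end to end.

## Worked example

```python
import numpy as np
from repeatscape import (
    SimulationConfig, make_mini_reference, make_cohort,
    simulate_sv_callsets, merge_callsets,
    make_signature_matrix, simulate_mutation_catalog, nnls_fit,
)

cfg = SimulationConfig(seed=7)
ref = make_mini_reference(cfg)
tumor = next(m for m in make_cohort(cfg) if m.group == "tumor")

# consensus SV calling from four synthetic callers
callsets, truth = simulate_sv_callsets(cfg, ref, tumor)
consensus = merge_callsets(callsets, tol=500, min_size=50, min_support=2)
oracle = ((truth.n_detected >= 2) & ((truth.svtype == "TRA") | (truth.svlen >= 50))).sum()
print(f"consensus SVs retained: {len(consensus)} (truth-table expectation: {oracle})")
print(f"support distribution: {np.bincount([c.support for c in consensus])[2:].tolist()}")

# NNLS signature refitting of a 5000-mutation catalog
sigmat = make_signature_matrix(cfg, n_signatures=5)
catalog, w_true = simulate_mutation_catalog(cfg, tumor, sigmat, weights=[0.4, 0.3, 0.2, 0.1, 0.0])
fit = nnls_fit(catalog, sigmat)
print("planted mixture (%):", (100 * w_true).round(1).tolist())
print("fitted exposure (%):", fit.percent.round(1).tolist())
```

Output:

```
consensus SVs retained: 184 (truth-table expectation: 184)
support distribution: [9, 63, 112]
planted mixture (%): [40.0, 30.0, 20.0, 10.0, 0.0]
fitted exposure (%): [41.3, 29.3, 18.5, 10.9, 0.0]
```

The consensus count equals the count predicted independently from the
truth table (events detected by at least two callers at ≥ 50 bp, plus
translocations); of the 184 retained events, 9 are supported by two
callers, 63 by three, and 112 by all four.  The NNLS refit recovers the
planted 40/30/20/10/0 signature mixture to within ~1.5 percentage points
at a catalog size of 5,000 mutations.

## Command-line pipeline

```bash
repeatscape all --seed 7 --outdir out/
```

runs simulate → sv → signatures → coverage → methylation → thor on a
synthetic six-pair cohort.  Each stage directory contains its output tables
(TSV / VCF) and a `manifest.json` with the config hash, seed, version and
per-file checksums; a rerun with the same config is byte-identical.
Individual stages are available as subcommands (`repeatscape simulate`,
`repeatscape sv-merge`, ...), and every tunable can be set in a YAML config
passed via `--config` (CLI flags take precedence).

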