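# sigtool

A toolkit for mutational-signature analysis of somatic mutation
catalogues: classification of single-base substitutions (SBS), doublet-
base substitutions (DBS) and small insertions/deletions (ID) into the
community-standard class schemes; de novo signature extraction by two
nonnegative matrix factorisation families; per-sample signature
attribution; clustered-mutation (kataegis-like) analysis; signature
comparison; age-association statistics; and a fully ground-truthed
synthetic-data harness for validating all of the above.

It is aimed at cancer-genomics analysts who have curated somatic variant
calls (VCF or MAF-like tables) plus a reference sequence and want to go
from raw calls to signature profiles, per-sample activities and
downstream statistics in a reproducible, scriptable way.

## The model

A cohort is summarised as a catalogue matrix **V** (mutation classes x
samples) of nonnegative counts under one of the class schemes SBS96,
SBS192, SBS1536, DBS78 or ID83 (substitutions are represented by the
pyrimidine of the mutated base pair; doublets are collapsed over reverse
complements; indels are binned by size, repeat context and
microhomology). Signature analysis factorises

> V ≈ W · H

with **W** (classes x signatures) a set of probability profiles — the
mutational signatures — and **H** (signatures x samples) the nonnegative
activities: the number of mutations attributed to each signature in each
sample. Two extraction families are implemented:

* **Bootstrap consensus KL-NMF** — many multiplicative-update NMF runs
  minimising the generalized Kullback–Leibler divergence D(V‖WH), each on
  a multinomial bootstrap of every sample's spectrum; the pooled
  signatures are consensus-clustered (cosine distance, one signature per
  run per cluster via Hungarian matching) and the rank is chosen from the
  stability (mean silhouette) / reconstruction-error trade-off, with the
  full table reported for human review. A hierarchical mode re-extracts
  from poorly reconstructed samples to rescue rare signatures.
* **ARD Bayesian NMF** — per-component relevance priors shrink unneeded
  components to zero, inferring the number of signatures; a two-step mode
  extracts from low-burden samples first and lets hypermutated samples
  add novel signatures without distorting the cohort-wide profiles.

Fixed-profile attribution solves min ‖v − W·a‖ over a ≥ 0 per sample
(active-set NNLS), with optional backward-elimination sparsification,
biological allow-lists / indicator masks, and per-class signature
probabilities. See `docs/methods.md` for the complete model description,
parameter defaults and limitations.

## Worked example

Simulate a 200-sample cohort from three known signatures, re-extract them
de novo, and attribute exposures:

```python
from sigtool.synthetic import synthetic_signatures, SimulationScenario, simulate_catalogue
from sigtool.extraction import extract_signatures
from sigtool.attribution import attribute_catalogue
from sigtool.compare import match_signatures

truth = synthetic_signatures("SBS96", 3, seed=1, max_pairwise_cosine=0.5)
cohort = simulate_catalogue(
    SimulationScenario("demo", truth, n_samples=200, seed=7, noise="poisson")
)
sol = extract_signatures(cohort.catalogue, k_range=[2, 3, 4], n_iterations=64, seed=5)
print(sol.table().round(3)); print("selected rank:", sol.selected_rank)
for a, b, c in match_signatures(sol.selected.signatures, truth).pairs:
    print(f"  {a} ~ {b}: cosine {c:.4f}")
res = attribute_catalogue(cohort.catalogue, sol.selected.signatures)
print("median reconstruction cosine:", round(res.reconstruction_cosine.median(), 4))
```

This prints:

```
   stability   kl_error  frobenius_error
k
2      0.650  63252.121         6144.587
3      1.000   7083.569          507.111
4      0.554   7174.041          499.418
selected rank: 3
  S3-1 ~ SYN1: cosine 0.9999
  S3-2 ~ SYN3: cosine 1.0000
  S3-3 ~ SYN2: cosine 1.0000
median reconstruction cosine: 0.9971
```

Read: rank 2 is unstable (0.650) because three processes cannot fit two
clusters; rank 3 is perfectly stable with a ninefold drop in KL error;
rank 4 buys almost no error reduction and loses stability, so rank 3 is
selected. Each consensus signature matches one planted profile at cosine
≥ 0.9999, and re-attributing the catalogue with the extracted profiles
reconstructs the median sample at cosine 0.997.

The same workflow is available from the shell:

```bash
sigtool simulate --genome-length 20000 --n-sbs 60 --n-dbs 20 --n-indels 40 --seed 3 --out sim/
sigtool catalogue --schema SBS96 --vcf-dir sim/ --ref sim/genome.fa --out matrix.csv
sigtool extract --matrix matrix.csv --method kl-consensus --kmin 1 --kmax 4 --iterations 64 --seed 7 --out run/
sigtool attribute --matrix matrix.csv --signatures run/signatures.csv --out attr/
sigtool pipeline --config examples/pipeline.yaml --out artifacts/
```

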