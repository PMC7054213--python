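# Methods

This note documents the models and procedures implemented in `sigtool`,
the choices made where the design was genuinely open, and what the
synthetic validation harness does and does not demonstrate.

## Mutation classification

Somatic mutations are summarised as counts over fixed class alphabets:

* **SBS96.** Each single-base substitution is represented by the
  pyrimidine of the mutated base pair — a G>A call is recorded as its
  reverse complement C>T — together with one flanking base on each side.
  Six substitution types x 16 trinucleotide contexts = 96 classes.
  Canonical order: substitution types C>A, C>G, C>T, T>A, T>C, T>G; within
  a type, 5' base then 3' base, each ordered A < C < G < T.
* **SBS1536.** The same convention with two flanking bases per side.
  Dropping the outer bases projects the 1,536 labels 16-to-1 onto SBS96.
* **SBS192.** SBS96 restricted to annotated transcribed regions and
  prefixed `Transcribed:`/`Untranscribed:`. A mutation is *Transcribed*
  when the pyrimidine of the mutated pair lies on the template strand of
  the covering gene (i.e. the pyrimidine strand is the opposite of the
  gene's coding strand). Positions covered by genes on both strands, or
  by none, are excluded and logged.
* **DBS78.** A doublet substitution and its reverse complement are the
  same event; of the pair we keep the representative whose reference
  2-mer sorts first lexicographically (for palindromic references, the
  smaller alternate). Exhaustive enumeration of the 144 raw doublets
  yields exactly 78 canonical classes; the label list is frozen in code.
* **ID83.** Indels are classified by event size, repeat context and
  microhomology, using COSMIC-style labels `size:Del|Ins:C|T|R|M:bin`
  where the numeric field counts repeat units *besides* the event
  (so `1:Del:C:0` is a C deleted from a homopolymer of length 1, and
  `1:Del:T:4` one deleted from a run of five).  1-bp events collapse
  A→T and G→C; bins cap at 5 (6+ for deletion homopolymer length).
  Deletions of ≥2 bp at a single copy are scanned for microhomology: the
  longest prefix of the deleted motif matching the following sequence and
  the longest suffix matching the preceding sequence, taking the maximum;
  ties between the two directions are resolved by that same maximum.
  The grid (12+12+24+24+11) is the only one consistent with 83 classes.

Indels are left-normalised before classification; repeat-unit counts and
microhomology lengths are invariant under that shift, so classification
does not depend on the aligner's placement. Records with `N` in an allele
or context are skipped with a logged reason rather than raised. Catalogue
construction verifies the reference base at every site and enforces the
conservation law `classified + skipped = input`, per sample. Variant
coordinates are 1-based (VCF convention); annotation intervals 0-based
half-open (BED convention).

Insertion homopolymer context is measured as the longer of the runs
adjacent on either side of the left-normalised position. Any 2-base
substitution record is classified as DBS regardless of neighbouring
calls, and DBS records are excluded from the clustered-SBS analysis.

## Bootstrap consensus KL-NMF

The catalogue V (classes x samples) is factorised as V ≈ WH by
multiplicative updates minimising the generalized Kullback–Leibler
divergence D(V‖WH) = Σ V log(V/WH) − V + WH. The update rules are the
standard ones (objective monotonically non-increasing); a floor of 1e−16
inside divisions avoids singularities; convergence is declared when the
relative objective change drops below `tol` (default 1e−8, `max_iter`
10,000). W columns are normalised to sum 1 with the scale folded into H,
so signatures are probability profiles and activities are mutation counts.

For de novo extraction at rank k, the factorisation is repeated on
`n_iterations` (default 1,024; reduced in the bundled validation
scenarios) bootstrap replicates of V, each sample column resampled
multinomially with its own total and empirical class proportions
(totals preserved exactly). The pooled k·n_iterations signature vectors
are partition-clustered under cosine distance with the constraint that
each replicate contributes exactly one signature per cluster (Hungarian
matching per replicate, centroid update, initialised from a randomly
chosen replicate); the constraint prevents cluster collapse. The
consensus W is the normalised centroid set; the consensus H re-attributes
the *original* catalogue by nonnegative least squares; cluster stability
is the mean cosine silhouette of the pooled vectors.

Rank selection is advisory: the selected rank is the largest k whose
stability is ≥ `stability_min` (default 0.8) and whose relative KL
improvement over the previous rank is ≥ `gain_min` (default 2%); the full
stability/error table is always returned because the number of latent
processes is not reliably automatable and deserves human review. Within
the consensus stage the per-replicate factorisations use `tol` 1e−6 and
`max_iter` 1,000 — bootstrap noise dominates well before machine-precision
convergence matters.

Hierarchical extraction re-runs the procedure on the samples whose
reconstruction cosine falls below `recon_threshold` (default 0.95),
appending signatures that are novel (cosine < `novelty_max`, default 0.9,
to everything already found), up to `max_levels`. This rescues processes
confined to few samples, which a cohort-wide factorisation absorbs into
the dominant signatures.

All randomness flows from one master seed; per-replicate seeds are derived
with `numpy` seed sequences keyed by (rank, replicate), so results are
bitwise reproducible for a fixed seed and iteration order.

## ARD Bayesian NMF

`ard_nmf` places a per-component relevance scale λ_k on each (W column,
H row) pair — exponential priors by default, half-normal as an option,
with an inverse-gamma hyperprior (shape `a`, default 10; scale `b` set
from the data mean) — and maximises the posterior by multiplicative
updates with the closed-form λ update
λ_k = (ΣW_k + ΣH_k + b) / (F + N + a + 1).
Irrelevant components shrink toward zero; after convergence, components
whose mass (ΣW_k · ΣH_k) falls below 1e−2 of the maximum are pruned, and
the effective rank is the surviving count. The best of `n_restarts`
(default 10) random restarts by log posterior is returned. Pruning a
below-threshold component changes reconstruction error only within the
pruning tolerance, which the test suite checks directly.

**Two-step extraction for hypermutators.** Signatures are first extracted
from the low-burden samples alone; the hypermutated samples are then
explained by those profiles held exactly fixed plus `k_max` additional
free components. Free components are initialised at 1e−3 of the data
scale so the established profiles absorb the bulk of the spectra and the
free ones grow only where the data demand it; without this the free
components race the fixed ones and duplicate them. Surviving free
components are kept as *hyper-only* signatures only when novel (cosine
< 0.9 to every fixed profile and every stronger free component) —
near-duplicates arise when a free component merely corrects a fixed
profile's finite-sample estimation error, or when one novel process
splits across two components — and the hypermutator exposures are refit
on the deduplicated set. Hyper-only signatures must never be offered when
attributing low-burden samples. The hypermutator split itself is
caller-supplied sample lists, because the meaningful split is biological
(mismatch-repair deficiency, POLE, UV, treatment exposure); a
burden-quantile splitter is provided as an explicitly labelled heuristic.

## Attribution

With profiles fixed, each sample's activities minimise the Frobenius norm
‖v − Wa‖ over a ≥ 0. This problem is convex and its optimum
solver-independent, so the deterministic active-set NNLS solver is used
(tolerance 1e−10); the test suite confirms objective agreement with an
independent bounded least-squares solver to 1e−6 on random instances.
Optional behaviours:

* **Allow-lists / indicator mask.** Biological plausibility rules (e.g.
  restricting a tobacco-associated signature to the relevant tumour
  types) enter as per-sample allowed subsets, or as the binary
  signature-by-sample matrix Z multiplied into H after every update of
  the ARD H-only refit (`attribute_ard`), making disallowed exposures
  exactly zero. Rule tables ship only as an example config, never
  hard-coded.
* **Sparsification.** Backward elimination: repeatedly drop the active
  signature whose removal costs the least reconstruction cosine, while
  the cost is ≤ `drop_tol` (default 0.01), refitting after each removal.
  The support shrinks monotonically along the trace.
* **Scaling.** Exposures are reported unscaled by default (their sum may
  differ from the sample total by the residual); a flag renormalises to
  the observed total.
* **Per-class probabilities.** P[i,k] = W[i,k]·h[k] / Σ_k' W[i,k']·h[k'],
  rows summing to 1; classes with zero reconstructed mass are NaN.

## Clustered substitutions

An SBS is clustered when its nearest same-sample, same-chromosome
neighbour lies strictly closer than `max_dist` (default 1,000 bp).
The partition is exhaustive and disjoint, and catalogues built from the
clustered fraction feed the same extraction machinery. The expectation
of immediately adjacent pairs under uniform random placement of n
substitutions on a linear genome of length L, C(n,2)·2(L−1)/L² ≈ n(n−1)/L,
is provided as a heuristic yardstick for doublet enrichment; real genomes
are neither uniform nor unstructured, so it is a reference point, not a
test.

## Signature comparison

Cosine similarity on nonnegative profiles (scale invariant, in [0,1]);
globally optimal one-to-one matching between two sets via the Hungarian
algorithm on the cosine matrix (rectangular allowed, surplus unmatched);
set separation as the distribution and median of all C(n,2) pairwise
cosines. Two separation distributions are compared with a two-sided
Mann–Whitney U test (normal approximation, tie-corrected) by default — no
particular test is canonical for this task — with a seeded permutation
test on the mean difference as the config alternative.

## Age associations

Per (signature, cancer type) stratum: values beyond three standard
deviations from the stratum mean, in age or in exposure, are removed in a
single pass (mean and sd from the full input, no re-iteration; boundary
values exactly at 3 sd are kept — the non-strict choice is documented
here because either convention is defensible). The slope of exposure on
age is estimated by iteratively reweighted least squares with Tukey
bisquare weights, tuning constant 4.685 and scale 1.4826·MAD — the
classic `robustfit` defaults. The slope-zero F test (F = (slope/se)², 1
and n−2 df) uses the robust standard error from the IRLS covariance
rather than a plain weighted-OLS refit at the converged weights: the
weights are estimated from the data, and ignoring that makes the naive
F test anticonservative (empirically ~0.085 at nominal 0.05 under the
null, versus ~0.05 with the robust covariance). Strata with fewer than 4
samples after screening are skipped and logged. All stratum p-values form
one family for Benjamini–Hochberg correction, reported in input order.

## Synthetic validation harness

`simulate_catalogue` draws cohorts from known profiles: per sample a
log-uniform burden (default 10²–10⁴ mutations, matching the
orders-of-magnitude spread of real cohorts), a Dirichlet signature
mixture, an optional hypermutated subpopulation (default multiplier
100x), and Poisson, multinomial or no counting noise. Multinomial noise
conserves each burden exactly (the truth exposures are the per-signature
multinomial counts); Poisson conserves it in expectation. The exact noise
model behind published synthetic evaluations is not fixed, so both are
offered; Poisson is the default. `scenario_suite` pairs two fixture
profile sets with two exposure styles in all four combinations
(A-profiles/A-exposures, B/B, A/B, B/A) at 150 samples each (desk scale;
full scale multiplies by 20).

Fixture profiles are synthetic but structured: sparse, peaked (mass on ~8
classes over a 2% background) with rejection-controlled pairwise cosines,
so tests need no downloaded reference profiles; a loader for real profile
CSVs is provided for users who want faithful realism.

`simulate_genome_and_vcf` writes a random toy genome and a VCF of
implanted SBS/DBS/indel events whose true classes are computed at
generation time with the module's own independent labelling arithmetic:
each indel site's local sequence is overwritten with a controlled motif
(homopolymer run, tandem repeat, or microhomology junction flanked by
guard bases chosen so the intended repeat count and microhomology length
are fixed by construction). Catalogue construction on the emitted VCF
must reproduce the truth table exactly — an end-to-end check of VCF
parsing, allele normalisation, left-alignment and classification.

**What passing these tests shows — and does not.** The harness emulates
burden heterogeneity, mixture sparsity, hypermutators and counting noise.
It does not emulate sequencing artefacts, calling errors, germline
contamination, signature profiles with heavy overlap (beyond the
configured cosine bounds), inter-sample profile drift, or correlated
noise; recovery on these cohorts is therefore a necessary, not
sufficient, indication of behaviour on real tumours. Validation scales
(200-sample cohorts, 64 bootstrap iterations, 20 seeds) are the package's
desk-scale defaults chosen to keep the whole suite comfortably
re-runnable; the algorithms accept the full-scale settings (1,024
iterations, 10 restarts) unchanged.

## Pipeline and formats

All matrices are plain UTF-8 CSV, '.' decimal, class labels in canonical
order in the first column; exposure matrices are signatures x samples.
The YAML pipeline executes stages in dependency order, fails fast on
missing inputs, removes partial outputs on error, and is bitwise
reproducible for a fixed config and seed. Provenance (tool version, seed,
config SHA-256) goes to a `provenance.yaml` sidecar so the CSVs stay
diff-stable.

## Known limitations

* Rank selection and ARD pruning are heuristics; both are surfaced with
  their full diagnostic tables and should be reviewed, not trusted blind.
* The ARD prior hyperparameters (a = 10, data-scaled b) are a pragmatic
  default; very small cohorts with extreme burdens can still retain
  noise components (mitigated, for the two-step path, by the novelty
  dedup described above).
* Transcription-strand classification requires a non-overlapping strand
  annotation; positions under bidirectional transcription are dropped
  rather than modelled.
* The adjacency expectation treats the genome as a uniform linear
  sequence; it is not a significance test.
* Multi-nucleotide substitutions of three or more bases have no class
  scheme and are skipped with a logged reason.
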