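# Methods

## Overview

`eqdtu` tests genes for differential transcript usage (DTU) by applying a
count-based usage test directly to equivalence-class counts (ECCs). An
equivalence class is the set of transcripts a read is compatible with
under pseudo-alignment; reads sharing that set form one class. The package
also implements the two comparator quantifications that bracket ECCs —
EM-estimated transcript counts and flattened exon-bin counts — so the
three counting units can be run through the identical statistical test and
compared on simulated data with known truth.

## Equivalence-class compilation

Per-sample EC observations (parsed from Salmon `--dumpEq` output, Kallisto
`pseudo --batch` directories, or the built-in pseudo-aligner) are matched
across samples by a canonical key: the lexicographically sorted transcript
ids joined with `|`. The compiled matrix takes the union of observed
classes over samples, filling zeros where a sample lacks a class; column
totals equal each sample's assigned reads. Each class is labelled with the
single gene its transcripts belong to; classes spanning more than one gene
are removed, and classes containing transcripts missing from the
transcript-to-gene map are dropped with a warning (a strict mode turns
this into an error). This removal is the only filtering applied by
default. Unobserved-but-theoretically-possible classes are never
enumerated — the matrix holds what the data produced.

## The pseudo-aligner

A minimal k-mer engine: the index maps every k-mer of every transcript to
the set of transcripts containing it, and a read's class is the
intersection of those sets over all of its k-mers that occur in the index.
k-mers absent from the index are skipped rather than failing the read;
this mirrors lightweight-aligner behaviour and keeps assignment stable at
exon junctions of small references. A read with no indexed k-mer or an
empty intersection is unassigned (tallied and excluded). Paired mode
intersects the two mates' sets. Default k = 31; tiny unit-test references
use smaller k (down to 7). Only forward-strand, error-free reads are
handled by default (the simulator emits exactly these); a `both` mode
unions forward and reverse-complement assignments. On error-free reads
from repeat-free references this procedure equals full-read substring
containment, which the test suite asserts read-by-read.

## EM transcript quantification

The transcript branch estimates abundances from the same EC table by
expectation-maximisation on the collapsed EC likelihood
`L(pi) = prod_e (sum_{t in e} pi_t / l_t)^{n_e}` with `pi` the read-mass
proportions on the simplex and `l_t = max(L_t − fragment_mean + 1, 1)` the
effective length. Proportions start uniform (the likelihood is concave in
`pi`, so initialisation affects only iteration count); iteration stops
when the max absolute proportion change falls below `tol` (default 1e-8,
max 1000 sweeps). Estimated counts are the responsibility-weighted read
mass (conserving the assigned total), TPM renormalises count/length to
1e6, and scaled-TPM counts rescale TPM to the library size before
rounding to integers for testing. The tracked objective is the
observed-data log-likelihood above; tests assert it never decreases.

## Exon bins

Per gene, exons are cut at every exon boundary of the gene plus any
boundary of an overlapping same-strand gene, yielding disjoint parts with
fixed transcript membership; parts overlapping a different gene on the
same strand are excluded, and adjacent parts with identical membership are
merged, which makes the partition exactly the run-length merge of a
per-base labelling (the oracle used in tests). Counting uses the
simulator's true genomic read coordinates — a read increments every bin of
its gene it overlaps by at least one base — so the counting-unit
comparison is isolated from aligner noise. A vectorised offset-based
counting route is used at benchmark scale and is cross-checked against the
per-read route.

## The usage test

Each feature of a multi-feature gene is tested in a two-row
representation: the feature's counts and the per-sample sum of the gene's
remaining features. The negative-binomial log-link GLM
(`Var = mu + alpha mu^2`) compares

```
full:  log mu = log(size factor) + sample + bin + condition:bin
null:  log mu = log(size factor) + sample + bin
```

by likelihood ratio against chi-square with (conditions − 1) df. Fitting
is iteratively reweighted least squares with a small ridge (1e-8) on the
normal equations, linear predictors clamped to ±30, convergence at a
relative log-likelihood change below 1e-8 within 100 iterations;
non-converged features are flagged and reported with p = 1 (conservative).
Size factors are DESeq-style median-of-ratios over features positive in
all samples, falling back to library-size ratios when none exists.

Dispersion is estimated per feature by maximising the Cox-Reid adjusted
profile likelihood (`loglik − ½ log det XᵀWX`) over log-dispersion in
[1e-8, 10]. A parametric trend `alpha(mu) = a1/mu + a0` is fitted across
features by iterated Gamma-family regression with outlier exclusion
(ratio outside [1e-4, 15]); the final value is the posterior mode under a
log-normal prior centred on the trend whose width is the MAD of log
residuals (floor 0.25), except that MLEs more than two residual SDs above
the trend keep their MLE. Exact agreement with any specific release of an
existing exon-usage tool is deliberately not a goal; the contract is the
documented model plus the calibration and power properties the test suite
measures.

Gene-level calls aggregate feature p-values with the Šidák bound
`1 − (1 − min p)^F` and BH across genes. When every gene has one feature
this reduces exactly to BH of the feature p-values. Feature-level BH is
also reported. Single-feature genes are untestable (no "other" row) and
are reported as such. The DRIMSeq-style expression filter (feature count
≥ 10 in ≥ 3 samples within genes totalling ≥ 10 in ≥ 6 samples) is
opt-in and off by default.

## The simulator

The generator emulates the classic two-group isoform-switch benchmark:
two conditions × n replicates, a chosen fraction of genes given DTU by
exchanging the expression levels of their two most abundant transcripts
(ties broken by transcript id; the switch leaves per-gene totals
untouched, so there is no differential gene expression), NB count noise
across replicates, and error-free fixed-length reads with known offsets
and spliced genomic coordinates.

Structure per gene: one exon shared by all isoforms, one exon private to
each isoform (guaranteeing both joint and singleton classes), remaining
exons included per isoform with probability ½; exon sequences are uniform
random ACGT. Gene expression weights are log-normal (sigma 1), isoform
proportions flat Dirichlet, DTU genes drawn uniformly among multi-isoform
genes. Replicate counts per transcript are gamma-Poisson draws of
NB(depth × relative abundance, dispersion).

The default "soneson-mini" configuration — 200 genes, 2–5 isoforms from
3–12 exons of 100–600 bp, 100 bp single-end reads, 3 vs 3 replicates at
4×10⁵ expected reads per sample, NB dispersion 0.05, 10% DTU — is a
deliberately miniaturised version of the published benchmark design
(which uses genome-scale annotation and 1000 DTU genes) sized so the
whole three-branch comparison runs in minutes on one core.

Two read paths share the same replicate counts: the read-level path
materialises every read, while the analytic path computes each
transcript's EC profile (the compatibility set of the window starting at
every offset, via a run-compressed sweep) and splits the NB count
multinomially over it. The two agree in distribution, which a
three-standard-error consistency test checks.

What the generator does **not** emulate: sequencing errors, GC/positional
bias, fragment-length variation (single-end reads of fixed length, with
paired-end emission available but not default), intron retention or novel
junctions, correlated isoform structure between genes, and realistic
(non-uniform-random) sequence repetitiveness. Passing tests therefore
demonstrate correctness of the machinery and the qualitative counting-unit
behaviour under the stated design, not performance on real libraries —
where reference incompleteness, mapping bias and biological variance
structure matter.

## Evaluation

Gene calls at nominal q-value cutoffs (0.01, 0.05, 0.1 by default) are
scored against a truth set: TPR = recovered fraction of truth, observed
FDR = non-truth fraction of calls (0/0 → 0). Methods are compared on a
common universe of tested genes (untestable single-feature genes are
excluded and the truth intersected accordingly). For real data without
simulation truth, consensus truth sets (union for FDR, intersection for
TPR) over several methods support subset experiments: repeated scoring of
pipelines re-run on random per-condition subsamples, redrawn until every
sample is used at least once, fully seeded. Diagnostics: per-gene counts
of features with at least one read per counting unit, and per-feature
log2(variance/mean) of CPM-transformed counts per condition after a light
CPM ≥ 1 filter (zero-variance cells excluded and tallied). Rank-order
false-positive curves count non-truth genes among the top-q-ranked.

## Numerical and design choices

- Dispersion bounds [1e-8, 10]; degenerate fits fall back to the trend.
- The dispersion optimiser uses a bounded scalar search with default
  tolerance 0.02 on log-dispersion (tightened where tests compare against
  a generic optimiser); the LRT refits at fixed dispersion with tolerance
  1e-8.
- LRT values in [−1e-6, 0] from finite fitting tolerance are clamped to 0.
- Ties in abundance (the switch) and in q-value ranking break by id, so
  every pipeline output is bit-identical across reruns.
- Effective length uses the single-end formula with fragment length =
  read length for simulated data; paired-end data would supply the
  fragment mean (the classic single-end estimate for short-read data is
  ~68 bp with SD 15).
- All RNG flows through `numpy.random.default_rng` seeds carried in the
  configuration; iteration orders are sorted, never set/dict-order
  dependent.

## Known limitations

- The Šidák aggregation assumes independent feature p-values; features of
  a gene are negatively correlated through the "other" row, so gene-level
  FDR control is approximate (observed FDR on the mini benchmark runs
  above nominal at loose cutoffs, as it does for the published
  exon-usage machinery this mirrors).
- Only two-group designs with a single condition factor are supported.
- The pseudo-aligner has no reverse-complement handling by default, no
  mismatch tolerance and no coloured-graph skipping heuristics; it is a
  reference implementation for synthetic data, not a production aligner.
- Probability-weighted (fragment-length-aware) equivalence classes are out
  of scope; Salmon's weighted EC dialect is parsed but the weights are
  ignored, as the method consumes plain counts.
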