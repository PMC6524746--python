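"""Synthetic DTU experiments: toy transcriptome, isoform switches, NB reads.

The generator emulates the classic two-group isoform-switch benchmark
design: two conditions with n replicates each, a chosen fraction of genes
given differential transcript usage by exchanging the expression levels of
their two most abundant transcripts, negative-binomial count noise across
replicates, and error-free fixed-length reads with known genomic
coordinates. The switch leaves per-gene totals untouched, so the signal is
pure usage change without differential gene expression.

Two read paths exist: :func:`simulate_reads` materialises every read (with
its transcript source and spliced genomic interval, for exon-bin counting
and pseudo-alignment), while :func:`simulate_ec_counts` skips read
generation and samples EC counts directly from each transcript's analytic
EC profile (the compatibility set of the read starting at every offset) —
the two paths agree in distribution and the fast one makes
statistics-heavy experiments cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .formats_io import SampleTable, TranscriptAnnotation, TranscriptRecord
from .ec_core import ECCountMatrix, build_ec_matrix
from .formats_io import RawECTable
from .pseudoalign import KmerIndex, ReadRecord, build_index, window_compatibility

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "soneson_mini",
    "simulate_transcriptome",
    "assign_abundances",
    "apply_dtu_switch",
    "simulate_reads",
    "simulate_ec_counts",
    "simulate_null_feature_matrix",
    "build_sample_table",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All knobs of the synthetic design.

    Defaults are the "soneson-mini" configuration: 200 genes with 2-5
    isoforms built from 3-12 exons of 100-600 bp, single-end 100 bp reads,
    two conditions x 3 replicates at 4e5 expected reads per sample, NB
    dispersion 0.05, and 10% of (multi-isoform) genes given DTU.
    """

    n_genes: int = 200
    isoforms_per_gene: tuple[int, int] = (2, 5)
    exons_per_gene: tuple[int, int] = (3, 12)
    exon_length: tuple[int, int] = (100, 600)
    read_length: int = 100
    depth: int = 400_000
    nb_dispersion: float = 0.05
    prop_dtu: float = 0.1
    n_replicates: int = 3
    seed: int = 0
    k: int = 31
    intron_length: int = 100
    gene_gap: int = 1000
    overlap_fraction: float = 0.0
    gene_expr_sigma: float = 1.0
    conditions: tuple[str, str] = ("S1", "S2")

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.depth <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.prop_dtu <= 1.0):
            raise ValueError("prop_dtu must be in [0, 1]")
        if self.isoforms_per_gene[0] < 1 or self.isoforms_per_gene[0] > self.isoforms_per_gene[1]:
            raise ValueError("bad isoform range")
        if self.exon_length[0] < self.read_length:
            raise ValueError("exons must be at least one read long")
        if self.exons_per_gene[1] < self.isoforms_per_gene[1] + 1:
            raise ValueError(
                "infeasible config: need exons_per_gene max >= isoforms max + 1 "
                "(one shared exon plus one private exon per isoform)"
            )


def soneson_mini(seed: int = 0, **overrides) -> SimConfig:
    """The default mini benchmark configuration with a chosen seed."""
    return SimConfig(seed=seed, **overrides)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    dtu_genes: set[str]
    proportions: dict[str, dict[str, float]]  # condition -> transcript -> within-gene prop
    expected_counts: dict[str, dict[str, float]]  # condition -> transcript -> reads/sample
    transcript_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    # sample -> transcript -> realised NB count


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------


def simulate_transcriptome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[TranscriptAnnotation, dict[str, str]]:
    """Lay out a toy multi-isoform transcriptome on one synthetic chromosome.

    Every gene gets one exon shared by all isoforms and one exon private to
    each isoform (so singleton and joint equivalence classes are both
    guaranteed); remaining exons are included per isoform at random.
    ``overlap_fraction`` > 0 places that fraction of genes overlapping their
    predecessor on the same strand, to exercise the exon-part exclusion
    rule.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    iso_lo, iso_hi = config.isoforms_per_gene
    ex_lo, ex_hi = config.exons_per_gene
    records: list[TranscriptRecord] = []
    sequences: dict[str, str] = {}
    cursor = 0
    prev_span: tuple[int, int] | None = None
    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:04d}"
        n_iso = int(rng.integers(iso_lo, iso_hi + 1))
        n_ex = int(rng.integers(max(ex_lo, n_iso + 1), ex_hi + 1))
        lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
        overlap = (
            prev_span is not None
            and config.overlap_fraction > 0
            and rng.random() < config.overlap_fraction
        )
        if overlap:
            start = max(prev_span[1] - config.exon_length[0], prev_span[0])
        else:
            start = cursor
        exon_ivs: list[tuple[int, int]] = []
        pos = start
        for L in lens:
            exon_ivs.append((pos, pos + int(L)))
            pos += int(L) + config.intron_length
        gene_end = exon_ivs[-1][1]
        cursor = max(cursor, gene_end + config.gene_gap)
        prev_span = (start, gene_end)

        exon_seqs = [
            "".join(rng.choice(_BASES, size=e - s)) for s, e in exon_ivs
        ]
        # exon 0 shared by all isoforms; exon 1+i private to isoform i
        for ii in range(n_iso):
            members = {0, 1 + ii}
            for rest in range(n_iso + 1, n_ex):
                if rng.random() < 0.5:
                    members.add(rest)
            exon_idx = sorted(members)
            tx_id = f"{gene_id}.t{ii + 1}"
            records.append(
                TranscriptRecord(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    chrom="chrS",
                    strand="+",
                    exons=tuple(exon_ivs[j] for j in exon_idx),
                )
            )
            sequences[tx_id] = "".join(exon_seqs[j] for j in exon_idx)
    return TranscriptAnnotation(records=records), sequences


# ---------------------------------------------------------------------------
# abundances and the DTU switch
# ---------------------------------------------------------------------------


def assign_abundances(
    config: SimConfig,
    annotation: TranscriptAnnotation,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Baseline gene expression weights and within-gene isoform proportions.

    Gene expression weights are log-normal; isoform proportions are flat
    Dirichlet per gene. Returns (gene_expr, transcript_proportion); the
    expression weights are relative (normalised downstream against total).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes = annotation.genes()
    gene_expr: dict[str, float] = {}
    proportions: dict[str, float] = {}
    for gene_id in sorted(genes):
        recs = sorted(genes[gene_id], key=lambda r: r.transcript_id)
        gene_expr[gene_id] = float(rng.lognormal(mean=0.0, sigma=config.gene_expr_sigma))
        props = rng.dirichlet(np.ones(len(recs)))
        for rec, p in zip(recs, props):
            proportions[rec.transcript_id] = float(p)
    return gene_expr, proportions


def select_dtu_genes(
    config: SimConfig,
    annotation: TranscriptAnnotation,
    rng: np.random.Generator | None = None,
) -> set[str]:
    """Uniform draw of DTU genes among genes with >=2 isoforms."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    eligible = sorted(g for g, recs in annotation.genes().items() if len(recs) >= 2)
    n_dtu = int(round(config.prop_dtu * config.n_genes))
    if n_dtu > len(eligible):
        raise ValueError(f"cannot select {n_dtu} DTU genes from {len(eligible)} eligible")
    chosen = rng.choice(len(eligible), size=n_dtu, replace=False)
    return {eligible[i] for i in chosen}


def apply_dtu_switch(
    proportions: dict[str, float],
    dtu_genes: set[str],
    annotation: TranscriptAnnotation,
) -> dict[str, float]:
    """Exchange the proportions of the two most abundant transcripts.

    Applied per DTU gene; every other transcript and every non-DTU gene is
    returned unchanged. Ties in abundance are broken by transcript id, so
    "two most abundant" is always well defined.
    """
    genes = annotation.genes()
    out = dict(proportions)
    for gene_id in sorted(dtu_genes):
        recs = genes.get(gene_id, [])
        if len(recs) < 2:
            raise ValueError(f"DTU gene {gene_id} has <2 isoforms")
        order = sorted(
            (r.transcript_id for r in recs),
            key=lambda t: (-proportions[t], t),
        )
        a, b = order[0], order[1]
        out[a], out[b] = proportions[b], proportions[a]
    return out


def _expected_counts(
    config: SimConfig,
    annotation: TranscriptAnnotation,
    gene_expr: dict[str, float],
    proportions: dict[str, float],
) -> dict[str, float]:
    total = sum(
        gene_expr[rec.gene_id] * proportions[rec.transcript_id] for rec in annotation
    )
    return {
        rec.transcript_id: config.depth
        * gene_expr[rec.gene_id]
        * proportions[rec.transcript_id]
        / total
        for rec in annotation
    }


def simulate_experiment_design(
    config: SimConfig,
) -> tuple[TranscriptAnnotation, dict[str, str], SimTruth]:
    """Transcriptome + per-condition expected abundances + truth ledger."""
    rng = np.random.default_rng(config.seed)
    annotation, sequences = simulate_transcriptome(config, rng)
    gene_expr, props1 = assign_abundances(config, annotation, rng)
    dtu_genes = select_dtu_genes(config, annotation, rng)
    props2 = apply_dtu_switch(props1, dtu_genes, annotation)
    c1, c2 = config.conditions
    truth = SimTruth(
        dtu_genes=dtu_genes,
        proportions={c1: props1, c2: props2},
        expected_counts={
            c1: _expected_counts(config, annotation, gene_expr, props1),
            c2: _expected_counts(config, annotation, gene_expr, props2),
        },
    )
    return annotation, sequences, truth


def build_sample_table(config: SimConfig) -> SampleTable:
    rows = []
    for cond in config.conditions:
        for r in range(1, config.n_replicates + 1):
            rows.append((f"{cond}_rep{r}", cond, ""))
    return SampleTable(rows=rows)


# ---------------------------------------------------------------------------
# NB replicate counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return int(rng.poisson(lam))


def _transcript_counts_for_samples(
    config: SimConfig,
    annotation: TranscriptAnnotation,
    truth: SimTruth,
    rng: np.random.Generator,
) -> dict[str, dict[str, int]]:
    """Realised NB count per transcript for every replicate of each condition."""
    out: dict[str, dict[str, int]] = {}
    tx_ids = sorted(r.transcript_id for r in annotation)
    for cond in config.conditions:
        exp = truth.expected_counts[cond]
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_rep{rep}"
            out[sample] = {
                t: _nb_draw(rng, exp[t], config.nb_dispersion) for t in tx_ids
            }
    return out


def simulate_null_feature_matrix(
    n_genes: int = 500,
    n_replicates: int = 3,
    features_per_gene: tuple[int, int] = (2, 5),
    dispersion: float = 0.1,
    log_mean: float = 3.5,
    log_sd: float = 1.0,
    seed: int = 0,
    conditions: tuple[str, str] = ("S1", "S2"),
):
    """A no-signal NB feature matrix for calibration experiments.

    Every feature's counts are NB draws around one mean shared by both
    conditions (log-normal across features), so any gene call is a false
    positive. Returns (matrix DataFrame, SampleTable).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    samples = [
        (f"{cond}_rep{r}", cond, "")
        for cond in conditions
        for r in range(1, n_replicates + 1)
    ]
    n_samples = len(samples)
    rows, gene_ids, keys = [], [], []
    for g in range(n_genes):
        nf = int(rng.integers(features_per_gene[0], features_per_gene[1] + 1))
        mus = rng.lognormal(log_mean, log_sd, size=nf)
        for f in range(nf):
            counts = [_nb_draw(rng, mus[f], dispersion) for _ in range(n_samples)]
            rows.append(counts)
            gene_ids.append(f"g{g + 1:04d}")
            keys.append(f"g{g + 1:04d}:f{f + 1}")
    df = pd.DataFrame(rows, columns=[s for s, _, _ in samples], index=keys)
    df.insert(0, "gene_id", gene_ids)
    df.index.name = "feature_key"
    return df, SampleTable(rows=samples)


# ---------------------------------------------------------------------------
# read-level path
# ---------------------------------------------------------------------------


def _genomic_blocks(
    rec: TranscriptRecord, offset: int, length: int
) -> tuple[tuple[str, int, int], ...]:
    """Project transcript interval [offset, offset+length) to spliced genomic blocks."""
    blocks = []
    remaining = length
    pos = offset
    cum = 0
    for s, e in rec.exons:
        ex_len = e - s
        if pos < cum + ex_len and remaining > 0:
            start_in = max(pos - cum, 0)
            take = min(ex_len - start_in, remaining)
            blocks.append((rec.chrom, s + start_in, s + start_in + take))
            remaining -= take
            pos += take
        cum += ex_len
        if remaining <= 0:
            break
    return tuple(blocks)


def simulate_reads(
    annotation: TranscriptAnnotation,
    sequences: dict[str, str],
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    materialize_sequences: bool = True,
) -> dict[str, list[ReadRecord]]:
    """Error-free reads for every replicate, with truth coordinates.

    Per replicate and transcript the read count is NB(depth x relative
    abundance, nb_dispersion); read starts are uniform over
    [0, L - read_length]. Each record carries its source transcript, offset
    and spliced genomic blocks. Transcripts shorter than the read length are
    excluded with a warning. Fills ``truth.transcript_counts`` as a side
    effect.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 10)
    rl = config.read_length
    recs = {r.transcript_id: r for r in annotation}
    too_short = [t for t, r in recs.items() if r.length < rl]
    if too_short:
        logger.warning("simulate_reads: %d transcript(s) shorter than read length excluded", len(too_short))
    tx_counts = _transcript_counts_for_samples(config, annotation, truth, rng)
    truth.transcript_counts = tx_counts
    reads: dict[str, list[ReadRecord]] = {}
    for sample in tx_counts:
        sample_reads: list[ReadRecord] = []
        for t, count in tx_counts[sample].items():
            if count == 0 or t in too_short:
                continue
            rec = recs[t]
            seq = sequences[t]
            offsets = rng.integers(0, len(seq) - rl + 1, size=count)
            for i, p in enumerate(offsets):
                p = int(p)
                sample_reads.append(
                    ReadRecord(
                        read_id=f"{sample}:{t}:{i}",
                        sequence=seq[p : p + rl] if materialize_sequences else "",
                        true_source=(t, p),
                        genomic_blocks=_genomic_blocks(rec, p, rl),
                    )
                )
        reads[sample] = sample_reads
    return reads


# ---------------------------------------------------------------------------
# analytic EC path
# ---------------------------------------------------------------------------


def transcript_ec_profiles(
    sequences: dict[str, str], config: SimConfig, index: KmerIndex | None = None
) -> dict[str, dict[frozenset[str], float]]:
    """Per transcript, the probability of each EC for a uniform read start."""
    if index is None:
        index = build_index(sequences, k=config.k)
    profiles: dict[str, dict[frozenset[str], float]] = {}
    for t in sorted(sequences):
        assignments = window_compatibility(sequences[t], index, config.read_length)
        counts: dict[frozenset[str], int] = {}
        n_valid = 0
        for ec in assignments:
            if ec is None:
                continue
            n_valid += 1
            counts[ec] = counts.get(ec, 0) + 1
        if n_valid == 0:
            logger.warning("transcript_ec_profiles: %s produced no assignable window", t)
            continue
        profiles[t] = {ec: c / n_valid for ec, c in counts.items()}
    return profiles


def simulate_ec_counts(
    annotation: TranscriptAnnotation,
    sequences: dict[str, str],
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    index: KmerIndex | None = None,
) -> ECCountMatrix:
    """Sample EC counts directly from analytic per-transcript EC profiles.

    Per replicate, each transcript's NB count is split multinomially over
    its EC profile; the distribution of the resulting matrix matches
    pseudo-aligning the reads of :func:`simulate_reads` in expectation.
    Reuses ``truth.transcript_counts`` when already drawn (so the two paths
    can share one set of replicate counts), otherwise draws them.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 10)
    profiles = transcript_ec_profiles(sequences, config, index=index)
    if not truth.transcript_counts:
        truth.transcript_counts = _transcript_counts_for_samples(
            config, annotation, truth, rng
        )
    tx_names = sorted(sequences)
    name_to_idx = {t: i for i, t in enumerate(tx_names)}
    tables: list[RawECTable] = []
    for sample in truth.transcript_counts:
        ec_counts: dict[frozenset[str], int] = {}
        counts = truth.transcript_counts[sample]
        for t in sorted(counts):
            c = counts[t]
            if c == 0 or t not in profiles:
                continue
            ecs = sorted(profiles[t], key=lambda s: sorted(s))
            probs = np.array([profiles[t][e] for e in ecs])
            draws = rng.multinomial(c, probs / probs.sum())
            for ec, d in zip(ecs, draws):
                if d > 0:
                    ec_counts[ec] = ec_counts.get(ec, 0) + int(d)
        entries = [
            (frozenset(name_to_idx[t] for t in ec), c) for ec, c in ec_counts.items()
        ]
        tables.append(
            RawECTable(transcript_names=list(tx_names), entries=entries, sample_id=sample)
        )
    return build_ec_matrix(tables)
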