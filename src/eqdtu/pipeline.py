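"""End-to-end synthetic benchmark: the three counting branches on one dataset.

Given one simulated experiment, build the three feature matrices that enter
the same differential-usage test — equivalence-class counts, EM-estimated
transcript counts (scaled-TPM), and flattened exon-bin counts — run the
test on each, and score the gene calls against the simulation truth. This
is the package's own miniature version of the counting-unit comparison.

Exon-bin counts are derived from the simulator's true read coordinates
(offset sampling per transcript), which isolates the counting-unit
comparison from aligner noise; the per-read path in
:mod:`eqdtu.quantify` is the reference implementation this vectorised
route is checked against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dtu_stats, evaluate
from .ec_core import ECCountMatrix, annotate_genes, filter_multigene
from .formats_io import RawECTable, SampleTable, TranscriptAnnotation
from .quantify import (
    ExonBinTable,
    effective_lengths,
    em_abundance,
    flatten_exon_bins,
    scaled_tpm_counts,
)
from .simulate import SimConfig, SimTruth, build_sample_table, simulate_ec_counts, simulate_experiment_design

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkData",
    "raw_tables_from_matrix",
    "transcript_count_matrix",
    "exon_bin_matrix_from_offsets",
    "simulate_benchmark",
    "run_branch_dtu",
]


def raw_tables_from_matrix(matrix: ECCountMatrix) -> list[RawECTable]:
    """Split an EC count matrix back into per-sample tables (for EM input)."""
    tx_names = sorted({t for ec in matrix.rows for t in ec.transcripts})
    idx_of = {t: i for i, t in enumerate(tx_names)}
    tables = []
    for j, sample in enumerate(matrix.samples):
        entries = [
            (frozenset(idx_of[t] for t in ec.transcripts), int(c))
            for ec, c in zip(matrix.rows, matrix.counts[:, j])
            if c > 0
        ]
        tables.append(
            RawECTable(transcript_names=list(tx_names), entries=entries, sample_id=sample)
        )
    return tables


def transcript_count_matrix(
    matrix: ECCountMatrix,
    annotation: TranscriptAnnotation,
    fragment_mean: float,
    em_tol: float = 1e-7,
) -> pd.DataFrame:
    """EM transcript counts per sample, scaled-TPM style, rounded to integers."""
    t2g = annotation.t2g()
    tables = raw_tables_from_matrix(matrix)
    lens = {rec.transcript_id: rec.length for rec in annotation}
    columns = {}
    tx_order: list[str] | None = None
    for table in tables:
        eff = effective_lengths({t: lens[t] for t in table.transcript_names}, fragment_mean)
        est = em_abundance(table, eff, tol=em_tol)
        counts = scaled_tpm_counts(est, table.total_reads)
        columns[table.sample_id] = counts
        if tx_order is None:
            tx_order = list(counts.index)
    df = pd.DataFrame(columns).loc[tx_order].round().astype(np.int64)
    df.insert(0, "gene_id", [t2g[t] for t in df.index])
    df.index.name = "feature_key"
    return df


def exon_bin_matrix_from_offsets(
    annotation: TranscriptAnnotation,
    bins: ExonBinTable,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Count exon bins from uniformly sampled read offsets per transcript.

    For each transcript, each bin it covers occupies a contiguous
    transcript-coordinate interval [a, b); a read starting at offset p
    overlaps the bin iff a - read_length < p < b. Offsets are drawn once
    per (sample, transcript) from the same NB replicate counts the other
    branches use.
    """
    rl = config.read_length
    recs = {r.transcript_id: r for r in annotation}
    by_gene = bins.by_gene()

    # transcript -> [(bin_id, a, b)] in transcript coordinates
    bin_spans: dict[str, list[tuple[str, int, int]]] = {}
    for tx_id, rec in recs.items():
        spans = []
        cum = 0
        for s, e in rec.exons:
            for b in by_gene.get(rec.gene_id, []):
                if s <= b.start and b.end <= e and tx_id in b.transcripts:
                    a = cum + (b.start - s)
                    spans.append((b.bin_id, a, a + (b.end - b.start)))
            cum += e - s
        bin_spans[tx_id] = spans

    samples = list(truth.transcript_counts)
    counts = {b.bin_id: np.zeros(len(samples), dtype=np.int64) for b in bins}
    for j, sample in enumerate(samples):
        for tx_id, c in truth.transcript_counts[sample].items():
            if c == 0:
                continue
            L = recs[tx_id].length
            if L < rl:
                continue
            offsets = np.sort(rng.integers(0, L - rl + 1, size=c))
            for bin_id, a, b in bin_spans[tx_id]:
                lo = max(a - rl + 1, 0)
                n = np.searchsorted(offsets, b) - np.searchsorted(offsets, lo)
                counts[bin_id][j] += n
    df = pd.DataFrame(
        {s: [counts[b.bin_id][j] for b in bins] for j, s in enumerate(samples)},
        index=[b.bin_id for b in bins],
    )
    df.insert(0, "gene_id", [b.gene_id for b in bins])
    df.index.name = "feature_key"
    return df


@dataclass
class BenchmarkData:
    config: SimConfig
    annotation: TranscriptAnnotation
    sequences: dict[str, str]
    truth: SimTruth
    sample_table: SampleTable
    ec_matrix: ECCountMatrix  # annotated + multi-gene filtered
    ec_frame: pd.DataFrame
    transcript_frame: pd.DataFrame
    exon_frame: pd.DataFrame


def simulate_benchmark(config: SimConfig, with_exons: bool = True) -> BenchmarkData:
    """Simulate one experiment and build all three feature matrices."""
    annotation, sequences, truth = simulate_experiment_design(config)
    sample_table = build_sample_table(config)
    rng = np.random.default_rng(config.seed + 10)
    raw_matrix = simulate_ec_counts(annotation, sequences, truth, config, rng=rng)
    annotated = annotate_genes(raw_matrix, annotation.t2g())
    ec_matrix = filter_multigene(annotated)
    ec_frame = ec_matrix.to_frame()
    tx_frame = transcript_count_matrix(
        raw_matrix, annotation, fragment_mean=config.read_length
    )
    if with_exons:
        bins = flatten_exon_bins(annotation)
        exon_frame = exon_bin_matrix_from_offsets(annotation, bins, truth, config, rng)
    else:
        exon_frame = pd.DataFrame(columns=["gene_id"])
    return BenchmarkData(
        config=config,
        annotation=annotation,
        sequences=sequences,
        truth=truth,
        sample_table=sample_table,
        ec_matrix=ec_matrix,
        ec_frame=ec_frame,
        transcript_frame=tx_frame,
        exon_frame=exon_frame,
    )


def run_branch_dtu(
    frame: pd.DataFrame, sample_table: SampleTable, method: str
) -> tuple[evaluate.MethodResult, list, list]:
    """Run the usage test on one feature matrix and wrap the gene calls."""
    features, genes = dtu_stats.run_dtu(frame, sample_table)
    return evaluate.MethodResult.from_gene_results(method, genes), features, genes
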