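"""The two comparator quantifications: EM transcript abundances and exon bins.

``em_abundance`` runs the standard equivalence-class-level EM for transcript
abundance: given EC counts n_e and effective lengths l_t, iterate

    pi_t  <-  (1/N) * sum_e n_e * (pi_t / l_t) / sum_{t' in e} (pi_t' / l_t')

until the proportions converge. ``flatten_exon_bins`` produces the disjoint
exon parts used for exon-level counting: each gene's exons are cut at every
distinct exon boundary within the gene, so every part has a fixed transcript
membership; parts overlapping a different gene on the same strand are
excluded. ``count_exon_bins`` counts simulated reads into those bins the way
an exon-counting tool does: a read increments every bin it overlaps by at
least one base within its gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import RawECTable, TranscriptAnnotation
from .pseudoalign import ReadRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceEstimate",
    "ExonBin",
    "ExonBinTable",
    "effective_lengths",
    "em_abundance",
    "scaled_tpm_counts",
    "flatten_exon_bins",
    "count_exon_bins",
]


@dataclass
class AbundanceEstimate:
    """Per-transcript EM output: expected read counts, TPM, effective length."""

    transcript_ids: list[str]
    estimated_counts: np.ndarray
    tpm: np.ndarray
    effective_lengths: np.ndarray
    n_iterations: int = 0
    log_likelihoods: list[float] | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.estimated_counts, index=self.transcript_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_ids,
                "estimated_count": self.estimated_counts,
                "tpm": self.tpm,
                "effective_length": self.effective_lengths,
            }
        )


def effective_lengths(
    annotation_or_lengths, fragment_mean: float
) -> dict[str, float]:
    """Effective length per transcript: max(L - fragment_mean + 1, 1).

    Accepts a :class:`TranscriptAnnotation` or an id -> length mapping.
    """
    if fragment_mean <= 0:
        raise ValueError("fragment_mean must be > 0")
    if isinstance(annotation_or_lengths, TranscriptAnnotation):
        lengths = {rec.transcript_id: rec.length for rec in annotation_or_lengths}
    else:
        lengths = dict(annotation_or_lengths)
    return {t: max(L - fragment_mean + 1.0, 1.0) for t, L in lengths.items()}


def em_abundance(
    table: RawECTable,
    eff_lengths: dict[str, float],
    tol: float = 1e-8,
    max_iter: int = 1000,
    track_likelihood: bool = False,
) -> AbundanceEstimate:
    """EM estimation of transcript abundances from equivalence-class counts.

    Proportions start uniform (the EC likelihood is concave in the
    proportions, so initialisation only affects iteration count). Stops when
    the max absolute proportion change drops below ``tol`` or after
    ``max_iter`` sweeps. Estimated counts are the final
    responsibility-weighted read mass and sum to the total assigned reads;
    TPM re-normalises count/effective-length to one million.
    """
    names = table.transcript_names
    n_tx = len(names)
    lens = np.array([float(eff_lengths[t]) for t in names])
    if (lens <= 0).any():
        raise ValueError("effective lengths must be positive")

    ec_counts = np.array([c for _, c in table.entries], dtype=float)
    total = ec_counts.sum()
    if total == 0:
        logger.warning("em_abundance: zero total reads; returning all-zero estimate")
        return AbundanceEstimate(
            transcript_ids=list(names),
            estimated_counts=np.zeros(n_tx),
            tpm=np.zeros(n_tx),
            effective_lengths=lens,
        )

    # flat CSR-like layout of EC membership
    member_tx = np.concatenate(
        [np.fromiter(sorted(idx), dtype=np.int64) for idx, _ in table.entries]
    )
    ec_sizes = np.array([len(idx) for idx, _ in table.entries])
    ec_of_member = np.repeat(np.arange(len(table.entries)), ec_sizes)

    pi = np.full(n_tx, 1.0 / n_tx)
    lls: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        rate = pi / lens  # unnormalised read-generation rate per transcript
        denom = np.bincount(ec_of_member, weights=rate[member_tx], minlength=len(ec_counts))
        if track_likelihood:
            with np.errstate(divide="ignore"):
                lls.append(float(np.sum(ec_counts * np.log(denom))))
        # responsibility-weighted read mass per transcript
        frac = rate[member_tx] / denom[ec_of_member]
        mass = np.bincount(member_tx, weights=frac * ec_counts[ec_of_member], minlength=n_tx)
        new_pi = mass / total
        delta = np.abs(new_pi - pi).max()
        pi = new_pi
        if delta < tol:
            break

    counts = pi * total
    dens = counts / lens
    tpm = dens / dens.sum() * 1e6 if dens.sum() > 0 else np.zeros(n_tx)
    return AbundanceEstimate(
        transcript_ids=list(names),
        estimated_counts=counts,
        tpm=tpm,
        effective_lengths=lens,
        n_iterations=n_iter,
        log_likelihoods=lls if track_likelihood else None,
    )


def scaled_tpm_counts(abundance: AbundanceEstimate, library_size: float) -> pd.Series:
    """Transcript counts scaled from TPM to the sample's library size."""
    counts = abundance.tpm * library_size / 1e6
    return pd.Series(counts, index=abundance.transcript_ids)


# ---------------------------------------------------------------------------
# exon bins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonBin:
    """A disjoint exon part: genomic interval plus transcript membership."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    bin_id: str
    transcripts: tuple[str, ...]


@dataclass
class ExonBinTable:
    bins: list[ExonBin]

    def __iter__(self):
        return iter(self.bins)

    def __len__(self) -> int:
        return len(self.bins)

    def by_gene(self) -> dict[str, list[ExonBin]]:
        out: dict[str, list[ExonBin]] = {}
        for b in self.bins:
            out.setdefault(b.gene_id, []).append(b)
        return out


def flatten_exon_bins(annotation: TranscriptAnnotation) -> ExonBinTable:
    """Cut each gene's exons at every exon boundary into disjoint parts.

    Every part carries the transcripts whose exons cover it. Parts
    overlapping the exonic footprint of a different gene on the same strand
    are excluded, matching exon-count preparation that disables aggregation
    of overlapping genes.
    """
    genes = annotation.genes()

    # exonic footprints per (chrom, strand) for overlap exclusion and cutting
    footprints: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for gene_id, recs in genes.items():
        for rec in recs:
            for s, e in rec.exons:
                footprints.setdefault((rec.chrom, rec.strand), []).append((s, e, gene_id))

    bins: list[ExonBin] = []
    for gene_id in sorted(genes):
        recs = genes[gene_id]
        chrom, strand = recs[0].chrom, recs[0].strand
        own = sorted({pos for rec in recs for s, e in rec.exons for pos in (s, e)})
        neighbours = footprints.get((chrom, strand), ())
        # cut also at foreign exon edges inside this gene's span, so overlap
        # exclusion can drop exactly the shared stretch
        lo, hi = own[0], own[-1]
        foreign = {
            pos
            for os_, oe, og in neighbours
            if og != gene_id
            for pos in (os_, oe)
            if lo < pos < hi
        }
        boundaries = sorted(set(own) | foreign)

        segments: list[tuple[int, int, tuple[str, ...]]] = []
        for s, e in zip(boundaries[:-1], boundaries[1:]):
            covering = tuple(
                sorted(
                    rec.transcript_id
                    for rec in recs
                    if any(xs <= s and e <= xe for xs, xe in rec.exons)
                )
            )
            if not covering:
                continue  # intronic gap between exon boundaries
            if any(og != gene_id and s < oe and os_ < e for os_, oe, og in neighbours):
                continue  # overlaps a different gene on the same strand
            if segments and segments[-1][1] == s and segments[-1][2] == covering:
                segments[-1] = (segments[-1][0], e, covering)  # merge same-membership runs
            else:
                segments.append((s, e, covering))

        for i, (s, e, covering) in enumerate(segments, start=1):
            bins.append(
                ExonBin(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=s,
                    end=e,
                    bin_id=f"{gene_id}:E{i:03d}",
                    transcripts=covering,
                )
            )
    return ExonBinTable(bins=bins)


def count_exon_bins(
    reads_by_sample: dict[str, list[ReadRecord]],
    bins: ExonBinTable,
    gene_of_transcript: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Count reads into exon bins from their true genomic intervals.

    A read increments every bin of its gene that it overlaps by >=1 base;
    reads overlapping no bin are ignored (tallied in the log). Returns a
    count-matrix DataFrame (bin_id index, gene_id first column, one column
    per sample).
    """
    by_gene = bins.by_gene()
    samples = list(reads_by_sample)
    counts = {b.bin_id: {s: 0 for s in samples} for b in bins}
    gene_of_bin = {b.bin_id: b.gene_id for b in bins}
    n_orphan = 0
    for sample, reads in reads_by_sample.items():
        for read in reads:
            if read.true_source is None:
                continue
            tx = read.true_source[0]
            gene = gene_of_transcript.get(tx) if gene_of_transcript else None
            if gene is None and gene_of_transcript is not None:
                n_orphan += 1
                continue
            candidates = by_gene.get(gene, []) if gene is not None else bins.bins
            hit = False
            for b in candidates:
                for chrom, s, e in read.genomic_blocks:
                    if chrom == b.chrom and s < b.end and b.start < e:
                        counts[b.bin_id][sample] += 1
                        hit = True
                        break
            if not hit:
                n_orphan += 1
    if n_orphan:
        logger.info("count_exon_bins: %d read(s) overlapped no bin", n_orphan)
    df = pd.DataFrame(
        [[counts[b.bin_id][s] for s in samples] for b in bins],
        index=[b.bin_id for b in bins],
        columns=samples,
    )
    df.insert(0, "gene_id", [gene_of_bin[b.bin_id] for b in bins])
    df.index.name = "feature_key"
    return df
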