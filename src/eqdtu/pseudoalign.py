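"""A minimal k-mer pseudo-aligner.

Assigns error-free reads to equivalence classes by intersecting, over all
of a read's k-mers found in the index, the sets of transcripts containing
each k-mer. This is pure set compatibility: no base-level alignment, no
positional or orientation filters. It exists so the whole pipeline can run
on synthetic data without an external aligner.

k-mers absent from the index are skipped rather than forcing a failed
assignment; this mirrors lightweight-aligner behaviour and keeps
assignment robust at exon-junction edges of small references. A read is
UNASSIGNED when none of its k-mers are indexed or the intersection is
empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats_io import RawECTable

logger = logging.getLogger(__name__)

__all__ = ["KmerIndex", "ReadRecord", "build_index", "assign_ec", "pseudoalign_sample"]

_VALID = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class KmerIndex:
    """Maps every k-mer to the set of transcripts containing it."""

    k: int
    table: dict[str, frozenset[str]]
    transcript_names: list[str]

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")


@dataclass
class ReadRecord:
    """A simulated read; ``true_source`` is carried for evaluation only."""

    read_id: str
    sequence: str
    true_source: tuple[str, int] | None = None
    mate_sequence: str | None = None
    genomic_blocks: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)


def build_index(sequences: dict[str, str], k: int = 31) -> KmerIndex:
    """Index every k-mer of every transcript sequence.

    Sequences shorter than k are skipped with a warning; non-ACGT
    characters are an error.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    table: dict[str, set[str]] = {}
    names: list[str] = []
    for name, seq in sequences.items():
        names.append(name)
        if set(seq) - _VALID:
            bad = sorted(set(seq) - _VALID)
            raise ValueError(f"transcript {name}: non-ACGT character(s) {bad}")
        if len(seq) < k:
            logger.warning("build_index: skipping %s (length %d < k=%d)", name, len(seq), k)
            continue
        for i in range(len(seq) - k + 1):
            table.setdefault(seq[i : i + k], set()).add(name)
    frozen = {kmer: frozenset(txs) for kmer, txs in table.items()}
    return KmerIndex(k=k, table=frozen, transcript_names=names)


def _kmer_hit_sets(sequence: str, index: KmerIndex) -> list[frozenset[str]]:
    k = index.k
    table = index.table
    return [
        s
        for i in range(len(sequence) - k + 1)
        if (s := table.get(sequence[i : i + k])) is not None
    ]


def assign_ec(read: ReadRecord | str, index: KmerIndex, stranded: str = "forward"):
    """Compatibility set of a read: intersection over its indexed k-mers.

    Returns a frozenset of transcript ids, or ``None`` (UNASSIGNED) when no
    k-mer is indexed or the intersection is empty. ``stranded="both"``
    additionally tries the reverse complement and unions the two
    assignments.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if len(seq) < index.k:
        logger.debug("assign_ec: read shorter than k, unassigned")
        return None
    result = _intersect_hits(_kmer_hit_sets(seq, index))
    if stranded == "both":
        rc = _intersect_hits(_kmer_hit_sets(revcomp(seq), index))
        if result is None:
            result = rc
        elif rc is not None:
            result = result | rc
    return result


def _intersect_hits(hits: list[frozenset[str]]):
    if not hits:
        return None
    out = set(hits[0])
    for s in hits[1:]:
        out &= s
        if not out:
            return None
    return frozenset(out)


def pseudoalign_sample(
    reads: Iterable[ReadRecord],
    index: KmerIndex,
    paired: bool = False,
    sample_id: str = "",
    stranded: str = "forward",
) -> RawECTable:
    """Aggregate per-read EC assignments into a per-sample count table.

    In paired mode each mate is assigned separately and the two sets are
    intersected before classifying the fragment. Unassigned reads are
    tallied, logged and excluded from the table.
    """
    counts: dict[frozenset[str], int] = {}
    n_unassigned = 0
    n_total = 0
    for read in reads:
        n_total += 1
        ec = assign_ec(read, index, stranded=stranded)
        if paired and read.mate_sequence is not None:
            mate_ec = assign_ec(read.mate_sequence, index, stranded=stranded)
            if ec is None or mate_ec is None:
                ec = None
            else:
                ec = ec & mate_ec
                if not ec:
                    ec = None
        if ec is None:
            n_unassigned += 1
            continue
        counts[ec] = counts.get(ec, 0) + 1
    if n_unassigned:
        logger.info(
            "pseudoalign_sample %s: %d/%d reads unassigned", sample_id, n_unassigned, n_total
        )
    name_to_idx = {n: i for i, n in enumerate(index.transcript_names)}
    entries = [
        (frozenset(name_to_idx[t] for t in ec), c) for ec, c in counts.items()
    ]
    return RawECTable(
        transcript_names=list(index.transcript_names),
        entries=entries,
        sample_id=sample_id,
    )


def window_compatibility(
    sequence: str, index: KmerIndex, read_length: int
) -> list[frozenset[str] | None]:
    """EC assignment of the error-free read starting at every offset.

    Equivalent to calling :func:`assign_ec` on each length-``read_length``
    substring, but computed with a run-compressed sweep so whole
    transcripts can be profiled cheaply. Entry ``p`` is the compatibility
    set of ``sequence[p:p+read_length]`` (``None`` = unassigned).
    """
    k = index.k
    if read_length < k or len(sequence) < read_length:
        return []
    n_kmers = len(sequence) - k + 1
    window = read_length - k + 1  # k-mers per read

    # per-position k-mer hit sets, run-length compressed
    sets: list[frozenset[str] | None] = [
        index.table.get(sequence[i : i + k]) for i in range(n_kmers)
    ]
    runs: list[tuple[int, int, frozenset[str] | None]] = []
    start = 0
    for i in range(1, n_kmers + 1):
        if i == n_kmers or sets[i] is not sets[start] and sets[i] != sets[start]:
            runs.append((start, i, sets[start]))
            start = i

    n_windows = len(sequence) - read_length + 1
    out: list[frozenset[str] | None] = []
    run_starts = [r[0] for r in runs]
    import bisect

    cache_key: tuple[int, int] | None = None
    cache_val: frozenset[str] | None = None
    for p in range(n_windows):
        lo, hi = p, p + window  # k-mer positions [lo, hi)
        first = bisect.bisect_right(run_starts, lo) - 1
        last = bisect.bisect_right(run_starts, hi - 1) - 1
        key = (first, last)
        if key != cache_key:
            hits = [runs[r][2] for r in range(first, last + 1) if runs[r][2] is not None]
            cache_val = _intersect_hits(hits)
            cache_key = key
        out.append(cache_val)
    return out
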