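"""Canonical equivalence classes and the cross-sample EC count matrix.

An equivalence class (EC) is the set of transcripts a read is compatible
with under pseudo-alignment; all reads sharing that set form one class.
This module matches per-sample EC observations into a single matrix, labels
each class with the gene its transcripts belong to, and removes classes
whose transcripts span more than one gene — the only filtering the method
applies to EC counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .formats_io import RawECTable

logger = logging.getLogger(__name__)

#: Gene label for ECs whose transcripts belong to more than one gene.
AMBIGUOUS = "__ambiguous__"
#: Gene label for ECs containing a transcript absent from the t2g map.
UNKNOWN = "__unknown__"

__all__ = [
    "AMBIGUOUS",
    "UNKNOWN",
    "EquivalenceClass",
    "ECCountMatrix",
    "canonical_key",
    "build_ec_matrix",
    "annotate_genes",
    "filter_multigene",
]


def canonical_key(transcript_ids) -> str:
    """Deterministic row key for a transcript set: sorted ids joined by '|'."""
    ids = sorted(set(transcript_ids))
    if not ids:
        raise ValueError("cannot build a key for an empty transcript set")
    return "|".join(ids)


@dataclass(frozen=True)
class EquivalenceClass:
    """A canonical EC: sorted transcript tuple plus (optional) gene label."""

    transcripts: tuple[str, ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError("equivalence class must contain >=1 transcript")
        if list(self.transcripts) != sorted(set(self.transcripts)):
            raise ValueError("transcripts must be sorted and unique")

    @property
    def key(self) -> str:
        return "|".join(self.transcripts)

    @classmethod
    def from_ids(cls, transcript_ids, gene_id: str | None = None) -> "EquivalenceClass":
        return cls(transcripts=tuple(sorted(set(transcript_ids))), gene_id=gene_id)


@dataclass
class ECCountMatrix:
    """Rows of equivalence classes by columns of samples, integer counts."""

    rows: list[EquivalenceClass]
    samples: list[str]
    counts: np.ndarray  # shape (n_rows, n_samples), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.rows), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.rows)} rows x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        keys = [r.key for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate EC row keys")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def keys(self) -> list[str]:
        return [r.key for r in self.rows]

    @property
    def gene_ids(self) -> list[str | None]:
        return [r.gene_id for r in self.rows]

    def column_totals(self) -> dict[str, int]:
        sums = self.counts.sum(axis=0)
        return {s: int(v) for s, v in zip(self.samples, sums)}

    def to_frame(self) -> pd.DataFrame:
        """Count-matrix DataFrame (feature_key index, gene_id first column)."""
        df = pd.DataFrame(self.counts, index=self.keys, columns=self.samples)
        df.insert(0, "gene_id", [g if g is not None else "" for g in self.gene_ids])
        df.index.name = "feature_key"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ECCountMatrix":
        samples = [c for c in df.columns if c != "gene_id"]
        rows = [
            EquivalenceClass(
                transcripts=tuple(str(key).split("|")),
                gene_id=(str(g) if str(g) != "" else None),
            )
            for key, g in zip(df.index, df["gene_id"])
        ]
        return cls(rows=rows, samples=samples, counts=df[samples].to_numpy())

    def subset_samples(self, sample_ids) -> "ECCountMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return ECCountMatrix(
            rows=list(self.rows),
            samples=list(sample_ids),
            counts=self.counts[:, idx],
        )


def build_ec_matrix(tables: list[RawECTable], sample_order: list[str] | None = None) -> ECCountMatrix:
    """Match ECs across samples and compile them into one count matrix.

    Rows are the union of observed classes over all samples; a sample
    lacking a class gets count 0. Per-sample totals are conserved. All
    tables must share one transcript namespace (the same reference).
    """
    if sample_order is None:
        sample_order = [t.sample_id for t in tables]
    if len(set(sample_order)) != len(sample_order):
        raise ValueError("duplicate sample id in sample order")
    by_id = {t.sample_id: t for t in tables}
    if len(by_id) != len(tables):
        raise ValueError("duplicate sample id among input tables")
    missing = [s for s in sample_order if s not in by_id]
    if missing:
        raise ValueError(f"sample order names absent samples: {missing}")

    namespaces = {frozenset(t.transcript_names) for t in tables}
    if len(namespaces) > 1:
        raise ValueError(
            "input tables use different transcript references; refusing to merge"
        )

    row_index: dict[str, int] = {}
    row_classes: list[EquivalenceClass] = []
    per_sample_counts: list[dict[int, int]] = []
    for sample_id in sample_order:
        table = by_id[sample_id]
        col: dict[int, int] = {}
        for tx_set, count in table.named_entries():
            ec = EquivalenceClass.from_ids(tx_set)
            i = row_index.get(ec.key)
            if i is None:
                i = len(row_classes)
                row_index[ec.key] = i
                row_classes.append(ec)
            col[i] = col.get(i, 0) + count
        per_sample_counts.append(col)

    counts = np.zeros((len(row_classes), len(sample_order)), dtype=np.int64)
    for j, col in enumerate(per_sample_counts):
        for i, c in col.items():
            counts[i, j] = c
    return ECCountMatrix(rows=row_classes, samples=list(sample_order), counts=counts)


def annotate_genes(matrix: ECCountMatrix, t2g: dict[str, str]) -> ECCountMatrix:
    """Label every EC row with the unique gene of its transcripts.

    Rows whose transcripts span more than one gene are labelled
    :data:`AMBIGUOUS`; rows containing a transcript missing from ``t2g``
    are labelled :data:`UNKNOWN`.
    """
    new_rows: list[EquivalenceClass] = []
    for ec in matrix.rows:
        genes = set()
        unknown = False
        for tx in ec.transcripts:
            g = t2g.get(tx)
            if g is None:
                unknown = True
            else:
                genes.add(g)
        if unknown:
            label = UNKNOWN
        elif len(genes) > 1:
            label = AMBIGUOUS
        else:
            label = next(iter(genes))
        new_rows.append(replace(ec, gene_id=label))
    return ECCountMatrix(
        rows=new_rows, samples=list(matrix.samples), counts=matrix.counts.copy()
    )


def filter_multigene(matrix: ECCountMatrix, strict: bool = False) -> ECCountMatrix:
    """Remove ECs mapping to more than a single gene (and unannotated ones).

    This removal is the only filtering applied to the EC matrix by default.
    ``strict=True`` turns unannotated (UNKNOWN) rows into an error instead
    of a logged drop.
    """
    n_unknown = sum(1 for ec in matrix.rows if ec.gene_id == UNKNOWN)
    if strict and n_unknown:
        raise ValueError(f"{n_unknown} EC row(s) contain unannotated transcripts")
    if n_unknown:
        logger.warning(
            "filter_multigene: dropping %d EC row(s) with unannotated transcripts",
            n_unknown,
        )
    keep = [
        i
        for i, ec in enumerate(matrix.rows)
        if ec.gene_id not in (AMBIGUOUS, UNKNOWN)
    ]
    return ECCountMatrix(
        rows=[matrix.rows[i] for i in keep],
        samples=list(matrix.samples),
        counts=matrix.counts[keep, :],
    )
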