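"""Readers and writers for the external formats the pipeline touches.

Equivalence-class outputs from Salmon (``eq_classes.txt``, produced with
``--dumpEq``) and Kallisto (``pseudo --batch`` directories), transcript
annotation as GTF, sequences as FASTA/FASTQ, and the TSV count-matrix and
sample-table formats used between pipeline stages.

Coordinates are 1-based inclusive in GTF files and 0-based half-open
everywhere inside the package; conversion happens at the I/O boundary.
Gzip-compressed inputs are accepted transparently by ``.gz`` extension.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptRecord",
    "TranscriptAnnotation",
    "RawECTable",
    "SampleTable",
    "read_salmon_eq",
    "write_salmon_eq",
    "read_kallisto_pseudo",
    "write_kallisto_pseudo",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_table",
    "write_sample_table",
    "ECParseError",
]


class ECParseError(ValueError):
    """Malformed equivalence-class file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: its gene, location and exon structure.

    Exons are 0-based half-open genomic intervals, non-overlapping and
    sorted by start.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(
                    f"bad exon interval [{start}, {end}) in {self.transcript_id}"
                )
            if start < prev_end:
                raise ValueError(
                    f"exons overlap or are unsorted in {self.transcript_id}"
                )
            prev_end = end

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class TranscriptAnnotation:
    """A set of transcript models; each transcript belongs to exactly one gene."""

    records: list[TranscriptRecord]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rec in self.records:
            if rec.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {rec.transcript_id}")
            seen[rec.transcript_id] = rec.gene_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def transcript(self, transcript_id: str) -> TranscriptRecord:
        for rec in self.records:
            if rec.transcript_id == transcript_id:
                return rec
        raise KeyError(transcript_id)

    def t2g(self) -> dict[str, str]:
        """Transcript-to-gene map."""
        return {rec.transcript_id: rec.gene_id for rec in self.records}

    def genes(self) -> dict[str, list[TranscriptRecord]]:
        out: dict[str, list[TranscriptRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.gene_id, []).append(rec)
        return out


@dataclass
class RawECTable:
    """Per-sample equivalence-class observations.

    ``entries`` pairs a set of transcript indices (into ``transcript_names``)
    with a non-negative read count. No two entries share an index set.
    """

    transcript_names: list[str]
    entries: list[tuple[frozenset[int], int]]
    sample_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.transcript_names)
        seen: set[frozenset[int]] = set()
        for idx_set, count in self.entries:
            if not idx_set:
                raise ValueError("empty transcript index set in EC entry")
            if min(idx_set) < 0 or max(idx_set) >= n:
                raise ECParseError(
                    f"transcript index out of bounds (N={n}) in sample "
                    f"{self.sample_id!r}"
                )
            if count < 0:
                raise ValueError("negative EC count")
            if idx_set in seen:
                raise ECParseError(
                    f"duplicate equivalence class in sample {self.sample_id!r}"
                )
            seen.add(idx_set)

    @property
    def total_reads(self) -> int:
        return sum(c for _, c in self.entries)

    def named_entries(self) -> list[tuple[frozenset[str], int]]:
        """Entries with transcript indices resolved to names."""
        return [
            (frozenset(self.transcript_names[i] for i in idx), c)
            for idx, c in self.entries
        ]


@dataclass
class SampleTable:
    """Sample sheet: id, condition label (e.g. S1/S2) and input path."""

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in sample table")
        if self.rows and not self.conditions:
            raise ValueError("sample table has no conditions")

    @property
    def sample_ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for _, cond, _ in self.rows:
            if cond not in seen:
                seen.append(cond)
        return seen

    def condition_of(self) -> dict[str, str]:
        return {sid: cond for sid, cond, _ in self.rows}

    def paths(self) -> dict[str, str]:
        return {sid: path for sid, _, path in self.rows}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Salmon eq_classes.txt
# ---------------------------------------------------------------------------


def read_salmon_eq(path, sample_id: str | None = None) -> RawECTable:
    """Parse a Salmon ``eq_classes.txt`` file into a :class:`RawECTable`.

    The file starts with the number of transcripts N and the number of
    equivalence classes M, followed by N transcript names and M class lines.
    Each class line holds k, then k transcript indices, then the read count.
    The weighted dialect (k indices followed by k per-transcript weights and
    the count) is auto-detected; weights are ignored because the method
    consumes plain counts.
    """
    if sample_id is None:
        sample_id = os.path.basename(os.path.dirname(os.path.abspath(path))) or str(path)
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 2:
        raise ECParseError(f"{path}: truncated header (need two count lines)")
    try:
        n_tx = int(lines[0].strip())
        n_ec = int(lines[1].strip())
    except ValueError as exc:
        raise ECParseError(f"{path}: malformed header on line 1-2: {exc}") from exc
    if len(lines) < 2 + n_tx + n_ec:
        raise ECParseError(
            f"{path}: expected {2 + n_tx + n_ec} lines, found {len(lines)}"
        )
    names = [lines[2 + i].strip() for i in range(n_tx)]
    entries: list[tuple[frozenset[int], int]] = []
    for j in range(n_ec):
        lineno = 2 + n_tx + j + 1
        tokens = lines[2 + n_tx + j].split()
        if not tokens:
            raise ECParseError(f"{path}: empty EC line {lineno}")
        try:
            k = int(tokens[0])
        except ValueError as exc:
            raise ECParseError(f"{path}: bad class size on line {lineno}") from exc
        body = tokens[1:]
        if len(body) == k + 1:
            idx_tokens, count_token = body[:k], body[k]
        elif len(body) == 2 * k + 1:
            # weighted dialect: k indices, k weights, count
            idx_tokens, count_token = body[:k], body[2 * k]
        else:
            raise ECParseError(
                f"{path}: EC line {lineno} has {len(body)} fields, "
                f"expected {k + 1} or {2 * k + 1}"
            )
        try:
            indices = frozenset(int(t) for t in idx_tokens)
            count = int(round(float(count_token)))
        except ValueError as exc:
            raise ECParseError(f"{path}: bad field on line {lineno}") from exc
        if indices and max(indices) >= n_tx:
            raise ECParseError(
                f"{path}: transcript index out of bounds on line {lineno}"
            )
        entries.append((indices, count))
    return RawECTable(transcript_names=names, entries=entries, sample_id=sample_id)


def write_salmon_eq(table: RawECTable, path) -> None:
    """Serialize a :class:`RawECTable` in the plain Salmon dialect."""
    with _open_text(path, "wt") as fh:
        fh.write(f"{len(table.transcript_names)}\n{len(table.entries)}\n")
        for name in table.transcript_names:
            fh.write(name + "\n")
        for idx_set, count in table.entries:
            idx = sorted(idx_set)
            fh.write(" ".join([str(len(idx))] + [str(i) for i in idx] + [str(count)]) + "\n")


# ---------------------------------------------------------------------------
# Kallisto pseudo --batch layout
# ---------------------------------------------------------------------------

_KALLISTO_FILES = ("transcripts.txt", "matrix.ec", "matrix.cells", "matrix.tsv")


def read_kallisto_pseudo(directory) -> list[RawECTable]:
    """Parse a Kallisto ``pseudo --batch`` output directory.

    Returns one table per sample listed in ``matrix.cells``, in file order.
    Classes with zero count in a sample are omitted from that sample's
    entries.
    """
    directory = os.fspath(directory)
    for fname in _KALLISTO_FILES:
        if not os.path.exists(os.path.join(directory, fname)) and not os.path.exists(
            os.path.join(directory, fname + ".gz")
        ):
            raise FileNotFoundError(f"{directory}: missing {fname}")

    def _find(fname):
        p = os.path.join(directory, fname)
        return p if os.path.exists(p) else p + ".gz"

    with _open_text(_find("transcripts.txt")) as fh:
        names = [ln.strip() for ln in fh if ln.strip()]
    ec_defs: dict[int, frozenset[int]] = {}
    with _open_text(_find("matrix.ec")) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            ec_id_s, idx_s = ln.rstrip("\n").split("\t")
            ec_defs[int(ec_id_s)] = frozenset(int(t) for t in idx_s.split(","))
    with _open_text(_find("matrix.cells")) as fh:
        cells = [ln.strip() for ln in fh if ln.strip()]
    per_sample: list[list[tuple[frozenset[int], int]]] = [[] for _ in cells]
    with _open_text(_find("matrix.tsv")) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            ec_id_s, samp_s, count_s = ln.rstrip("\n").split("\t")
            ec_id, samp, count = int(ec_id_s), int(samp_s), int(count_s)
            if ec_id not in ec_defs:
                raise ECParseError(
                    f"{directory}: matrix.tsv references undefined EC id {ec_id}"
                )
            if not (0 <= samp < len(cells)):
                raise ECParseError(
                    f"{directory}: matrix.tsv references sample index {samp}"
                )
            if count > 0:
                per_sample[samp].append((ec_defs[ec_id], count))
    return [
        RawECTable(transcript_names=list(names), entries=entries, sample_id=cell)
        for cell, entries in zip(cells, per_sample)
    ]


def write_kallisto_pseudo(tables: Sequence[RawECTable], directory) -> None:
    """Serialize tables (sharing one transcript namespace) in the batch layout."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    if not tables:
        raise ValueError("no tables to write")
    names = tables[0].transcript_names
    for t in tables:
        if t.transcript_names != names:
            raise ValueError("tables do not share a transcript namespace")
    ec_index: dict[frozenset[int], int] = {}
    for t in tables:
        for idx_set, _ in t.entries:
            if idx_set not in ec_index:
                ec_index[idx_set] = len(ec_index)
    with open(os.path.join(directory, "transcripts.txt"), "w") as fh:
        fh.write("".join(n + "\n" for n in names))
    with open(os.path.join(directory, "matrix.ec"), "w") as fh:
        for idx_set, ec_id in ec_index.items():
            fh.write(f"{ec_id}\t{','.join(str(i) for i in sorted(idx_set))}\n")
    with open(os.path.join(directory, "matrix.cells"), "w") as fh:
        fh.write("".join(t.sample_id + "\n" for t in tables))
    with open(os.path.join(directory, "matrix.tsv"), "w") as fh:
        for samp, t in enumerate(tables):
            for idx_set, count in t.entries:
                if count > 0:
                    fh.write(f"{ec_index[idx_set]}\t{samp}\t{count}\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def read_gtf(path) -> TranscriptAnnotation:
    """Read exon features from a GTF into a :class:`TranscriptAnnotation`.

    GTF's 1-based inclusive coordinates become 0-based half-open. Exons are
    grouped per transcript and sorted by start. An exon without a
    transcript_id is skipped with a warning; a transcript assigned to two
    genes is an error.
    """
    import gffutils

    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    n_skipped = 0
    for feat in db.features_of_type("exon"):
        tx_ids = feat.attributes.get("transcript_id")
        gene_ids = feat.attributes.get("gene_id")
        if not tx_ids:
            n_skipped += 1
            continue
        tx_id = tx_ids[0]
        gene_id = gene_ids[0] if gene_ids else ""
        if tx_id in meta and meta[tx_id][0] != gene_id:
            raise ValueError(
                f"transcript {tx_id} assigned to genes {meta[tx_id][0]} and {gene_id}"
            )
        meta.setdefault(tx_id, (gene_id, feat.seqid, feat.strand))
        # GTF is 1-based inclusive
        exons.setdefault(tx_id, []).append((feat.start - 1, feat.end))
    if n_skipped:
        logger.warning("read_gtf: skipped %d exon(s) without transcript_id", n_skipped)
    records = [
        TranscriptRecord(
            transcript_id=tx_id,
            gene_id=meta[tx_id][0],
            chrom=meta[tx_id][1],
            strand=meta[tx_id][2],
            exons=tuple(sorted(exons[tx_id])),
        )
        for tx_id in exons
    ]
    return TranscriptAnnotation(records=records)


def write_gtf(annotation: TranscriptAnnotation, path, source: str = "eqdtu") -> None:
    """Write exon features (one line per exon, 1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        for rec in annotation.records:
            for start, end in rec.exons:
                attrs = (
                    f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            rec.chrom,
                            source,
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            rec.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict; duplicate ids error."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate sequence id {rec.id}")
            out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path, quality: int = 40) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    with _open_text(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]


# ---------------------------------------------------------------------------
# TSV count matrices and sample tables
# ---------------------------------------------------------------------------


def write_count_matrix(df: pd.DataFrame, path) -> None:
    """Write a count matrix TSV.

    Layout: columns ``feature_key``, ``gene_id``, then one integer column per
    sample. ``df`` must carry feature_key as its index and gene_id as its
    first column.
    """
    if df.columns[0] != "gene_id":
        raise ValueError("first column must be gene_id")
    out = df.reset_index()
    out = out.rename(columns={out.columns[0]: "feature_key"})
    out.to_csv(path, sep="\t", index=False)


def read_count_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"feature_key": str, "gene_id": str})
    if "feature_key" not in df.columns or "gene_id" not in df.columns:
        raise ValueError(f"{path}: not a count matrix (missing key columns)")
    df = df.set_index("feature_key")
    count_cols = [c for c in df.columns if c != "gene_id"]
    for col in count_cols:
        try:
            values = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric count in column {col}") from exc
        if not (values == values.round()).all():
            raise ValueError(f"{path}: non-integer count in column {col}")
        df[col] = values.astype("int64")
    return df


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample table needs columns {sorted(required)}")
    if "path" not in df.columns:
        df["path"] = ""
    rows = [
        (str(r["sample"]), str(r["condition"]), str(r["path"]))
        for _, r in df.iterrows()
    ]
    return SampleTable(rows=rows)


def write_sample_table(table: SampleTable, path) -> None:
    pd.DataFrame(table.rows, columns=["sample", "condition", "path"]).to_csv(
        path, sep="\t", index=False
    )
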