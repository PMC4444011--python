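"""Readers, writers and core containers for the plain-text genomics formats
the pipeline consumes.

Coordinate convention
---------------------
All internal coordinates are **0-based, half-open** (``[start, end)``), the
BED/bedGraph convention.  GFF3's 1-based closed intervals are converted at the
parse/serialize boundary and nowhere else, so there is a single place where an
off-by-one could live.  Stored gene models are never rewritten for strand:
minus-strand genes keep their genomic coordinates and are reflected about the
TSS only when a transcription-oriented profile is extracted.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

__all__ = [
    "GeneModel",
    "CountMatrix",
    "CoverageTrack",
    "merge_intervals",
    "read_gene_models",
    "write_gene_models",
    "read_bedgraph",
    "write_bedgraph",
    "read_count_matrix",
    "write_count_matrix",
]


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Sort half-open intervals and merge any that touch or overlap."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    if not ivs:
        raise ValueError("at least one interval is required")
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
    merged: list[list[int]] = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene: TSS, merged exons and exonic length.

    ``exons`` are half-open genomic intervals; they are merged and sorted on
    construction so the stored model always satisfies its own invariants.
    The TSS is the leftmost exon start on the plus strand and the rightmost
    exon end on the minus strand (multi-transcript genes collapse to the
    union of exons, anchored at the most extreme annotated start).
    """

    gene_id: str
    contig: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        object.__setattr__(self, "exons", merge_intervals(self.exons))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class CountMatrix:
    """Genes x samples raw read counts plus per-sample library sizes.

    Library sizes are the totals of *uniquely mapped* reads and may exceed the
    column sums (not all mapped reads fall in exons); they must be positive.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError("counts dimensions must match gene/sample id lists")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.library_sizes.shape != (len(self.sample_ids),):
            raise ValueError("one library size per sample required")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]


@dataclass
class CoverageTrack:
    """Per-contig read density in contiguous fixed-width bins.

    ``values[i]`` is the density (reads per bp) over the genomic interval
    ``[origin + i*step, origin + (i+1)*step)``.  ``step=1`` is base
    resolution.
    """

    contig: str
    origin: int
    step: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.step < 1:
            raise ValueError("step must be >= 1 bp")
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coverage values must be finite")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    @property
    def end(self) -> int:
        return self.origin + self.step * len(self.values)

    def total(self) -> float:
        """Integrated coverage, i.e. sum(values) * step (approx. read count)."""
        return float(self.values.sum() * self.step)

    def base_values(self, start: int, end: int) -> np.ndarray:
        """Per-base densities over genomic ``[start, end)``.

        Raises if the requested region exceeds the track extent.
        """
        if start < self.origin or end > self.end or end <= start:
            raise ValueError(
                f"region [{start}, {end}) outside track {self.contig} "
                f"[{self.origin}, {self.end})"
            )
        expanded = np.repeat(self.values, self.step)
        off = start - self.origin
        return expanded[off : off + (end - start)]


# ---------------------------------------------------------------------------
# Gene models (BED6 / GFF3)
# ---------------------------------------------------------------------------

_BED6_COLS = ["contig", "start", "end", "name", "score", "strand"]


def read_gene_models(path: str | Path, format: str = "bed6") -> list[GeneModel]:
    """Read gene models from a BED6 or GFF3 file.

    BED is taken as 0-based half-open; GFF3 1-based closed intervals are
    converted on the way in.  Records without a usable strand are rejected
    with a logged warning.  Rows/features sharing a gene id are collapsed to
    the union of their exons; the same id on conflicting contigs or strands
    is an error.
    """
    if format == "bed6":
        return _read_bed6(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown gene-model format {format!r} (use 'bed6' or 'gff3')")


def _collapse(records: dict[str, list[tuple[str, str, Interval]]]) -> list[GeneModel]:
    genes = []
    for gid, rows in records.items():
        contigs = {c for c, _, _ in rows}
        strands = {s for _, s, _ in rows}
        if len(contigs) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene id {gid!r} appears on conflicting contigs/strands"
            )
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=rows[0][0],
                strand=rows[0][1],
                exons=tuple(iv for _, _, iv in rows),
            )
        )
    return genes


def _read_bed6(path: str | Path) -> list[GeneModel]:
    try:
        df = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None, names=_BED6_COLS, dtype=str
        )
    except pd.errors.EmptyDataError:
        return []
    records: dict[str, list[tuple[str, str, Interval]]] = {}
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            logger.warning(
                "BED record %r has no usable strand (%r); record rejected",
                row.name,
                row.strand,
            )
            continue
        records.setdefault(row.name, []).append(
            (row.contig, row.strand, (int(row.start), int(row.end)))
        )
    return _collapse(records)


def _read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: dict[str, list[tuple[str, str, Interval]]] = {}
    for exon in db.features_of_type("exon"):
        parents = list(db.parents(exon, featuretype="gene"))
        if parents:
            gid = parents[0].id
        elif "gene_id" in exon.attributes:
            gid = exon.attributes["gene_id"][0]
        elif "Parent" in exon.attributes:
            gid = exon.attributes["Parent"][0]
        else:
            logger.warning("GFF3 exon at %s:%s has no gene; record rejected",
                           exon.seqid, exon.start)
            continue
        if exon.strand not in ("+", "-"):
            logger.warning("GFF3 exon of %r has no usable strand; record rejected", gid)
            continue
        # 1-based closed -> 0-based half-open
        records.setdefault(gid, []).append(
            (exon.seqid, exon.strand, (exon.start - 1, exon.end))
        )
    return _collapse(records)


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Serialize gene models to BED6, one row per merged exon."""
    with open(path, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                fh.write(f"{g.contig}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path, step: int = 1) -> list[CoverageTrack]:
    """Read a 4-column bedGraph into per-contig :class:`CoverageTrack` objects.

    Run-length intervals are expanded into the binned representation; gaps
    between intervals are filled with zero.  Intervals must be sorted and
    non-overlapping per contig, with non-negative values, and (for step > 1)
    aligned to the bin grid.
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["contig", "start", "end", "value"],
        )
    except pd.errors.EmptyDataError:
        return []
    df = df[~df["contig"].astype(str).str.startswith(("track", "browser"))]
    tracks = []
    for contig, sub in df.groupby("contig", sort=False):
        starts = sub["start"].to_numpy(int)
        ends = sub["end"].to_numpy(int)
        vals = sub["value"].to_numpy(float)
        if (vals < 0).any():
            raise ValueError(f"negative coverage value on contig {contig}")
        order = np.argsort(starts, kind="stable")
        starts, ends, vals = starts[order], ends[order], vals[order]
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping bedGraph intervals on contig {contig}")
        origin = int(starts[0])
        if step > 1 and (
            ((starts - origin) % step).any() or ((ends - origin) % step).any()
        ):
            raise ValueError(
                f"bedGraph intervals on {contig} not aligned to step={step}"
            )
        n = (int(ends[-1]) - origin) // step
        values = np.zeros(n, dtype=float)
        for s, e, v in zip(starts, ends, vals):
            values[(s - origin) // step : (e - origin) // step] = v
        tracks.append(CoverageTrack(contig=str(contig), origin=origin, step=step,
                                    values=values))
    return tracks


def write_bedgraph(tracks: Sequence[CoverageTrack], path: str | Path) -> None:
    """Write tracks as run-length-encoded bedGraph (zero runs included, so a
    write -> read round trip reproduces the binned values exactly)."""
    with open(path, "w") as fh:
        for t in tracks:
            if len(t.values) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(t.values)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(t.values)]))
            for s, e in zip(starts, ends):
                g0 = t.origin + s * t.step
                g1 = t.origin + e * t.step
                fh.write(f"{t.contig}\t{g0}\t{g1}\t{t.values[s]:.10g}\n")


# ---------------------------------------------------------------------------
# Count matrices (TSV)
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column gene ids, header sample ids).

    An optional metadata line ``#library_sizes<TAB>n1<TAB>n2...`` carries the
    per-sample totals of uniquely mapped reads; when absent, column sums are
    used and a notice is logged.
    """
    lib_line = None
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if line.startswith("#library_sizes"):
                    lib_line = line
                continue
            body.append(line)
    df = pd.read_csv(_stdio.StringIO("".join(body)), sep="\t", index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (np.mod(coerced.fillna(0), 1) != 0)
        if bad.any():
            gene = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(
                f"non-integer or missing count at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced.astype(np.int64)
    sample_ids = [str(c) for c in df.columns]
    if lib_line is not None:
        fields = lib_line.rstrip("\n").split("\t")[1:]
        if len(fields) != len(sample_ids):
            raise ValueError(
                "#library_sizes line must carry one value per sample column"
            )
        library_sizes = np.array([int(x) for x in fields], dtype=np.int64)
    else:
        library_sizes = df.to_numpy().sum(axis=0)
        logger.info(
            "no #library_sizes line in %s; defaulting to column sums", path
        )
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=sample_ids,
        counts=df.to_numpy(),
        library_sizes=library_sizes,
    )


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#library_sizes\t" + "\t".join(str(int(x)) for x in cm.library_sizes)
                 + "\n")
        cm.to_frame().rename_axis("gene_id").to_csv(fh, sep="\t")


def write_table(obj, path: str | Path) -> None:
    """Write a pipeline object to a TSV file.

    Dispatches on type: :class:`CountMatrix` gains its ``#library_sizes``
    metadata line; DataFrames are written as plain TSV.
    """
    if isinstance(obj, CountMatrix):
        write_count_matrix(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t")
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__} to a table")
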