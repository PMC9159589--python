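"""Readers and writers for the tabular/interval formats the pipeline consumes.

Coordinates are 0-based half-open (BED convention) everywhere internally.
Parsers validate strictly and raise :class:`FormatError` naming the offending
line; malformed records are never silently repaired. Counts are required to
be raw non-negative integers — normalization (RPKM) is always computed
downstream, never read from file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ASSAYS = ("TF_A", "TF_B", "H3K27Ac", "H3K4Me3", "H3K27Me3", "ATAC", "IgG")
GENOTYPES = ("WT", "KO_A", "KO_B")
STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A malformed record in an input file."""


@dataclass
class GenomicInterval:
    """A located element (peak) on a genome; the atom of all overlap logic.

    ``start``/``end`` are 0-based half-open; ``summit_offset``, when present,
    is the offset of the single-base summit from ``start``.
    """

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"interval {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"interval {self.name!r}: bad strand {self.strand!r}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise FormatError(
                f"interval {self.name!r}: summit_offset {self.summit_offset} "
                f"outside [0, {self.end - self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def point(self) -> int:
        """Reference point: summit when present, else midpoint (floor)."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return self.start + self.length // 2


@dataclass
class SampleSheet:
    """Sample metadata: assay, genotype, replicate and library size per sample."""

    df: pd.DataFrame

    REQUIRED = ("sample_id", "assay", "genotype", "replicate", "library_size")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        df = self.df
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        bad_assay = set(df["assay"]) - set(ASSAYS)
        if bad_assay:
            raise FormatError(f"unknown assay token(s): {sorted(bad_assay)}")
        bad_geno = set(df["genotype"]) - set(GENOTYPES)
        if bad_geno:
            raise FormatError(f"unknown genotype token(s): {sorted(bad_geno)}")
        if (df["library_size"] <= 0).any():
            raise FormatError("library_size must be > 0 for every sample")
        if (df["replicate"] < 1).any():
            raise FormatError("replicate must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def samples_for(self, assay: str, genotype: str) -> list[str]:
        m = (self.df["assay"] == assay) & (self.df["genotype"] == genotype)
        return list(self.df.loc[m, "sample_id"])

    def library_sizes(self, sample_ids: Sequence[str]) -> np.ndarray:
        s = self.df.set_index("sample_id")["library_size"]
        return s.loc[list(sample_ids)].to_numpy(dtype=float)


@dataclass
class SignalMatrix:
    """Raw per-(peak, sample) read counts plus peak lengths in bp."""

    peak_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_peaks, n_samples), non-negative ints
    peak_lengths: np.ndarray  # shape (n_peaks,), bp

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.peak_lengths = np.asarray(self.peak_lengths)
        if self.counts.shape != (len(self.peak_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.peak_ids)} peaks x {len(self.sample_ids)} samples"
            )
        if len(set(self.peak_ids)) != len(self.peak_ids):
            raise FormatError("peak_ids must be unique")
        if self.peak_lengths.shape != (len(self.peak_ids),):
            raise FormatError("peak_lengths length mismatch")
        if (self.peak_lengths <= 0).any():
            raise FormatError("peak_lengths must be > 0")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise FormatError("counts must be non-negative")

    def subset_samples(self, sample_ids: Sequence[str]) -> "SignalMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SignalMatrix(
            self.peak_ids, list(sample_ids), self.counts[:, idx], self.peak_lengths
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.peak_ids, columns=self.sample_ids)


def _fields(line: str, lineno: int, path: str, n_min: int) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) == 1:  # tolerate space-separated BED
        parts = line.split()
    if len(parts) < n_min:
        raise FormatError(
            f"{path}:{lineno}: expected >= {n_min} columns, got {len(parts)}"
        )
    return parts


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[GenomicInterval]:
    """Read a BED6 or ENCODE narrowPeak file into a list of intervals.

    narrowPeak column 10 (0-based offset of the summit) maps to
    ``summit_offset``; the conventional ``-1`` sentinel means "no summit".
    Peak names must be unique within the file (they are the join key for
    count matrices and classifications downstream).
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    n_min = 4 if dialect == "bed6" else 10
    out: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _fields(line, lineno, str(path), n_min)
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
            summit = None
            if dialect == "narrowPeak":
                try:
                    raw = int(parts[9])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: narrowPeak summit column not an integer"
                    ) from None
                summit = None if raw == -1 else raw
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate peak name {name!r}")
            seen.add(name)
            try:
                out.append(GenomicInterval(chrom, start, end, name, strand, summit))
            except FormatError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
    return out


def write_peaks(
    peaks: Iterable[GenomicInterval], path: str | Path, dialect: str = "narrowPeak"
) -> None:
    """Write intervals as BED6 or narrowPeak (round-trips with read_peaks)."""
    with open(path, "w") as fh:
        for p in peaks:
            base = [p.chrom, str(p.start), str(p.end), p.name, "0", p.strand]
            if dialect == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                base += ["0", "-1", "-1", str(summit)]
            fh.write("\t".join(base) + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a tab-separated sample sheet with the required metadata columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay": str, "genotype": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.df.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, sheet: SampleSheet) -> SignalMatrix:
    """Read a peak_id x sample count table (with a ``length`` column).

    Every sample column must be declared in ``sheet``; counts must be
    non-negative integers.
    """
    df = pd.read_csv(path, sep="\t")
    if "peak_id" not in df.columns or "length" not in df.columns:
        raise FormatError(f"{path}: need 'peak_id' and 'length' columns")
    sample_cols = [c for c in df.columns if c not in ("peak_id", "length")]
    unknown = set(sample_cols) - set(sheet.sample_ids)
    if unknown:
        raise FormatError(f"{path}: sample columns not in sheet: {sorted(unknown)}")
    counts = df[sample_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if np.isnan(counts.astype(float)).any() or not np.all(np.mod(counts, 1) == 0):
            raise FormatError(f"{path}: counts must be integers")
        counts = counts.astype(np.int64)
    if (counts < 0).any():
        raise FormatError(f"{path}: negative count")
    return SignalMatrix(
        list(df["peak_id"].astype(str)),
        sample_cols,
        counts,
        df["length"].to_numpy(dtype=np.int64),
    )


def write_counts(matrix: SignalMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.insert(0, "length", matrix.peak_lengths)
    df.index.name = "peak_id"
    df.to_csv(path, sep="\t")


def read_deg(
    path: str | Path, fc_thresh: float = 1.0, padj_thresh: float = 0.05
) -> pd.DataFrame:
    """Read a differential-expression table and assign up/down/unchanged status.

    ``log2fc`` is knockout relative to wild type; ``status`` is "up" if
    padj < padj_thresh and log2fc > fc_thresh, "down" if padj < padj_thresh
    and log2fc < -fc_thresh, else "unchanged".
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing DEG columns {sorted(missing)}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise FormatError(f"{path}: padj outside [0, 1]")
    return assign_deg_status(df, fc_thresh, padj_thresh)


def assign_deg_status(
    df: pd.DataFrame, fc_thresh: float = 1.0, padj_thresh: float = 0.05
) -> pd.DataFrame:
    df = df.copy()
    sig = df["padj"] < padj_thresh
    status = np.where(
        sig & (df["log2fc"] > fc_thresh),
        "up",
        np.where(sig & (df["log2fc"] < -fc_thresh), "down", "unchanged"),
    )
    df["status"] = status
    return df


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a 4-column BED-like TSS table: chrom, tss, gene_id, strand."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "tss", "gene_id", "strand"]
    )
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene_id")
    if (df["tss"] < 0).any():
        raise FormatError(f"{path}: negative TSS coordinate")
    return df[["gene_id", "chrom", "tss", "strand"]]


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["chrom", "tss", "gene_id", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_table(records: pd.DataFrame, path: str | Path, key: str | None = None) -> None:
    """Write any tabular result as TSV with header and deterministic row order.

    Rows are sorted by ``key`` (defaults to the first column) so that
    identical inputs always produce byte-identical files.
    """
    df = pd.DataFrame(records)
    if len(df):
        sort_key = key if key is not None else df.columns[0]
        df = df.sort_values(sort_key, kind="mergesort")
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())
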