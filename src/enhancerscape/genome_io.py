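"""Genomic domain types and text-format I/O.

Everything downstream speaks these types. Coordinates are 0-based
half-open (BED convention) everywhere, in memory and on disk; GTF input
is converted on read. Chromosome names are taken verbatim — no "chr"
normalisation — so a naming mismatch between input files surfaces as an
explicit validation error rather than silent zero overlap.

Formats handled: BED3/5/6, ENCODE broadPeak, bedGraph, minimal GTF
(``gene`` features only), TSV count matrix with a sample→group map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "SignalTrack",
    "GeneAnnotation",
    "CountMatrix",
    "read_intervals",
    "write_intervals",
    "read_signal",
    "write_signal",
    "read_gene_annotation",
    "read_count_matrix",
    "read_gene_sets",
]


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    """An ordered, deduplicated collection of intervals from one source."""

    intervals: list[GenomicInterval]
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        out: list[GenomicInterval] = []
        for iv in sorted(self.intervals, key=GenomicInterval.sort_key):
            key = iv.sort_key()
            if key not in seen:
                seen.add(key)
                out.append(iv)
        self.intervals = out

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})


class SignalTrack:
    """Piecewise-constant coverage: non-overlapping (start, end, value) runs.

    Values are in reads per bp (or any non-negative unit); ``total_signal``
    is sum(value * length). ``library_size`` is the total mapped-read count
    used for RPKM scaling and defaults to ``total_signal``.
    """

    def __init__(
        self,
        runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: float | None = None,
    ) -> None:
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: run with end <= start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping runs")
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValueError(f"{chrom}: values must be finite and >= 0")
            self.runs[chrom] = (starts, ends, values)
        self.total_signal = float(
            sum(
                np.sum(v * (e - s))
                for s, e, v in self.runs.values()
            )
        )
        self.library_size = (
            float(library_size) if library_size is not None else self.total_signal
        )

    def chroms(self) -> list[str]:
        return sorted(self.runs)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value x overlap length over [start, end)."""
        if chrom not in self.runs:
            return 0.0
        starts, ends, values = self.runs[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum(values[lo:hi] * np.maximum(e - s, 0)))

    def values_per_bp(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-bp values over [start, end); zero where uncovered."""
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self.runs:
            return out
        starts, ends, values = self.runs[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            out[max(s - start, 0): max(min(e, end) - start, 0)] = v
        return out


@dataclass
class GeneAnnotation:
    """Gene records with a strand-derived TSS per gene.

    TSS = start on '+' strand, end-1 on '-' strand (last covered base of
    the half-open interval).
    """

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in self.genes.columns]
        if missing:
            raise ValueError(f"annotation missing columns {missing}")
        dup = self.genes["gene_id"][self.genes["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene_id(s): {sorted(set(dup))}")
        bad_strand = set(self.genes["strand"]) - {"+", "-"}
        if bad_strand:
            raise ValueError(f"invalid strand value(s): {sorted(bad_strand)}")
        g = self.genes.copy()
        g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
        self.genes = g.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    def tss_by_chrom(self) -> dict[str, np.ndarray]:
        return {
            chrom: np.sort(sub["tss"].to_numpy())
            for chrom, sub in self.genes.groupby("chrom")
        }


@dataclass
class CountMatrix:
    """Gene-by-sample read counts plus gene lengths and group labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) non-negative ints
    gene_lengths: np.ndarray  # bp per gene
    groups: dict[str, str]  # sample_id -> {"normal", "tumor"}

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=np.float64)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with gene/sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.gene_lengths.shape != (len(self.gene_ids),):
            raise ValueError("gene_lengths inconsistent with gene_ids")
        orphans = [s for s in self.sample_ids if s not in self.groups]
        if orphans:
            raise ValueError(f"sample(s) missing from group map: {orphans}")
        bad = {g for g in self.groups.values()} - {"normal", "tumor"}
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")

    def samples_in(self, group: str) -> list[int]:
        return [
            i for i, s in enumerate(self.sample_ids) if self.groups[s] == group
        ]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split()


def read_intervals(path: str | Path, format: str = "bed") -> PeakSet:
    """Read a BED3+ or ENCODE broadPeak file into a sorted, deduped PeakSet."""
    if format not in ("bed", "broadPeak"):
        raise ValueError(f"unknown interval format {format!r}")
    min_cols = 9 if format == "broadPeak" else 3
    intervals: list[GenomicInterval] = []
    for lineno, cols in _lines(path):
        if len(cols) < min_cols:
            raise FormatError(
                f"{path}: expected >= {min_cols} columns at line {lineno}, "
                f"got {len(cols)}"
            )
        try:
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed coordinates at line {lineno}") from exc
        if start >= end:
            raise FormatError(f"{path}: start >= end at line {lineno}")
        name = cols[3] if len(cols) > 3 and cols[3] != "." else None
        score: float | None = None
        strand = "."
        if format == "broadPeak":
            # ENCODE column 7 (0-based 6) is signalValue
            score = float(cols[6])
            strand = cols[5] if cols[5] in ("+", "-") else "."
        else:
            if len(cols) > 4:
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-numeric score at line {lineno}"
                    ) from exc
            if len(cols) > 5 and cols[5] in ("+", "-"):
                strand = cols[5]
        intervals.append(
            GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
        )
    if not intervals:
        warnings.warn(f"{path}: no intervals found, returning empty PeakSet")
    return PeakSet(intervals, source_label=Path(path).stem)


def write_intervals(peaks: PeakSet, path: str | Path, format: str = "bed") -> None:
    """Write a PeakSet as sorted, tab-delimited BED (3 or 5 columns)."""
    if format != "bed":
        raise ValueError(f"unknown output format {format!r}")
    with open(path, "w") as fh:
        for iv in peaks:
            if iv.name is not None or iv.score is not None:
                name = iv.name if iv.name is not None else "."
                score = iv.score if iv.score is not None else 0.0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_signal(path: str | Path, library_size: float | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack; overlapping runs rejected."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, cols in _lines(path):
        if len(cols) < 4:
            raise FormatError(f"{path}: expected 4 columns at line {lineno}")
        try:
            chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed bedGraph line {lineno}") from exc
        if value < 0:
            raise FormatError(f"{path}: negative value at line {lineno}")
        if start >= end:
            raise FormatError(f"{path}: start >= end at line {lineno}")
        per_chrom.setdefault(chrom, []).append((start, end, value))
    runs = {}
    for chrom, triples in per_chrom.items():
        arr = np.array(triples, dtype=np.float64)
        runs[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return SignalTrack(runs, library_size=library_size)


def write_signal(track: SignalTrack, path: str | Path) -> None:
    """Write a SignalTrack as bedGraph (zero-value runs included)."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_gene_annotation(path: str | Path, format: str = "bed6") -> GeneAnnotation:
    """Read gene records from BED6 or a minimal GTF (``gene`` features only).

    GTF 1-based starts are converted to 0-based on read.
    """
    records: list[dict] = []
    if format == "bed6":
        for lineno, cols in _lines(path):
            if len(cols) < 6:
                raise FormatError(
                    f"{path}: BED6 requires 6 columns (strand present) at line {lineno}"
                )
            if cols[5] not in ("+", "-"):
                raise FormatError(f"{path}: missing/invalid strand at line {lineno}")
            records.append(
                dict(
                    gene_id=cols[3],
                    chrom=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=cols[5],
                )
            )
    elif format == "gtf":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    raise FormatError(f"{path}: expected 9 GTF columns at line {lineno}")
                if cols[2] != "gene":
                    continue
                if cols[6] not in ("+", "-"):
                    raise FormatError(f"{path}: missing strand at line {lineno}")
                attrs = dict(
                    (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                    for kv in cols[8].rstrip(";").split(";")
                    if kv.strip()
                )
                if "gene_id" not in attrs:
                    raise FormatError(f"{path}: gene feature without gene_id at line {lineno}")
                records.append(
                    dict(
                        gene_id=attrs["gene_id"],
                        chrom=cols[0],
                        start=int(cols[3]) - 1,  # GTF is 1-based inclusive
                        end=int(cols[4]),
                        strand=cols[6],
                    )
                )
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not records:
        raise FormatError(f"{path}: no gene records found")
    return GeneAnnotation(pd.DataFrame.from_records(records))


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in ann.genes.itertuples():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


def read_count_matrix(
    path: str | Path,
    group_map: Mapping[str, str] | str | Path,
    gene_lengths: Mapping[str, float] | None = None,
    lengths_column: str = "length",
) -> CountMatrix:
    """Read a TSV count matrix (first column gene ids, header sample ids).

    ``group_map`` is either a {sample: group} mapping or a path to a
    two-column TSV. Gene lengths come from a ``length`` column in the
    matrix or from an explicit mapping.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if isinstance(group_map, (str, Path)):
        gm_df = pd.read_csv(group_map, sep="\t", header=None, names=["sample", "group"])
        group_map = dict(zip(gm_df["sample"], gm_df["group"]))
    group_map = dict(group_map)

    if lengths_column in df.columns:
        lengths = df[lengths_column].to_numpy(dtype=np.float64)
        df = df.drop(columns=[lengths_column])
    elif gene_lengths is not None:
        missing = [g for g in df.index if g not in gene_lengths]
        if missing:
            raise ValueError(f"gene(s) missing from length map: {missing[:5]}")
        lengths = np.array([gene_lengths[g] for g in df.index], dtype=np.float64)
    else:
        raise ValueError("no gene lengths: need a 'length' column or a length map")

    for col in df.columns:
        vals = df[col]
        if not np.all(vals == np.floor(vals)):
            bad = df.index[vals != np.floor(vals)][0]
            raise ValueError(f"non-integer count for gene {bad!r} in sample {col!r}")
    orphans = [s for s in df.columns if s not in group_map]
    if orphans:
        raise ValueError(f"sample(s) missing from group map: {orphans}")
    return CountMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        counts=df.to_numpy(dtype=np.int64),
        gene_lengths=lengths,
        groups={s: group_map[s] for s in df.columns},
    )


def read_gene_sets(paths: Iterable[str | Path]) -> dict[str, set[str]]:
    """Read gene-set files: one gene_id per line, '#' comments allowed."""
    out: dict[str, set[str]] = {}
    for path in paths:
        genes: set[str] = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    genes.add(line)
        out[Path(path).stem] = genes
    return out


def check_shared_chromosomes(
    a: Sequence[str], b: Sequence[str], what: str = "inputs"
) -> None:
    """Fail loudly when two inputs share no chromosome names."""
    if set(a) and set(b) and not (set(a) & set(b)):
        raise ValueError(
            f"no shared chromosome names between {what}: {sorted(set(a))[:3]} vs "
            f"{sorted(set(b))[:3]} — check naming conventions"
        )
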