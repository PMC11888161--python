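"""Genomic interval containers, readers, and exact interval algebra.

Coordinates are 0-based half-open (BED convention) everywhere. The UCSC
RepeatMasker table dump already uses 0-based ``genoStart`` so no shift is
applied on read. Strand is ignored throughout: the overlap statistic the
pipeline computes is strandless.

Overlap is defined on coverage unions: both sets are merged before
intersection, so the statistic is invariant to within-set redundancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "Interval",
    "IntervalSet",
    "AnnotationCatalog",
    "read_chrom_sizes",
    "read_intervals",
    "read_rmsk_catalog",
    "read_peak_directory",
    "write_bed",
    "merge_intervals",
    "total_bp",
    "overlap_bp",
]


class Interval(NamedTuple):
    """A strandless genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with lengths; the shuffling universe.

    Order is preserved as read: output tables report chromosomes in this
    order. Names must be unique and lengths strictly positive.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome layout")
        for name, length in self.entries:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes.items()))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.entries]

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.entries)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.entries)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def length_of(self, chrom: str) -> int:
        return self.sizes[chrom]


@dataclass
class IntervalSet:
    """A named bag of intervals; may contain overlaps and duplicates.

    Raw input is deliberately not merged on read — ``merge_intervals``
    canonicalizes when union semantics are needed.
    """

    intervals: list[Interval] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def validate(self, genome: GenomeLayout) -> None:
        """Raise ValueError on the first interval not fitting the layout."""
        sizes = genome.sizes
        for iv in self.intervals:
            if iv.chrom not in sizes:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if not (0 <= iv.start < iv.end <= sizes[iv.chrom]):
                raise ValueError(f"interval {iv} out of bounds for {iv.chrom} (len {sizes[iv.chrom]})")

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Group into per-chromosome (n, 2) int64 arrays of [start, end)."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


@dataclass
class AnnotationCatalog:
    """Named annotation families (repeat classes or peak tracks)."""

    families: dict[str, IntervalSet]
    source_kind: str = "rmsk_class"  # rmsk_class | rmsk_family | peak_file_directory

    def __len__(self) -> int:
        return len(self.families)

    def validate(self, genome: GenomeLayout) -> None:
        for fam in self.families.values():
            fam.validate(genome)


# ---------------------------------------------------------------------------
# readers / writers


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column chrom.sizes table (name, length)."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from exc
            entries.append((parts[0], length))
    return GenomeLayout(tuple(entries))


def _parse_bed_line(parts: list[str], lineno: int, path: str, min_cols: int) -> Interval:
    if len(parts) < min_cols:
        raise ValueError(f"{path}:{lineno}: expected >= {min_cols} columns, got {len(parts)}")
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinate in {parts[1:3]}") from exc
    if start < 0 or start >= end:
        raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
    label = parts[3] if len(parts) > 3 else None
    return Interval(parts[0], start, end, label)


def read_intervals(path: str | Path, dialect: str = "bed", genome: GenomeLayout | None = None) -> IntervalSet:
    """Read a BED3+ or ENCODE narrowPeak file into an IntervalSet.

    Only chrom/start/end drive the overlap statistic; column 4 (if present)
    is kept as the interval label. Intervals on chromosomes absent from
    ``genome`` are dropped with a logged count so a catalog built on a full
    genome can be used with a subset layout.
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    min_cols = 10 if dialect == "narrowPeak" else 3
    intervals: list[Interval] = []
    dropped = 0
    sizes = genome.sizes if genome is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line.split("\t"), lineno, str(path), min_cols)
            if sizes is not None and iv.chrom not in sizes:
                dropped += 1
                continue
            intervals.append(iv)
    if dropped:
        log.warning("%s: dropped %d interval(s) on chromosomes absent from layout", path, dropped)
    return IntervalSet(intervals, name=Path(path).stem)


_RMSK_REQUIRED = ("genoName", "genoStart", "genoEnd", "repClass", "repFamily")


def read_rmsk_catalog(path: str | Path, group_by: str = "repClass", genome: GenomeLayout | None = None) -> AnnotationCatalog:
    """Read a UCSC RepeatMasker table dump, grouped into families.

    The dump is tab-separated with named columns (header line may start with
    '#'). ``genoStart`` is already 0-based. One catalog family is built per
    distinct value of ``group_by`` (repClass or repFamily).
    """
    if group_by not in ("repClass", "repFamily"):
        raise ValueError(f"group_by must be repClass or repFamily, got {group_by!r}")
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.lstrip("#").split("\t")
        missing = [c for c in _RMSK_REQUIRED if c not in header]
        if missing:
            raise ValueError(f"{path}: rmsk table missing column(s) {missing}; found {header}")
        col = {name: i for i, name in enumerate(header)}
        families: dict[str, list[Interval]] = {}
        dropped = 0
        sizes = genome.sizes if genome is not None else None
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            chrom = parts[col["genoName"]]
            try:
                start = int(parts[col["genoStart"]])
                end = int(parts[col["genoEnd"]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if sizes is not None and chrom not in sizes:
                dropped += 1
                continue
            fam = parts[col[group_by]]
            families.setdefault(fam, []).append(Interval(chrom, start, end, parts[col["repFamily"]]))
    if dropped:
        log.warning("%s: dropped %d repeat row(s) on chromosomes absent from layout", path, dropped)
    kind = "rmsk_class" if group_by == "repClass" else "rmsk_family"
    return AnnotationCatalog({k: IntervalSet(v, name=k) for k, v in families.items()}, source_kind=kind)


def read_peak_directory(directory: str | Path, dialect: str = "narrowPeak", genome: GenomeLayout | None = None) -> AnnotationCatalog:
    """Treat each peak file in a directory as one catalog family (file stem = name)."""
    directory = Path(directory)
    exts = {".narrowPeak", ".bed"}
    files = sorted(p for p in directory.iterdir() if p.suffix in exts)
    if not files:
        raise ValueError(f"{directory}: no .bed/.narrowPeak files found")
    families = {p.stem: read_intervals(p, dialect=dialect if p.suffix == ".narrowPeak" else "bed", genome=genome) for p in files}
    return AnnotationCatalog(families, source_kind="peak_file_directory")


def write_bed(s: IntervalSet, path: str | Path) -> None:
    """Write chrom/start/end (+ label if present) as BED."""
    with open(path, "w") as fh:
        for iv in s.intervals:
            if iv.label is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# interval algebra


def _merge_arrays(arr: np.ndarray) -> np.ndarray:
    """Merge an (n, 2) array into sorted, disjoint, non-bookended intervals."""
    if arr.shape[0] == 0:
        return arr.reshape(0, 2)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    run_end = np.maximum.accumulate(arr[:, 1])
    # a new run starts where the start exceeds the running max end so far
    new_run = np.empty(arr.shape[0], dtype=bool)
    new_run[0] = True
    new_run[1:] = arr[1:, 0] > run_end[:-1]
    starts = arr[new_run, 0]
    idx = np.flatnonzero(new_run)
    ends = np.empty_like(starts)
    ends[:-1] = run_end[idx[1:] - 1]
    ends[-1] = run_end[-1]
    return np.column_stack([starts, ends])


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Canonicalize to sorted, pairwise-disjoint, non-bookended intervals.

    Bookended intervals ([0,10) + [10,20)) are merged: half-open adjacency is
    treated as contiguous coverage. Coverage union is preserved exactly and
    the operation is idempotent. Labels are dropped.
    """
    merged: list[Interval] = []
    for chrom, arr in s.by_chrom().items():
        for start, end in _merge_arrays(arr):
            merged.append(Interval(chrom, int(start), int(end)))
    merged.sort(key=lambda iv: (iv.chrom, iv.start))
    return IntervalSet(merged, name=s.name)


def total_bp(s: IntervalSet) -> int:
    """Base pairs of the coverage union of the set."""
    bp = 0
    for arr in s.by_chrom().values():
        m = _merge_arrays(arr)
        bp += int((m[:, 1] - m[:, 0]).sum())
    return bp


def _intersect_merged(a: np.ndarray, b: np.ndarray) -> int:
    """Total intersection bp of two merged (disjoint, sorted) interval arrays."""
    if a.shape[0] == 0 or b.shape[0] == 0:
        return 0
    # event sweep: depth 2 regions are in both unions (each set has depth <= 1)
    pos = np.concatenate([a[:, 0], a[:, 1], b[:, 0], b[:, 1]])
    delta = np.concatenate(
        [
            np.ones(a.shape[0], dtype=np.int64),
            -np.ones(a.shape[0], dtype=np.int64),
            np.ones(b.shape[0], dtype=np.int64),
            -np.ones(b.shape[0], dtype=np.int64),
        ]
    )
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], delta[order]
    depth = np.cumsum(delta)
    spans = np.diff(pos)
    return int(spans[depth[:-1] == 2].sum())


def overlap_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Base pairs of intersection of the coverage unions |union(a) ∩ union(b)|.

    Symmetric; overlap_bp(a, a) == total_bp(a); bounded above by the smaller
    coverage. This is the enrichment test statistic of the shuffle pipeline.
    """
    a_chrom = a.by_chrom()
    b_chrom = b.by_chrom()
    bp = 0
    for chrom in a_chrom.keys() & b_chrom.keys():
        bp += _intersect_merged(_merge_arrays(a_chrom[chrom]), _merge_arrays(b_chrom[chrom]))
    return bp
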