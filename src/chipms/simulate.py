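"""Synthetic genomes, repeat catalogs, peak sets, and intensity matrices.

Everything the pipeline consumes can be generated with known ground truth:

- a genome whose "Satellite" family is a small number of long arrays
  clustered around one per-chromosome centromere locus, with "LINE"
  elements dispersed uniformly — the qualitative geometry of pericentromeric
  satellite DNA versus interspersed retrotransposons (no sequence content);
- peak sets whose placement is biased toward a chosen family by a known
  factor rho (rho = 1 is exactly uniform);
- log2 intensity matrices with planted group effects and intensity-dependent
  (MNAR, logistic) missingness, the regime that down-shifted Gaussian
  imputation presumes.

All generators are pure functions of their spec (seed included): the same
spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationCatalog,
    GenomeLayout,
    Interval,
    IntervalSet,
    merge_intervals,
)
from .ipms import IntensityMatrix

__all__ = [
    "GenomeSimSpec",
    "PeakSimSpec",
    "ProteomicsSimSpec",
    "simulate_genome_and_repeats",
    "simulate_peaks",
    "simulate_intensity_matrix",
    "write_rmsk_table",
    "write_chrom_sizes",
    "write_narrowpeak",
    "write_intensity_tsv",
    "write_group_map",
]


@dataclass(frozen=True)
class GenomeSimSpec:
    """Study-condition genome: 1 Mb chromosome, 5% clustered satellite,
    100 dispersed LINEs of 0.5-6 kb."""

    n_chromosomes: int = 1
    chromosome_lengths: tuple[int, ...] = (1_000_000,)
    satellite_fraction: float = 0.05
    satellite_array_count: int = 5
    line_count: int = 100
    line_length_range: tuple[int, int] = (500, 6000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.satellite_fraction < 1):
            raise ValueError("satellite_fraction must lie in [0, 1)")
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must have n_chromosomes entries")
        lo, hi = self.line_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid line_length_range")


@dataclass(frozen=True)
class PeakSimSpec:
    """Peak set with optional placement bias rho toward one family."""

    n_peaks: int = 200
    peak_length: int = 200
    bias_family: str | None = None
    bias_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_factor < 1.0:
            raise ValueError("bias_factor rho must be >= 1 (rho = 1 means uniform)")
        if self.peak_length <= 0 or self.n_peaks < 0:
            raise ValueError("invalid peak spec")


@dataclass(frozen=True)
class ProteomicsSimSpec:
    """Planted-truth IP-MS matrix: baseline log2 intensities, group effect on
    the first n_hits proteins, and logistic-in-intensity (MNAR) missingness.

    slope <= 0 so lower intensity means higher dropout probability; the
    default intercept/slope give roughly 10% missing cells at the default
    baseline. slope = 0 with a very negative intercept recovers a complete
    matrix (MCAR switch: set slope = 0 and choose the intercept for the
    desired flat rate).
    """

    n_proteins: int = 500
    n_hits: int = 50
    effect_log2fc: float = 3.0
    within_group_sd: float = 0.5
    group_sizes: tuple[int, int] = (3, 3)
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    missing_intercept: float = 16.5
    missing_slope: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hits > self.n_proteins:
            raise ValueError("n_hits must be <= n_proteins")
        if self.missing_slope > 0:
            raise ValueError("missing_slope must be <= 0 (MNAR: lower intensity, more missing)")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs >= 2 samples")


def simulate_genome_and_repeats(spec: GenomeSimSpec) -> tuple[GenomeLayout, AnnotationCatalog]:
    """Generate the genome layout plus a {"Satellite", "LINE"} catalog.

    Per chromosome the satellite budget (satellite_fraction * length,
    exactly) is split across satellite_array_count arrays laid out
    consecutively around a mid-chromosome centromere coordinate with small
    random gaps; LINEs are placed uniformly (overlaps allowed).
    """
    rng = np.random.default_rng(spec.seed)
    entries = tuple((f"chr{i + 1}", int(L)) for i, L in enumerate(spec.chromosome_lengths))
    genome = GenomeLayout(entries)
    satellites: list[Interval] = []
    lines: list[Interval] = []
    for chrom, L in entries:
        sat_total = int(round(spec.satellite_fraction * L))
        k = spec.satellite_array_count
        if sat_total > 0 and k > 0:
            # split the budget into k blocks (roughly equal, jittered)
            weights = rng.dirichlet(np.full(k, 20.0))
            sizes = np.maximum(1, np.round(weights * sat_total).astype(int))
            sizes[-1] += sat_total - int(sizes.sum())  # keep the total exact
            sizes = sizes[sizes > 0]
            gaps = rng.integers(0, max(2, sat_total // (10 * k)), size=sizes.size)
            span = int(sizes.sum() + gaps[:-1].sum()) if sizes.size else 0
            centro = int(rng.integers(int(0.4 * L), int(0.6 * L) + 1))
            left = min(max(0, centro - span // 2), max(0, L - span))
            pos = left
            for i, size in enumerate(sizes.tolist()):
                satellites.append(Interval(chrom, pos, pos + size, "Satellite"))
                pos += size
                if i < sizes.size - 1:
                    pos += int(gaps[i])
        if spec.line_count > 0:
            lo, hi = spec.line_length_range
            lens = rng.integers(lo, hi + 1, size=spec.line_count)
            lens = np.minimum(lens, L)
            starts = rng.integers(0, L - lens + 1)
            for st, ln in zip(starts.tolist(), lens.tolist()):
                lines.append(Interval(chrom, st, st + ln, "LINE"))
    catalog = AnnotationCatalog(
        {
            "Satellite": IntervalSet(satellites, name="Satellite"),
            "LINE": IntervalSet(lines, name="LINE"),
        },
        source_kind="rmsk_class",
    )
    return genome, catalog


def _genome_offsets(genome: GenomeLayout) -> tuple[list[str], np.ndarray]:
    names = genome.names
    lengths = np.array([genome.length_of(c) for c in names], dtype=np.int64)
    return names, np.concatenate([[0], np.cumsum(lengths)])


def simulate_peaks(genome: GenomeLayout, catalog: AnnotationCatalog, spec: PeakSimSpec) -> IntervalSet:
    """Place peaks with midpoint density proportional to rho inside the bias
    family's coverage and 1 outside, then extend to peak_length and clip.

    With rho = 1 the mixture collapses exactly to a uniform midpoint on the
    genome. Midpoints are sampled exactly (no rejection): inside-coverage
    and outside-coverage positions are each drawn uniformly via cumulative
    base counts, with the component chosen by its total weight.
    """
    if spec.n_peaks == 0:
        return IntervalSet([], name="peaks")
    names, offsets = _genome_offsets(genome)
    G = int(offsets[-1])
    if all(spec.peak_length > genome.length_of(c) for c in names):
        raise ValueError(f"peak_length {spec.peak_length} exceeds every chromosome")
    rng = np.random.default_rng(spec.seed)

    # genome-linear coordinates of the bias-family coverage
    cov_segments = np.empty((0, 2), dtype=np.int64)
    if spec.bias_family is not None:
        if spec.bias_family not in catalog.families:
            raise ValueError(f"bias family {spec.bias_family!r} not in catalog")
        merged = merge_intervals(catalog.families[spec.bias_family])
        segs = []
        for iv in merged:
            off = int(offsets[names.index(iv.chrom)])
            segs.append((off + iv.start, off + iv.end))
        if segs:
            cov_segments = np.asarray(sorted(segs), dtype=np.int64)

    F = int((cov_segments[:, 1] - cov_segments[:, 0]).sum()) if cov_segments.size else 0
    rho = spec.bias_factor
    w_in = rho * F
    w_out = float(G - F)
    p_in = w_in / (w_in + w_out) if (w_in + w_out) > 0 else 0.0

    inside = rng.random(spec.n_peaks) < p_in
    mids = np.empty(spec.n_peaks, dtype=np.int64)

    def _sample_from_segments(segments: np.ndarray, count: int) -> np.ndarray:
        lengths = segments[:, 1] - segments[:, 0]
        cum = np.concatenate([[0], np.cumsum(lengths)])
        u = rng.integers(0, cum[-1], size=count)
        idx = np.searchsorted(cum, u, side="right") - 1
        return segments[idx, 0] + (u - cum[idx])

    n_in = int(inside.sum())
    if n_in:
        mids[inside] = _sample_from_segments(cov_segments, n_in)
    n_out = spec.n_peaks - n_in
    if n_out:
        if cov_segments.size:
            # complement of coverage in genome-linear space
            bounds = np.concatenate([[0], cov_segments.ravel(), [G]])
            comp = bounds.reshape(-1, 2)
            comp = comp[comp[:, 1] > comp[:, 0]]
        else:
            comp = np.array([[0, G]], dtype=np.int64)
        mids[~inside] = _sample_from_segments(comp, n_out)

    # map linear midpoints back to (chrom, start) and clip the peak in-bounds
    peaks: list[Interval] = []
    half = spec.peak_length // 2
    chrom_idx = np.searchsorted(offsets, mids, side="right") - 1
    for mid, ci in zip(mids.tolist(), chrom_idx.tolist()):
        chrom = names[ci]
        L = genome.length_of(chrom)
        if spec.peak_length > L:
            continue
        start = min(max(0, mid - int(offsets[ci]) - half), L - spec.peak_length)
        peaks.append(Interval(chrom, start, start + spec.peak_length))
    return IntervalSet(peaks, name="peaks")


def simulate_intensity_matrix(spec: ProteomicsSimSpec) -> tuple[IntensityMatrix, np.ndarray]:
    """Generate a planted-truth log2 intensity matrix.

    Returns the matrix (NaN where missing) and the boolean ground-truth hit
    labels (the first n_hits proteins carry +effect_log2fc in the treatment
    group). Each cell goes missing independently with probability
    sigmoid(intercept + slope * value).
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.group_sizes
    n = spec.n_proteins
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[: spec.n_hits] = True
    means = np.tile(baseline[:, None], (1, n1 + n2))
    means[is_hit, :n1] += spec.effect_log2fc
    values = means + rng.normal(0.0, spec.within_group_sd, size=means.shape)
    p_missing = 1.0 / (1.0 + np.exp(-(spec.missing_intercept + spec.missing_slope * values)))
    missing = rng.random(values.shape) < p_missing
    values_masked = values.copy()
    values_masked[missing] = np.nan
    samples = [f"treat_{i + 1}" for i in range(n1)] + [f"ctrl_{i + 1}" for i in range(n2)]
    groups = {s: ("treatment" if s.startswith("treat") else "control") for s in samples}
    proteins = [f"P{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(values_masked, index=pd.Index(proteins, name="protein"), columns=samples)
    return IntensityMatrix(values=df, groups=groups), is_hit


# ---------------------------------------------------------------------------
# fixture writers: emit the same standard formats the readers consume


def write_chrom_sizes(genome: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.entries:
            fh.write(f"{chrom}\t{length}\n")


def write_rmsk_table(catalog: AnnotationCatalog, path: str | Path) -> None:
    """Write the catalog as a UCSC-style rmsk dump (family name -> repClass)."""
    with open(path, "w") as fh:
        fh.write("#genoName\tgenoStart\tgenoEnd\trepName\trepClass\trepFamily\n")
        for fam, ivset in catalog.families.items():
            for i, iv in enumerate(ivset):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fam}_{i}\t{fam}\t{fam}\n")


def write_narrowpeak(s: IntervalSet, path: str | Path) -> None:
    """Write a 10-column ENCODE narrowPeak file (neutral stats columns)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(s):
            summit = (iv.end - iv.start) // 2
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t0\t.\t0\t-1\t-1\t{summit}\n")


def write_intensity_tsv(m: IntensityMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", na_rep="")


def write_group_map(m: IntensityMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample in m.values.columns:
            fh.write(f"{sample}\t{m.groups[sample]}\n")
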