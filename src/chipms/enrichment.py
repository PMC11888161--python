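"""Chromosome-stratified shuffling null and the enrichment z-score.

The null model relocates every annotation element to a uniformly random
position on its own chromosome, independently of all other elements
(shuffled elements may overlap one another). The test statistic is the
base-pair overlap between the (union of the) relocated annotation set and
the fixed query peak set. Repeating the shuffle ``n_shuffles`` times gives a
null distribution; the enrichment z-score is

    z = (observed_bp - null_mean) / null_sd

with null_mean/null_sd the sample mean and sample standard deviation
(denominator n-1) over replicates.

Seeding contract: a master seed plus a deterministic substream per
(family name, replicate index), so batched results do not depend on the
order in which families are processed.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomeLayout, Interval, IntervalSet, merge_intervals, overlap_bp, total_bp

log = logging.getLogger(__name__)

__all__ = [
    "ShuffleParams",
    "EnrichmentResult",
    "shuffle_set",
    "null_overlap_distribution",
    "compute_enrichment",
    "family_seed_sequence",
]

DEFAULT_N_SHUFFLES = 20  # replicate count used to estimate the null


@dataclass(frozen=True)
class ShuffleParams:
    """Parameters of the shuffling null.

    n_shuffles defaults to 20; at least 2 replicates are required so a
    standard deviation is estimable. For a stable null sd, >= 100 replicates
    are recommended (the calibration tests use >= 100).
    """

    n_shuffles: int = DEFAULT_N_SHUFFLES
    seed: int = 0
    oversize_policy: str = "skip_with_warning"  # or "error"

    def __post_init__(self) -> None:
        if self.n_shuffles < 2:
            raise ValueError("n_shuffles must be >= 2 (a standard deviation must be estimable)")
        if self.oversize_policy not in ("skip_with_warning", "error"):
            raise ValueError(f"unknown oversize_policy {self.oversize_policy!r}")


@dataclass
class EnrichmentResult:
    """One family's observed overlap, null moments, and z-score.

    ``z`` is NaN when the null is degenerate (sd == 0 with observed != mean);
    when sd == 0 and observed == mean, z is exactly 0 and ``degenerate``
    stays False (a constant statistic is not an error).
    """

    family_name: str
    observed_bp: int
    null_mean: float
    null_sd: float
    z: float
    n_shuffles: int
    seed: int
    degenerate: bool
    n_elements: int
    total_annotation_bp: int


def family_seed_sequence(master_seed: int, family_name: str) -> np.random.SeedSequence:
    """Derive a family's seed substream from the master seed and its name.

    The name is hashed (sha256) so the substream does not depend on family
    iteration order or on the presence of other families.
    """
    digest = hashlib.sha256(family_name.encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *words])


def shuffle_set(
    s: IntervalSet,
    genome: GenomeLayout,
    rng: np.random.Generator,
    oversize_policy: str = "skip_with_warning",
) -> IntervalSet:
    """Relocate every element uniformly on its own chromosome.

    Chromosome and length are preserved per element; the new start is drawn
    uniformly from the integers [0, L - len] so every placement lies wholly
    inside the chromosome. Elements are placed independently — outputs may
    overlap. Elements longer than their chromosome are skipped with a
    warning or raise, per ``oversize_policy``.
    """
    sizes = genome.sizes
    out: list[Interval] = []
    # group per chromosome to vectorize the uniform draws
    per_chrom: dict[str, list[int]] = {}
    for iv in s.intervals:
        per_chrom.setdefault(iv.chrom, []).append(iv.length)
    for chrom, lengths_list in per_chrom.items():
        L = sizes[chrom]
        lengths = np.asarray(lengths_list, dtype=np.int64)
        oversize = lengths > L
        if oversize.any():
            bad = int(lengths[oversize][0])
            if oversize_policy == "error":
                raise ValueError(f"element of length {bad} exceeds chromosome {chrom} (length {L})")
            log.warning("skipping %d element(s) longer than chromosome %s", int(oversize.sum()), chrom)
            lengths = lengths[~oversize]
        if lengths.size == 0:
            continue
        starts = rng.integers(0, L - lengths + 1)
        for st, ln in zip(starts.tolist(), lengths.tolist()):
            out.append(Interval(chrom, st, st + ln))
    return IntervalSet(out, name=s.name)


def null_overlap_distribution(
    annotation: IntervalSet,
    peaks: IntervalSet,
    genome: GenomeLayout,
    params: ShuffleParams,
    seed_sequence: np.random.SeedSequence | None = None,
) -> list[int]:
    """Overlap statistic under ``n_shuffles`` independent relocations.

    Bit-reproducible for a fixed seed: replicate i consumes the i-th child
    of the seed sequence regardless of how many replicates are requested.
    """
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(int(params.seed) & 0xFFFFFFFF)
    peaks_merged = merge_intervals(peaks)
    children = seed_sequence.spawn(params.n_shuffles)
    dist: list[int] = []
    for child in children:
        rng = np.random.Generator(np.random.PCG64(child))
        shuffled = shuffle_set(annotation, genome, rng, oversize_policy=params.oversize_policy)
        dist.append(overlap_bp(shuffled, peaks_merged))
    return dist


def compute_enrichment(
    annotation: IntervalSet,
    peaks: IntervalSet,
    genome: GenomeLayout,
    params: ShuffleParams,
    family_name: str | None = None,
    seed_sequence: np.random.SeedSequence | None = None,
) -> EnrichmentResult:
    """Observed overlap, shuffle null moments, and enrichment z for one family.

    A degenerate null (sd == 0 with observed != mean) is reported with
    ``degenerate=True`` and z = NaN plus a logged warning — never a silent
    infinity.
    """
    name = family_name if family_name is not None else annotation.name
    observed = overlap_bp(annotation, peaks)
    dist = np.asarray(
        null_overlap_distribution(annotation, peaks, genome, params, seed_sequence=seed_sequence),
        dtype=float,
    )
    null_mean = float(dist.mean())
    null_sd = float(dist.std(ddof=1))
    degenerate = False
    if null_sd == 0.0:
        if observed == null_mean:
            z = 0.0
        else:
            z = math.nan
            degenerate = True
            log.warning("degenerate null for family %r: sd=0, observed=%d != mean=%g", name, observed, null_mean)
    else:
        z = (observed - null_mean) / null_sd
    return EnrichmentResult(
        family_name=name,
        observed_bp=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        n_shuffles=params.n_shuffles,
        seed=params.seed,
        degenerate=degenerate,
        n_elements=len(annotation),
        total_annotation_bp=total_bp(annotation),
    )
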