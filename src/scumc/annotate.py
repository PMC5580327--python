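"""Feature-level statistics: overlap fractions, shuffle-based enrichment,
CpG density, TSS distance, aggregate signal profiles, and cell-group
specific scUMC labelling.
"""
from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .core import GenomicRegion, Methylome, RegionIndex


def _as_point_map(
    points: Mapping[str, np.ndarray] | Sequence[tuple[str, int]],
) -> dict[str, np.ndarray]:
    """Normalize points to chrom -> sorted int64 array."""
    if isinstance(points, Mapping):
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in points.items()}
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in points:
        by_chrom.setdefault(chrom, []).append(int(pos))
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}


def overlap_fraction(
    features: Sequence[GenomicRegion], annotation: Sequence[GenomicRegion]
) -> tuple[float, int, int]:
    """Fraction of features overlapping >= 1 annotation interval by >= 1 bp.

    Returns ``(fraction, n_overlapping, n_features)``.
    """
    if not features:
        raise ValueError("empty feature set")
    index = RegionIndex(annotation)
    n_hit = 0
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom, regs in by_chrom.items():
        starts = np.array([r.start for r in regs])
        ends = np.array([r.end for r in regs])
        n_hit += int(index.overlaps_many(chrom, starts, ends).sum())
    return n_hit / len(features), n_hit, len(features)


@dataclass
class EnrichmentResult:
    """Observed-vs-expected overlap of a feature set with an annotation."""

    feature_set: str
    annotation: str
    n_features: int
    n_overlapping: int
    overlap_fraction: float
    expected_overlap: float
    log2_obs_exp: float  # NaN when expected overlap is zero across shuffles
    n_shuffles: int
    seed: int


def enrichment(
    features: Sequence[GenomicRegion],
    annotation: Sequence[GenomicRegion],
    chrom_sizes: Mapping[str, int],
    n_shuffles: int = 100,
    seed: int = 0,
    feature_set: str = "features",
    annotation_name: str = "annotation",
) -> EnrichmentResult:
    """Overlap enrichment against a uniform length-preserving null.

    The expected overlap count is the mean, over ``n_shuffles`` seeded
    shuffles, of the number of features overlapping the annotation after
    each feature is placed uniformly at random within its own chromosome
    (length preserved). ``log2_obs_exp = log2(observed / expected)``; when
    no shuffle produces any overlap the ratio is undefined and reported as
    NaN.
    """
    if not features:
        raise ValueError("empty feature set")
    for f in features:
        if f.chrom not in chrom_sizes:
            raise ValueError(f"chromosome {f.chrom} missing from chrom_sizes")
        if len(f) > chrom_sizes[f.chrom]:
            raise ValueError(
                f"feature {f.chrom}:{f.start}-{f.end} longer than its chromosome"
            )
    index = RegionIndex(annotation)
    frac, n_hit, n_feat = overlap_fraction(features, annotation)
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, np.ndarray] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(len(f))  # type: ignore[attr-defined]
    by_chrom = {c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()}
    null_counts = np.zeros(n_shuffles)
    for s in range(n_shuffles):
        count = 0
        for chrom, lengths in sorted(by_chrom.items()):
            high = chrom_sizes[chrom] - lengths + 1
            starts = rng.integers(0, high)
            count += int(index.overlaps_many(chrom, starts, starts + lengths).sum())
        null_counts[s] = count
    expected = float(null_counts.mean())
    log2 = math.log2(n_hit / expected) if expected > 0 and n_hit > 0 else math.nan
    return EnrichmentResult(
        feature_set=feature_set,
        annotation=annotation_name,
        n_features=n_feat,
        n_overlapping=n_hit,
        overlap_fraction=frac,
        expected_overlap=expected,
        log2_obs_exp=log2,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def cpg_density(
    regions: Sequence[GenomicRegion],
    cpg_map: Mapping[str, np.ndarray] | Sequence[tuple[str, int]],
) -> np.ndarray:
    """CpG count per region normalized to 100 bp.

    A CpG at position p belongs to a region iff p is in [start, end).
    """
    pts = _as_point_map(cpg_map)
    out = np.zeros(len(regions))
    for i, r in enumerate(regions):
        pos = pts.get(r.chrom)
        if pos is None:
            continue
        n = np.searchsorted(pos, r.end, side="left") - np.searchsorted(
            pos, r.start, side="left"
        )
        out[i] = n * 100.0 / len(r)
    return out


def tss_distance(
    features: Sequence[GenomicRegion],
    tss: Mapping[str, np.ndarray] | Sequence[tuple[str, int]],
    distal_cutoff: float = 3000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance (bp) from each feature midpoint to its nearest TSS.

    Ties between equidistant TSSs resolve toward the smaller coordinate
    (the reported distance is the same either way). A feature is distal
    iff its distance is strictly greater than ``distal_cutoff`` (default
    +/- 3 kb). Features on chromosomes with no TSS get distance inf.

    Returns ``(distances, is_distal)``.
    """
    pts = _as_point_map(tss)
    if not any(v.size for v in pts.values()):
        raise ValueError("empty TSS set")
    dist = np.full(len(features), np.inf)
    for i, f in enumerate(features):
        pos = pts.get(f.chrom)
        if pos is None or pos.size == 0:
            continue
        mid = (f.start + f.end) / 2.0
        j = np.searchsorted(pos, mid)
        best = np.inf
        if j > 0:
            best = mid - pos[j - 1]  # left neighbour first: ties go left
        if j < pos.size and pos[j] - mid < best:
            best = pos[j] - mid
        dist[i] = best
    return dist, dist > distal_cutoff


@dataclass
class ProfileMatrix:
    """Aggregate signal profile around feature midpoints.

    ``offsets`` are bin-center offsets (bp) symmetric about 0;
    ``mean_signal`` is the across-feature mean of per-feature in-bin means
    (NaN where no feature contributes data).
    """

    offsets: np.ndarray
    mean_signal: np.ndarray
    half_width: int
    bin_size: int
    n_features: int


def profile(
    features: Sequence[GenomicRegion],
    signal: Methylome | Mapping[str, tuple[np.ndarray, np.ndarray]],
    half_width: int = 2500,
    bin_size: int = 50,
) -> ProfileMatrix:
    """Mean signal in fixed-width bins centered on feature midpoints.

    ``signal`` is a :class:`~scumc.core.Methylome` (methylation ratios at
    CpG positions) or a mapping chrom -> (positions, values) for an
    arbitrary base-resolution track. Each feature contributes the mean
    signal of its covered positions per bin; bins with no data anywhere
    are NaN, never zero.
    """
    if not features:
        raise ValueError("empty feature set")
    if isinstance(signal, Methylome):
        track = {
            str(chrom): (
                sub["pos"].to_numpy(),
                sub["meth_ratio"].to_numpy(),
            )
            for chrom, sub in signal.records.groupby("chrom", sort=False)
        }
    else:
        track = {
            c: (np.asarray(p, dtype=np.int64), np.asarray(v, dtype=np.float64))
            for c, (p, v) in signal.items()
        }
    n_bins = (2 * half_width) // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for f in features:
        if f.chrom not in track:
            continue
        pos, val = track[f.chrom]
        mid = (f.start + f.end) // 2
        lo = np.searchsorted(pos, mid - half_width, side="left")
        hi = np.searchsorted(pos, mid + half_width, side="left")
        if hi <= lo:
            continue
        offs = pos[lo:hi] - (mid - half_width)
        bins = np.minimum(offs // bin_size, n_bins - 1)
        bin_sum = np.bincount(bins, weights=val[lo:hi], minlength=n_bins)
        bin_n = np.bincount(bins, minlength=n_bins)
        has = bin_n > 0
        sums[has] += bin_sum[has] / bin_n[has]
        counts[has] += 1
    mean_signal = np.full(n_bins, np.nan)
    covered = counts > 0
    mean_signal[covered] = sums[covered] / counts[covered]
    offsets = -half_width + bin_size * np.arange(n_bins) + bin_size / 2.0
    return ProfileMatrix(
        offsets=offsets,
        mean_signal=mean_signal,
        half_width=half_width,
        bin_size=bin_size,
        n_features=len(features),
    )


@dataclass
class GroupSpecificCall:
    """Lineage-specificity label of one scUMC region."""

    region: GenomicRegion
    mean_a: float
    mean_b: float
    frac_low_a: float
    frac_low_b: float
    label: str  # A_specific | B_specific | shared | ambiguous
    flagged: bool = False  # True when a group had no covered member CpG


def _group_meth(
    region: GenomicRegion,
    methylomes: Sequence[Methylome],
    min_coverage: int,
) -> tuple[list[float], float]:
    """Per-sample mean ratios of member CpGs (covered samples only)."""
    means: list[float] = []
    for meth in methylomes:
        sub = meth.chrom_table(region.chrom)
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        window = sub.iloc[lo:hi]
        window = window[window["coverage"] >= min_coverage]
        if len(window):
            means.append(float(window["meth_ratio"].mean()))
    group_mean = float(np.mean(means)) if means else math.nan
    return means, group_mean


def group_specific(
    scumcs: Sequence[GenomicRegion],
    group_a: Sequence[Methylome],
    group_b: Sequence[Methylome],
    low: float = 0.10,
    high: float = 0.30,
    min_frac: float = 1.0,
    min_coverage: int = 4,
) -> list[GroupSpecificCall]:
    """Label scUMCs as specific to one cell group, shared, or ambiguous.

    A group is "under-methylated" at a region when the fraction of its
    covered samples whose member-CpG mean ratio is <= ``low`` reaches
    ``min_frac``. A region is A-specific when group A is under-methylated
    and the group-B mean is >= ``high`` (and symmetrically for
    B-specific); shared when both groups are under-methylated; otherwise
    ambiguous. A region with no covered member CpG in either group is
    ambiguous and flagged.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must contain at least one methylome")
    calls: list[GroupSpecificCall] = []
    for region in scumcs:
        means_a, mean_a = _group_meth(region, group_a, min_coverage)
        means_b, mean_b = _group_meth(region, group_b, min_coverage)
        if not means_a or not means_b:
            calls.append(
                GroupSpecificCall(
                    region, mean_a, mean_b, math.nan, math.nan, "ambiguous", True
                )
            )
            continue
        frac_a = sum(m <= low for m in means_a) / len(means_a)
        frac_b = sum(m <= low for m in means_b) / len(means_b)
        under_a = frac_a >= min_frac
        under_b = frac_b >= min_frac
        if under_a and under_b:
            label = "shared"
        elif under_a and mean_b >= high:
            label = "A_specific"
        elif under_b and mean_a >= high:
            label = "B_specific"
        else:
            label = "ambiguous"
        calls.append(
            GroupSpecificCall(region, mean_a, mean_b, frac_a, frac_b, label)
        )
    return calls
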