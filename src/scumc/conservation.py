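"""Cross-sample conservation scoring and scUMC / conserved-UMR calling.

The conservation score of a CpG across N methylomes is

    S = 100 * (number of samples in which the CpG is a UMC) / N,

a percentage in [0, 100]. Candidate UMCs are CpGs that are a UMC in at
least one sample, lie outside the union of all samples' conventional UMRs
and do not coincide with a SNP. Outlier conservation scores are flagged
with Chebyshev's inequality, Pr(|X - m| >= k*v) <= 1/k^2, which holds for
any score distribution with finite mean m and standard deviation v: the
tail probability p fixes k = sqrt(1/p) and the score threshold m + k*v,
which translates into a minimal integer sample count n_min. Credible CpGs
within 300 bp of each other are merged into scUMC regions.

The credibility test is applied on the integer sample-count scale
(presence count >= n_min, the "ten or more samples" form): it coincides
with S >= m + k*v whenever that threshold is attainable (<= 100), and
degrades gracefully (n_min is clipped to N) when a heavy planted tail
pushes the score threshold beyond 100.
"""
from __future__ import annotations

import json
import math
from collections.abc import Iterable, Sequence, Set
from dataclasses import dataclass, field

import numpy as np

from .core import GenomicRegion, Methylome, RegionIndex, merge_regions
from .umr import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_UMC_MAX_METH,
    detect_umrs,
    umc_table,
)

DEFAULT_TAIL_P = 0.01
DEFAULT_MERGE_GAP = 300
DEFAULT_LENIENT_P = 0.95


@dataclass
class CandidateUMC:
    """One candidate CpG with its per-sample under-methylation flags.

    ``presence[i]`` is 1 iff the CpG is a UMC in sample i of the fixed
    sample order. The score denominator is the total sample count N by
    default; with ``callable_only`` scoring it is the number of samples in
    which the CpG is callable at that position.
    """

    chrom: str
    pos: int
    presence: np.ndarray
    denominator: int

    @property
    def n_present(self) -> int:
        return int(self.presence.sum())

    @property
    def score(self) -> float:
        return conservation_score(self.presence, self.denominator)


def conservation_score(presence: Sequence[int] | np.ndarray, n_samples: int) -> float:
    """Exact percentage of samples carrying the under-methylated state."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    arr = np.asarray(presence)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("presence vector must be 0/1")
    return 100.0 * float(arr.sum()) / n_samples


def chebyshev_p(k: float) -> float:
    """Chebyshev tail bound 1/k^2, capped at 1."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return min(1.0, 1.0 / (k * k))


@dataclass(frozen=True)
class ChebyshevModel:
    """Fitted outlier model over candidate conservation scores."""

    m: float
    v: float
    p: float
    k: float
    threshold: float
    n_min: int
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "v": self.v,
            "p": self.p,
            "k": self.k,
            "threshold": self.threshold,
            "n_min": self.n_min,
            "N": self.n_samples,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ChebyshevModel":
        return cls(
            m=d["m"], v=d["v"], p=d["p"], k=d["k"],
            threshold=d["threshold"], n_min=d["n_min"], n_samples=d["N"],
        )


def fit_chebyshev(
    scores: Sequence[float] | np.ndarray,
    p: float = DEFAULT_TAIL_P,
    n_samples: int | None = None,
) -> ChebyshevModel:
    """Fit the outlier model: k = sqrt(1/p), threshold = m + k*v.

    ``m`` and ``v`` are the mean and (population) standard deviation of
    the candidate scores; ``n_min`` is the smallest integer sample count
    whose score reaches the threshold, ceil(threshold * N / 100), clipped
    to [1, N].
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"tail probability p must be in (0, 1], got {p}")
    arr = np.asarray(scores, dtype=np.float64)
    if np.unique(arr).size < 2:
        raise ValueError(
            "need at least two distinct conservation scores to fit the model"
        )
    if n_samples is None or n_samples < 1:
        raise ValueError("n_samples (total sample count N) is required")
    m = float(arr.mean())
    v = float(arr.std())  # population sd
    if v == 0.0:
        raise ValueError("degenerate score distribution (zero variance)")
    k = math.sqrt(1.0 / p)
    threshold = m + k * v
    # tiny slack absorbs float error when threshold*N/100 is an exact integer
    n_min = math.ceil(threshold * n_samples / 100.0 - 1e-9)
    n_min = min(max(n_min, 1), n_samples)
    return ChebyshevModel(
        m=m, v=v, p=p, k=k, threshold=threshold, n_min=n_min, n_samples=n_samples
    )


def build_candidates(
    methylomes: Sequence[Methylome],
    umr_sets: Iterable[Sequence[GenomicRegion]],
    snp_positions: Set[tuple[str, int]] | None = None,
    umc_max_meth: float = DEFAULT_UMC_MAX_METH,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    callable_only: bool = False,
) -> list[CandidateUMC]:
    """Collect candidate UMCs across samples.

    A position qualifies when it is a UMC in at least one sample, lies
    outside the union of every sample's UMRs, and is not a SNP position.
    The presence vector follows the order of ``methylomes``.
    """
    if len(methylomes) < 2:
        raise ValueError("need at least two methylomes")
    sample_ids = [m.sample_id for m in methylomes]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample_id among {sample_ids}")
    n = len(methylomes)
    exclusion = RegionIndex([r for regs in umr_sets for r in regs])
    snps = snp_positions or set()
    presence: dict[tuple[str, int], np.ndarray] = {}
    for i, meth in enumerate(methylomes):
        tab = umc_table(meth, umc_max_meth, min_coverage)
        for chrom, sub in tab.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            keep = ~exclusion.contains_points(str(chrom), pos)
            for p in pos[keep]:
                key = (str(chrom), int(p))
                if key in snps:
                    continue
                vec = presence.get(key)
                if vec is None:
                    vec = presence[key] = np.zeros(n, dtype=np.uint8)
                vec[i] = 1
    callable_counts: dict[tuple[str, int], int] = {}
    if callable_only:
        for meth in methylomes:
            df = meth.records
            cal = df[df["coverage"] >= min_coverage]
            for chrom, sub in cal.groupby("chrom", sort=False):
                for p in sub["pos"].to_numpy():
                    key = (str(chrom), int(p))
                    if key in presence:
                        callable_counts[key] = callable_counts.get(key, 0) + 1
    out = []
    for (chrom, pos), vec in sorted(presence.items()):
        denom = callable_counts.get((chrom, pos), n) if callable_only else n
        out.append(CandidateUMC(chrom, pos, vec, denom))
    return out


def call_credible_umcs(
    candidates: Iterable[CandidateUMC], model: ChebyshevModel
) -> list[CandidateUMC]:
    """Candidates whose presence count reaches the model's ``n_min``.

    Equivalent to the score test S >= threshold whenever the threshold is
    attainable on the score scale.
    """
    return [c for c in candidates if c.n_present >= model.n_min]


def merge_credible(
    credible: Iterable[CandidateUMC],
    merge_gap: int = DEFAULT_MERGE_GAP,
    excluded: RegionIndex | None = None,
) -> list[GenomicRegion]:
    """Single-linkage merge of credible CpGs within ``merge_gap`` bp.

    Consecutive credible positions at most ``merge_gap`` apart (inclusive)
    join one region spanning first position to last position + 2. When an
    exclusion index is given (the UMR union), two CpGs are never merged
    across an excluded interval, so scUMC regions stay disjoint from it.

    Regions carry ``n_members``, ``score`` (max member score) and
    ``members`` (comma-joined member positions) in their attributes.
    """
    per_chrom: dict[str, list[CandidateUMC]] = {}
    for c in credible:
        per_chrom.setdefault(c.chrom, []).append(c)
    regions: list[GenomicRegion] = []
    for chrom in sorted(per_chrom):
        members = sorted(per_chrom[chrom], key=lambda c: c.pos)
        group: list[CandidateUMC] = [members[0]]
        groups: list[list[CandidateUMC]] = [group]
        for prev, cur in zip(members, members[1:]):
            bridge_ok = cur.pos - prev.pos <= merge_gap
            if bridge_ok and excluded is not None:
                bridge_ok = not excluded.overlaps_interval(
                    chrom, prev.pos, cur.pos + 2
                )
            if bridge_ok:
                group.append(cur)
            else:
                group = [cur]
                groups.append(group)
        for g in groups:
            regions.append(
                GenomicRegion(
                    chrom,
                    g[0].pos,
                    g[-1].pos + 2,
                    {
                        "n_members": len(g),
                        "score": max(c.score for c in g),
                        "members": ",".join(str(c.pos) for c in g),
                    },
                )
            )
    return regions


def nonredundant_umrs(
    umr_sets: Iterable[Sequence[GenomicRegion]],
) -> list[GenomicRegion]:
    """Union of all samples' UMRs merged by >= 1 bp overlap or book-ending."""
    flat = [r for regs in umr_sets for r in regs]
    if not flat:
        return []
    return merge_regions(flat, book_ended=True)


def call_conserved_umrs(
    nonredundant: Sequence[GenomicRegion],
    methylomes: Sequence[Methylome],
    model: ChebyshevModel,
    umc_max_meth: float = DEFAULT_UMC_MAX_METH,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    snp_positions: Set[tuple[str, int]] | None = None,
) -> list[GenomicRegion]:
    """Non-redundant UMRs containing >= 1 CpG at the conservation cutoff.

    Presence counts are computed for every CpG inside each region (no UMR
    exclusion; SNP positions are kept unless ``snp_positions`` is given).
    A region qualifies iff its best CpG is a UMC in at least ``n_min``
    samples; qualifying regions gain ``max_samples`` and ``score`` attrs.
    """
    counts: dict[str, dict[int, int]] = {}
    for meth in methylomes:
        tab = umc_table(meth, umc_max_meth, min_coverage)
        for chrom, sub in tab.groupby("chrom", sort=False):
            d = counts.setdefault(str(chrom), {})
            for p in sub["pos"].to_numpy():
                d[int(p)] = d.get(int(p), 0) + 1
    if snp_positions:
        for chrom, pos in snp_positions:
            counts.get(chrom, {}).pop(pos, None)
    pos_arrays = {
        chrom: (np.array(sorted(d)), np.array([d[p] for p in sorted(d)]))
        for chrom, d in counts.items()
    }
    out = []
    for region in nonredundant:
        if region.chrom not in pos_arrays:
            continue
        pos, cnt = pos_arrays[region.chrom]
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        if hi <= lo:
            continue
        best = int(cnt[lo:hi].max())
        if best >= model.n_min:
            region.attrs.update(
                max_samples=best,
                score=conservation_score(
                    [1] * best + [0] * (model.n_samples - best), model.n_samples
                ),
            )
            out.append(region)
    return out


def call_nonconserved_umcs(
    candidates: Iterable[CandidateUMC],
    model: ChebyshevModel,
    lenient_p: float = DEFAULT_LENIENT_P,
) -> list[CandidateUMC]:
    """Candidates below the lenient threshold and not credible.

    The lenient threshold is m + sqrt(1/lenient_p)*v, the score at which
    the Chebyshev bound stops being non-significant.
    """
    if not 0.0 < lenient_p <= 1.0:
        raise ValueError(f"lenient_p must be in (0, 1], got {lenient_p}")
    lenient_threshold = model.m + math.sqrt(1.0 / lenient_p) * model.v
    return [
        c
        for c in candidates
        if c.score < lenient_threshold and c.n_present < model.n_min
    ]


def singleton_fraction(candidates: Sequence[CandidateUMC]) -> float:
    """Fraction of candidates under-methylated in exactly one sample."""
    if not candidates:
        raise ValueError("no candidates")
    return sum(c.n_present == 1 for c in candidates) / len(candidates)


@dataclass
class ScUmcResult:
    """Bundled outputs of the full scUMC discovery pipeline."""

    sample_ids: list[str]
    umr_sets: dict[str, list[GenomicRegion]]
    nonredundant: list[GenomicRegion]
    candidates: list[CandidateUMC]
    model: ChebyshevModel | None
    credible: list[CandidateUMC]
    scumc_regions: list[GenomicRegion]
    conserved_umrs: list[GenomicRegion]
    nonconserved: list[CandidateUMC]


def run_scumc_pipeline(
    methylomes: Sequence[Methylome],
    snp_positions: Set[tuple[str, int]] | None = None,
    p: float = DEFAULT_TAIL_P,
    merge_gap: int = DEFAULT_MERGE_GAP,
    lenient_p: float = DEFAULT_LENIENT_P,
    umc_max_meth: float = DEFAULT_UMC_MAX_METH,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_cpg: int = 4,
    mean_max: float = 0.10,
    max_gap: int | None = None,
    callable_only: bool = False,
) -> ScUmcResult:
    """Run UMR calling, candidate collection, model fit and all calls.

    With fewer than two distinct candidate scores the model cannot be fit;
    the result then carries ``model=None`` and empty call sets.
    """
    umr_sets = {
        m.sample_id: detect_umrs(
            m,
            min_cpg=min_cpg,
            umc_max_meth=umc_max_meth,
            mean_max=mean_max,
            max_gap=max_gap,
            min_coverage=min_coverage,
        )
        for m in methylomes
    }
    candidates = build_candidates(
        methylomes,
        umr_sets.values(),
        snp_positions=snp_positions,
        umc_max_meth=umc_max_meth,
        min_coverage=min_coverage,
        callable_only=callable_only,
    )
    nonredundant = nonredundant_umrs(umr_sets.values())
    scores = np.array([c.score for c in candidates])
    if np.unique(scores).size < 2:
        return ScUmcResult(
            sample_ids=[m.sample_id for m in methylomes],
            umr_sets=umr_sets,
            nonredundant=nonredundant,
            candidates=candidates,
            model=None,
            credible=[],
            scumc_regions=[],
            conserved_umrs=[],
            nonconserved=list(candidates),
        )
    model = fit_chebyshev(scores, p=p, n_samples=len(methylomes))
    credible = call_credible_umcs(candidates, model)
    exclusion = RegionIndex([r for regs in umr_sets.values() for r in regs])
    scumc_regions = merge_credible(credible, merge_gap=merge_gap, excluded=exclusion)
    conserved = call_conserved_umrs(
        nonredundant,
        methylomes,
        model,
        umc_max_meth=umc_max_meth,
        min_coverage=min_coverage,
    )
    nonconserved = call_nonconserved_umcs(candidates, model, lenient_p=lenient_p)
    return ScUmcResult(
        sample_ids=[m.sample_id for m in methylomes],
        umr_sets=umr_sets,
        nonredundant=nonredundant,
        candidates=candidates,
        model=model,
        credible=credible,
        scumc_regions=scumc_regions,
        conserved_umrs=conserved,
        nonconserved=nonconserved,
    )
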