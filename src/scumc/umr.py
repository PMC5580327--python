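"""Per-sample UMC and UMR calling, and the shuffle-based FDR for the
minimal-CpG cutoff.

An under-methylated CpG (UMC) is a CpG with methylation ratio at or below
10% supported by at least four reads. An under-methylated region (UMR) is
a maximal run of at least four consecutive callable hypomethylated CpGs
whose mean ratio is strictly below 10%. "Consecutive" is counted among
callable CpGs (coverage >= ``min_coverage``): sites below the coverage
floor have no ratio estimate and are invisible to the segmentation.

The minimal run length defended by the data is estimated by comparing UMR
counts in the observed methylome against methylomes whose
(ratio, coverage) pairs have been randomly permuted over positions,
destroying the spatial correlation of methylation while preserving its
marginal distribution and the callability structure.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicRegion, Methylome

DEFAULT_UMC_MAX_METH = 0.10
DEFAULT_MIN_COVERAGE = 4
DEFAULT_MIN_CPG = 4
DEFAULT_MEAN_MAX = 0.10


@dataclass(frozen=True)
class UmcCall:
    """A single under-methylated CpG call in one sample."""

    chrom: str
    pos: int
    meth_ratio: float
    coverage: int
    sample_id: str


def umc_table(
    methylome: Methylome,
    umc_max_meth: float = DEFAULT_UMC_MAX_METH,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Rows of the methylome passing the UMC criteria (fast path)."""
    df = methylome.records
    mask = (df["coverage"] >= min_coverage) & (df["meth_ratio"] <= umc_max_meth)
    return df[mask]


def call_umcs(
    methylome: Methylome,
    umc_max_meth: float = DEFAULT_UMC_MAX_METH,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> list[UmcCall]:
    """Call UMCs: ratio <= ``umc_max_meth`` and coverage >= ``min_coverage``.

    Both thresholds are inclusive. Returns calls in position order.
    """
    sub = umc_table(methylome, umc_max_meth, min_coverage)
    sid = methylome.sample_id
    return [
        UmcCall(c, int(p), float(r), int(cov), sid)
        for c, p, r, cov in zip(
            sub["chrom"], sub["pos"], sub["meth_ratio"], sub["coverage"]
        )
    ]


def detect_umrs(
    methylome: Methylome,
    min_cpg: int = DEFAULT_MIN_CPG,
    umc_max_meth: float = DEFAULT_UMC_MAX_METH,
    mean_max: float = DEFAULT_MEAN_MAX,
    max_gap: int | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> list[GenomicRegion]:
    """Call UMRs as maximal runs of consecutive hypomethylated CpGs.

    A run extends over callable CpGs (coverage >= ``min_coverage``) whose
    ratio is <= ``umc_max_meth``; it is broken by a callable CpG above that
    threshold, and additionally by an inter-CpG gap larger than ``max_gap``
    base pairs when set. Runs are reported iff they contain at least
    ``min_cpg`` members and their mean ratio is strictly below
    ``mean_max``. The region spans from the first member position to the
    last member position + 2 (covering the final dinucleotide).

    Returned regions carry ``n_cpg``, ``mean_meth`` and ``sample_id`` in
    their attribute map.
    """
    if min_cpg < 1:
        raise ValueError(f"min_cpg must be >= 1, got {min_cpg}")
    regions: list[GenomicRegion] = []
    df = methylome.records
    for chrom, sub in df.groupby("chrom", sort=True):
        cal = sub[sub["coverage"] >= min_coverage]
        pos = cal["pos"].to_numpy()
        ratio = cal["meth_ratio"].to_numpy()
        low_idx = np.flatnonzero(ratio <= umc_max_meth)
        if low_idx.size == 0:
            continue
        breaks = np.diff(low_idx) > 1  # an intervening callable CpG was high
        if max_gap is not None:
            breaks |= np.diff(pos[low_idx]) > max_gap
        bounds = np.flatnonzero(breaks) + 1
        for run in np.split(low_idx, bounds):
            if run.size < min_cpg:
                continue
            mean_meth = float(ratio[run].mean())
            if mean_meth >= mean_max:
                continue
            regions.append(
                GenomicRegion(
                    str(chrom),
                    int(pos[run[0]]),
                    int(pos[run[-1]]) + 2,
                    {
                        "n_cpg": int(run.size),
                        "mean_meth": mean_meth,
                        "sample_id": methylome.sample_id,
                    },
                )
            )
    return regions


def shuffle_methylome(methylome: Methylome, seed: int) -> Methylome:
    """Permute (ratio, coverage) pairs uniformly over all positions.

    Positions are unchanged; the multiset of observations is preserved.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    df = methylome.records
    perm = rng.permutation(len(df))
    shuffled = df.assign(
        meth_ratio=df["meth_ratio"].to_numpy()[perm],
        coverage=df["coverage"].to_numpy()[perm],
    )
    return Methylome(methylome.sample_id, shuffled)


@dataclass
class FdrCurve:
    """FDR estimates for candidate minimal-CpG cutoffs.

    ``table`` has one row per cutoff ``c``: the observed UMR count with
    >= c CpGs, the mean null count over shuffles, the FDR estimate
    (NaN where the observed count is zero, marked by ``defined``).
    ``c_min`` is the smallest cutoff whose defined FDR is <= ``alpha``,
    or None when no cutoff qualifies.
    """

    table: pd.DataFrame
    c_min: int | None
    alpha: float
    n_shuffles: int
    seed: int

    def fdr_at(self, c: int) -> float:
        row = self.table[self.table["c"] == c]
        if not len(row):
            raise KeyError(f"no FDR estimate for cutoff {c}")
        return float(row["fdr"].iloc[0])


def fdr_min_cpg(
    methylome: Methylome,
    alpha: float = 0.05,
    n_shuffles: int = 10,
    seed: int = 0,
    umc_max_meth: float = DEFAULT_UMC_MAX_METH,
    mean_max: float = DEFAULT_MEAN_MAX,
    max_gap: int | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> FdrCurve:
    """Estimate the minimal CpG count a UMR needs to clear ``alpha`` FDR.

    UMRs are segmented with ``min_cpg = 1`` in both the observed methylome
    and each of ``n_shuffles`` randomized methylomes; for each cutoff
    ``c``, FDR(c) = mean null count of runs with >= c CpGs divided by the
    observed count. Cutoffs with zero observed runs are marked undefined
    and excluded from the ``c_min`` search.
    """
    if n_shuffles < 1:
        raise ValueError(f"n_shuffles must be >= 1, got {n_shuffles}")
    if len(methylome) == 0:
        raise ValueError("cannot estimate an FDR curve on an empty methylome")
    caller = dict(
        min_cpg=1,
        umc_max_meth=umc_max_meth,
        mean_max=mean_max,
        max_gap=max_gap,
        min_coverage=min_coverage,
    )
    obs_sizes = np.array(
        [r.attrs["n_cpg"] for r in detect_umrs(methylome, **caller)], dtype=np.int64
    )
    child_seeds = np.random.SeedSequence(seed).generate_state(n_shuffles)
    null_sizes = [
        np.array(
            [
                r.attrs["n_cpg"]
                for r in detect_umrs(shuffle_methylome(methylome, int(s)), **caller)
            ],
            dtype=np.int64,
        )
        for s in child_seeds
    ]
    c_max = int(obs_sizes.max()) if obs_sizes.size else 0
    rows = []
    c_min: int | None = None
    for c in range(1, c_max + 1):
        n_obs = int((obs_sizes >= c).sum())
        mean_null = float(np.mean([(ns >= c).sum() for ns in null_sizes]))
        defined = n_obs > 0
        fdr = mean_null / n_obs if defined else math.nan
        rows.append(
            {
                "c": c,
                "n_observed": n_obs,
                "mean_null": mean_null,
                "fdr": fdr,
                "defined": defined,
            }
        )
        if c_min is None and defined and fdr <= alpha:
            c_min = c
    table = pd.DataFrame(
        rows, columns=["c", "n_observed", "mean_null", "fdr", "defined"]
    )
    return FdrCurve(table=table, c_min=c_min, alpha=alpha, n_shuffles=n_shuffles, seed=seed)
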