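"""Synthetic multi-sample methylome generator with a known truth set.

The generator emulates the data regime the scUMC method targets: a shared
CpG map across N samples, a highly methylated background (Beta-distributed
ratios with mean ~0.8, matching the 70-80% of the methylome that is highly
methylated), Poisson read coverage, planted multi-CpG UMRs that are low in
every sample, planted conserved sparse UMCs low in exactly j of N samples
with highly methylated flanks, and stochastic sample-specific UMCs at a
per-CpG per-sample rate rho tuned so that the large majority (~93%) of
single-base candidate UMCs occur in exactly one sample.

Everything is seeded and byte-reproducible; the truth set records every
planted feature so sensitivity and specificity of the pipeline can be
measured exactly.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GenomicRegion, Methylome
from . import methio


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic methylome.

    Defaults describe 31 samples over a single dense 200-kb chromosome
    (~20,000 CpGs): 20 planted 8-CpG UMRs, 50 planted conserved UMCs each
    shared by j ~ Uniform{10..N} samples, stochastic sample-specific UMCs
    at rho = 0.0047 per CpG per sample (N*rho ~ 0.146, putting ~93% of
    stochastic candidate UMCs in exactly one sample), background ratios
    Beta(8, 2) and coverage Poisson(30).
    """

    n_samples: int = 31
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 200_000})
    mean_cpg_spacing: float = 10.0
    beta_a: float = 8.0
    beta_b: float = 2.0
    coverage_mean: float = 30.0
    n_planted_umrs: int = 20
    umr_n_cpg: int = 8
    n_planted_scumcs: int = 50
    scumc_j_min: int = 10
    scumc_j_max: int | None = None  # defaults to n_samples
    rho: float = 0.0047
    n_snps: int = 30
    min_feature_separation: int = 301  # planted features pairwise > 300 bp apart
    low_meth_max: float = 0.08  # planted low ratios ~ Uniform(0, this)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        jmax = self.scumc_j_max if self.scumc_j_max is not None else self.n_samples
        if not 1 <= self.scumc_j_min <= jmax <= self.n_samples:
            raise ValueError(
                f"need 1 <= j_min <= j_max <= n_samples, got "
                f"[{self.scumc_j_min}, {jmax}] with N={self.n_samples}"
            )
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.umr_n_cpg < 4:
            raise ValueError("planted UMRs need >= 4 CpGs")
        if min(self.n_planted_umrs, self.n_planted_scumcs, self.n_snps) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.mean_cpg_spacing <= 2.0:
            raise ValueError("mean CpG spacing must exceed the dinucleotide (2 bp)")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass(frozen=True)
class PlantedScUmc:
    chrom: str
    pos: int
    carriers: tuple[int, ...]  # sample indices in which the CpG is low

    @property
    def j(self) -> int:
        return len(self.carriers)


@dataclass
class TruthSet:
    """Ground truth of one simulation run."""

    umrs: list[GenomicRegion]
    scumcs: list[PlantedScUmc]
    stochastic: dict[str, list[tuple[str, int]]]  # sample_id -> positions
    snps: set[tuple[str, int]]
    cpg_map: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def stochastic_positions(self) -> set[tuple[str, int]]:
        return {p for positions in self.stochastic.values() for p in positions}


def _draw_cpg_map(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    spacing_p = 1.0 / (cfg.mean_cpg_spacing - 1.0)
    cpg_map = {}
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        n_guess = int(length / cfg.mean_cpg_spacing * 1.5) + 10
        gaps = 1 + rng.geometric(spacing_p, size=n_guess)  # >= 2 bp apart
        pos = np.cumsum(gaps)
        while pos[-1] < length - 2:
            extra = 1 + rng.geometric(spacing_p, size=n_guess)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        cpg_map[chrom] = pos[pos < length - 2].astype(np.int64)
    return cpg_map


def _place_features(
    cfg: SimConfig,
    rng: np.random.Generator,
    cpg_map: dict[str, np.ndarray],
) -> tuple[list[tuple[str, np.ndarray]], list[tuple[str, int, int]]]:
    """Choose planted UMR CpG index blocks and planted scUMC CpG indices.

    Features keep ``min_feature_separation`` bp between their spans.
    Returns UMR blocks as (chrom, index array) and scUMCs as
    (chrom, index, position).
    """
    chroms = sorted(cpg_map)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    sep = cfg.min_feature_separation

    def clashes(chrom: str, start: int, end: int) -> bool:
        return any(
            start - sep < e and s < end + sep for s, e in occupied[chrom]
        )

    weights = np.array([cpg_map[c].size for c in chroms], dtype=float)
    weights /= weights.sum()
    umr_blocks: list[tuple[str, np.ndarray]] = []
    attempts = 0
    while len(umr_blocks) < cfg.n_planted_umrs:
        if attempts > 200 * max(cfg.n_planted_umrs, 1):
            raise ValueError(
                "cannot place the requested planted UMRs: genome too small "
                "for the feature count and separation"
            )
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos = cpg_map[chrom]
        if pos.size < cfg.umr_n_cpg:
            continue
        i = int(rng.integers(0, pos.size - cfg.umr_n_cpg + 1))
        span = (int(pos[i]), int(pos[i + cfg.umr_n_cpg - 1]) + 2)
        if clashes(chrom, *span):
            continue
        occupied[chrom].append(span)
        umr_blocks.append((chrom, np.arange(i, i + cfg.umr_n_cpg)))
    scumcs: list[tuple[str, int, int]] = []
    attempts = 0
    while len(scumcs) < cfg.n_planted_scumcs:
        if attempts > 200 * max(cfg.n_planted_scumcs, 1):
            raise ValueError(
                "cannot place the requested planted scUMCs: genome too small "
                "for the feature count and separation"
            )
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos = cpg_map[chrom]
        i = int(rng.integers(0, pos.size))
        span = (int(pos[i]), int(pos[i]) + 2)
        if clashes(chrom, *span):
            continue
        occupied[chrom].append(span)
        scumcs.append((chrom, i, int(pos[i])))
    return umr_blocks, scumcs


def simulate_methylomes(cfg: SimConfig) -> tuple[list[Methylome], TruthSet]:
    """Generate N methylomes over a shared CpG map, plus the truth set.

    Deterministic per ``cfg.seed``. Ratios are rounded to six decimals so
    that written fixtures round-trip exactly. Coverage >= 4 is guaranteed
    at every truth position (planted UMR CpGs, planted scUMCs, stochastic
    UMCs), elsewhere it is Poisson(``coverage_mean``) and sites below the
    caller's floor are retained for the caller to filter.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cpg_map = _draw_cpg_map(cfg, rng)
    umr_blocks, scumc_sites = _place_features(cfg, rng, cpg_map)
    jmax = cfg.scumc_j_max if cfg.scumc_j_max is not None else cfg.n_samples

    sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    chroms = sorted(cpg_map)
    n_by_chrom = {c: cpg_map[c].size for c in chroms}

    # per-chromosome matrices: samples x CpGs
    ratios = {
        c: rng.beta(cfg.beta_a, cfg.beta_b, size=(cfg.n_samples, n_by_chrom[c]))
        for c in chroms
    }
    coverage = {
        c: rng.poisson(cfg.coverage_mean, size=(cfg.n_samples, n_by_chrom[c]))
        for c in chroms
    }

    truth_umrs: list[GenomicRegion] = []
    for chrom, idx in umr_blocks:
        ratios[chrom][:, idx] = rng.uniform(
            0.0, cfg.low_meth_max, size=(cfg.n_samples, idx.size)
        )
        coverage[chrom][:, idx] = np.maximum(coverage[chrom][:, idx], 4)
        pos = cpg_map[chrom][idx]
        truth_umrs.append(
            GenomicRegion(
                chrom, int(pos[0]), int(pos[-1]) + 2, {"n_cpg": int(idx.size)}
            )
        )

    truth_scumcs: list[PlantedScUmc] = []
    planted_cols: dict[str, set[int]] = {c: set() for c in chroms}
    for chrom, idx in umr_blocks:
        planted_cols[chrom].update(int(i) for i in idx)
    for chrom, i, pos in scumc_sites:
        j = int(rng.integers(cfg.scumc_j_min, jmax + 1))
        carriers = tuple(
            sorted(int(s) for s in rng.choice(cfg.n_samples, size=j, replace=False))
        )
        col = ratios[chrom][:, i]
        col[:] = np.where(col <= 0.10, rng.uniform(0.5, 0.9, size=col.size), col)
        col[list(carriers)] = rng.uniform(0.0, cfg.low_meth_max, size=j)
        coverage[chrom][:, i] = np.maximum(coverage[chrom][:, i], 4)
        planted_cols[chrom].add(i)
        truth_scumcs.append(PlantedScUmc(chrom, pos, carriers))

    # stochastic sample-specific UMCs everywhere outside planted columns
    stochastic: dict[str, list[tuple[str, int]]] = {sid: [] for sid in sample_ids}
    for chrom in chroms:
        n = n_by_chrom[chrom]
        free = np.setdiff1d(
            np.arange(n), np.fromiter(planted_cols[chrom], dtype=np.int64, count=len(planted_cols[chrom]))
        )
        hits = rng.random((cfg.n_samples, free.size)) < cfg.rho
        for s in range(cfg.n_samples):
            cols = free[hits[s]]
            if cols.size == 0:
                continue
            ratios[chrom][s, cols] = rng.uniform(
                0.0, cfg.low_meth_max, size=cols.size
            )
            coverage[chrom][s, cols] = np.maximum(coverage[chrom][s, cols], 4)
            stochastic[sample_ids[s]].extend(
                (chrom, int(p)) for p in cpg_map[chrom][cols]
            )

    # SNP positions drawn from non-planted CpGs; they remain ordinary CpGs
    # in the tables so the SNP filter has something to remove
    snps: set[tuple[str, int]] = set()
    all_free = [
        (chrom, int(i))
        for chrom in chroms
        for i in np.setdiff1d(
            np.arange(n_by_chrom[chrom]),
            np.fromiter(planted_cols[chrom], dtype=np.int64, count=len(planted_cols[chrom])),
        )
    ]
    if cfg.n_snps > len(all_free):
        raise ValueError("more SNPs requested than available CpG positions")
    if cfg.n_snps:
        pick = rng.choice(len(all_free), size=cfg.n_snps, replace=False)
        snps = {
            (all_free[i][0], int(cpg_map[all_free[i][0]][all_free[i][1]]))
            for i in pick
        }

    methylomes = []
    for s, sid in enumerate(sample_ids):
        frames = [
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": cpg_map[chrom],
                    "meth_ratio": np.round(ratios[chrom][s], 6),
                    "coverage": coverage[chrom][s],
                }
            )
            for chrom in chroms
        ]
        methylomes.append(Methylome(sid, pd.concat(frames, ignore_index=True)))
    truth = TruthSet(
        umrs=truth_umrs,
        scumcs=truth_scumcs,
        stochastic=stochastic,
        snps=snps,
        cpg_map=cpg_map,
        chrom_lengths=dict(cfg.chrom_lengths),
    )
    return methylomes, truth


def write_fixture(
    methylomes: list[Methylome],
    truth: TruthSet,
    outdir: str | os.PathLike,
    dialect: str = "moabs_ratio",
) -> Path:
    """Write a simulation as the file set the command-line tools consume.

    Emits ``manifest.tsv`` (sample_id, path, dialect), one ratio table per
    sample, ``truth_umrs.bed`` / ``truth_scumcs.bed`` / ``truth_snps.bed``
    and ``chrom.sizes``. Returns the manifest path.
    """
    if not methylomes:
        raise ValueError("no methylomes to write")
    if dialect != "moabs_ratio":
        raise ValueError("fixtures are written in the moabs_ratio dialect")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as mh:
        for meth in methylomes:
            fname = f"{meth.sample_id}.meth.tsv"
            df = meth.records
            with open(outdir / fname, "w") as fh:
                for chrom, pos, ratio, cov in zip(
                    df["chrom"], df["pos"], df["meth_ratio"], df["coverage"]
                ):
                    fh.write(f"{chrom}\t{pos}\t{ratio:.6f}\t{cov}\n")
            mh.write(f"{meth.sample_id}\t{fname}\t{dialect}\n")
    methio.write_regions(truth.umrs, outdir / "truth_umrs.bed")
    methio.write_regions(
        [
            GenomicRegion(
                s.chrom, s.pos, s.pos + 2,
                {"j": s.j, "carriers": ",".join(map(str, s.carriers))},
            )
            for s in truth.scumcs
        ],
        outdir / "truth_scumcs.bed",
    )
    snp_regions = [
        GenomicRegion(c, p, p + 1) for c, p in sorted(truth.snps)
    ]
    methio.write_regions(snp_regions, outdir / "truth_snps.bed")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom in sorted(truth.chrom_lengths):
            fh.write(f"{chrom}\t{truth.chrom_lengths[chrom]}\n")
    return manifest


def read_manifest(
    path: str | os.PathLike, combine_strands: bool = True
) -> list[Methylome]:
    """Load methylomes listed in a ``sample_id<TAB>path<TAB>dialect`` manifest."""
    path = Path(path)
    methylomes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise methio.ParseError(
                    f"{path}, line {lineno}: expected sample_id, path, dialect"
                )
            sid, fname, dialect = fields[:3]
            fpath = Path(fname)
            if not fpath.is_absolute():
                fpath = path.parent / fpath
            methylomes.append(
                methio.read_methylome(
                    fpath, dialect, sid, combine_strands=combine_strands
                )
            )
    return methylomes
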