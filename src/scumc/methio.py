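"""Readers and writers for methylation tables, BED intervals, SNP
positions and chromosome sizes.

Coordinate handling is explicit: every reader declares its input dialect
and converts to the internal 0-based half-open convention at parse time.
Ratios are stored as fractions in ``[0, 1]``; percent-scaled inputs are
divided by 100 while parsing.

Supported methylation dialects
------------------------------
``bedgraph0``
    Six columns ``chrom start end ratio n_meth n_unmeth`` (MethylDackel-style
    bedGraph). ``start`` is 0-based; ``ratio`` is a fraction in [0, 1];
    coverage is ``n_meth + n_unmeth``.
``bismark_cov1``
    Bismark coverage file: ``chrom pos pos percent n_meth n_unmeth`` with
    1-based positions and a percent-scaled ratio in [0, 100].
``moabs_ratio``
    Four columns ``chrom pos ratio coverage`` with 0-based positions and a
    fractional ratio (MOABS-style ratio table).
"""
from __future__ import annotations

import os
from collections.abc import Iterable, Mapping
from typing import Literal

import numpy as np
import pandas as pd

from .core import Methylome, GenomicRegion

DIALECTS = ("bedgraph0", "bismark_cov1", "moabs_ratio")

Dialect = Literal["bedgraph0", "bismark_cov1", "moabs_ratio"]


class ParseError(ValueError):
    """Raised for malformed input lines; message names file and line."""


def _is_data_line(line: str) -> bool:
    s = line.strip()
    return bool(s) and not s.startswith("#") and not s.startswith("track")


def _parse_methylome_line(
    fields: list[str], dialect: str, path: str, lineno: int
) -> tuple[str, int, float, int]:
    def fail(msg: str) -> None:
        raise ParseError(f"{path}, line {lineno}: {msg}")

    try:
        if dialect == "bedgraph0":
            if len(fields) < 6:
                fail("expected 6 columns (chrom start end ratio n_meth n_unmeth)")
            chrom, pos = fields[0], int(fields[1])
            ratio = float(fields[3])
            if not 0.0 <= ratio <= 1.0:
                fail(f"ratio {ratio} outside [0, 1]")
            coverage = int(fields[4]) + int(fields[5])
        elif dialect == "bismark_cov1":
            if len(fields) < 6:
                fail("expected 6 columns (chrom pos pos percent n_meth n_unmeth)")
            chrom, pos = fields[0], int(fields[1]) - 1
            percent = float(fields[3])
            if not 0.0 <= percent <= 100.0:
                fail(f"percent methylation {percent} outside [0, 100]")
            ratio = percent / 100.0
            coverage = int(fields[4]) + int(fields[5])
        elif dialect == "moabs_ratio":
            if len(fields) < 4:
                fail("expected 4 columns (chrom pos ratio coverage)")
            chrom, pos = fields[0], int(fields[1])
            ratio = float(fields[2])
            if not 0.0 <= ratio <= 1.0:
                fail(f"ratio {ratio} outside [0, 1]")
            coverage = int(fields[3])
        else:
            raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    except ParseError:
        raise
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}, line {lineno}: malformed record ({exc})") from None
    if pos < 0:
        fail(f"non-positive coordinate at {chrom}")
    if coverage < 0:
        fail(f"negative coverage {coverage}")
    return chrom, pos, ratio, coverage


def _combine_strands(
    df: pd.DataFrame, cpg_map: Mapping[str, np.ndarray] | None
) -> pd.DataFrame:
    """Merge plus/minus strand calls of one CpG dinucleotide.

    With a CpG map, a record at ``p + 1`` whose ``p`` is a mapped cytosine is
    the minus-strand call of the CpG at ``p``. Without a map, records at
    adjacent positions ``p``/``p + 1`` are paired — safe because two
    plus-strand CpG cytosines are never adjacent. Coverages add; ratios are
    coverage-weighted.
    """
    if not len(df):
        return df
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    target = df["pos"].to_numpy().copy()
    if cpg_map is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            ref = np.asarray(cpg_map.get(chrom, np.empty(0)), dtype=np.int64)
            pos = sub["pos"].to_numpy()
            minus = np.isin(pos - 1, ref) & ~np.isin(pos, ref)
            target[sub.index.to_numpy()[minus]] = pos[minus] - 1
    else:
        same_chrom = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
        adjacent = np.diff(df["pos"].to_numpy()) == 1
        pair = np.flatnonzero(same_chrom & adjacent)
        # greedy left-to-right pairing; a position joins at most one pair
        keep = []
        last = -2
        for i in pair:
            if i > last + 1:
                keep.append(i)
                last = i
        for i in keep:
            target[i + 1] = target[i]
    if np.array_equal(target, df["pos"].to_numpy()):
        return df

    def _agg(g: pd.DataFrame) -> pd.Series:
        cov = int(g["coverage"].sum())
        if cov > 0:
            ratio = float((g["meth_ratio"] * g["coverage"]).sum() / cov)
        else:
            ratio = float(g["meth_ratio"].mean())
        return pd.Series({"meth_ratio": ratio, "coverage": cov})

    out = (
        df.assign(pos=target)
        .groupby(["chrom", "pos"], sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["coverage"] = out["coverage"].astype(np.int64)
    return out[["chrom", "pos", "meth_ratio", "coverage"]]


def read_methylome(
    path: str | os.PathLike,
    dialect: Dialect,
    sample_id: str,
    combine_strands: bool = True,
    cpg_map: Mapping[str, np.ndarray] | None = None,
) -> Methylome:
    """Read a per-sample CpG methylation table.

    Parameters
    ----------
    path
        Input file; plain text, whitespace- or tab-separated.
    dialect
        One of :data:`DIALECTS`; never sniffed.
    sample_id
        Label attached to the resulting :class:`~scumc.core.Methylome`.
    combine_strands
        Merge strand-split calls at adjacent positions into one record per
        CpG dinucleotide (coverage-summed, coverage-weighted ratio).
        Inputs that are already strand-combined are unaffected.
    cpg_map
        Optional mapping chrom → sorted array of plus-strand CpG positions,
        used to anchor strand combination.

    Raises
    ------
    ParseError
        On a malformed line (message names the line number), a ratio
        outside its dialect's range, or a duplicate position.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = os.fspath(path)
    rows: list[tuple[str, int, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not _is_data_line(line):
                continue
            rows.append(_parse_methylome_line(line.split(), dialect, path, lineno))
    if rows:
        df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_ratio", "coverage"])
    else:
        df = Methylome.empty_frame()
    if combine_strands:
        df = _combine_strands(df, cpg_map)
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(f"{path}: duplicate position {row.chrom}:{int(row.pos)}")
    return Methylome(sample_id, df)


def _typed(token: str):
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        return token


def read_regions(path: str | os.PathLike) -> list[GenomicRegion]:
    """Read a BED3+ file into :class:`~scumc.core.GenomicRegion` objects.

    Columns 4-6 populate ``attrs['name'/'score'/'strand']`` (a bare ``.``
    is skipped); a seventh column of ``key=value`` pairs (as emitted by
    :func:`write_regions`) is parsed back into ``attrs``; other extra
    columns are kept as ``col7``, ``col8``, ...
    """
    path = os.fspath(path)
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not _is_data_line(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}, line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}: non-numeric coordinates"
                ) from None
            if start >= end:
                raise ParseError(
                    f"{path}, line {lineno}: start {start} >= end {end}"
                )
            attrs: dict = {}
            for key, idx in (("name", 3), ("score", 4), ("strand", 5)):
                if len(fields) > idx and fields[idx] != ".":
                    attrs[key] = _typed(fields[idx]) if key == "score" else fields[idx]
            for idx in range(6, len(fields)):
                token = fields[idx]
                if token == ".":
                    continue
                parts = token.split(";")
                if parts and all("=" in p for p in parts):
                    for p in parts:
                        k, v = p.split("=", 1)
                        attrs[k] = _typed(v)
                else:
                    attrs[f"col{idx + 1}"] = _typed(token)
            try:
                regions.append(GenomicRegion(fields[0], start, end, attrs))
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
    return regions


def _fmt(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def write_regions(
    regions: Iterable[GenomicRegion],
    path: str | os.PathLike,
    header: Iterable[str] | None = None,
) -> None:
    """Write regions as BED6+1 with a deterministic column order.

    Column 5 carries ``attrs['score']`` when present (e.g. the conservation
    score of an scUMC); every other attribute goes into column 7 as sorted
    ``key=value`` pairs so that ``read_regions`` round-trips exactly.
    Optional ``header`` lines are written as ``#``-prefixed comments.
    """
    with open(path, "w") as fh:
        for line in header or ():
            fh.write(f"# {line}\n")
        for r in regions:
            name = _fmt(r.attrs["name"]) if "name" in r.attrs else "."
            score = _fmt(r.attrs["score"]) if "score" in r.attrs else "."
            strand = _fmt(r.attrs["strand"]) if "strand" in r.attrs else "."
            rest = {
                k: v
                for k, v in r.attrs.items()
                if k not in ("name", "score", "strand")
            }
            extra = (
                ";".join(f"{k}={_fmt(rest[k])}" for k in sorted(rest)) if rest else "."
            )
            fh.write(
                "\t".join(
                    [r.chrom, str(r.start), str(r.end), name, score, strand, extra]
                )
                + "\n"
            )


def read_snp_positions(
    path: str | os.PathLike, fmt: Literal["bed", "vcf"]
) -> set[tuple[str, int]]:
    """Read SNP point positions as a set of ``(chrom, pos)`` (0-based).

    ``bed``: the start coordinate of each interval. ``vcf``: the POS field
    of each variant record shifted 1-based → 0-based (reference position
    only; genotypes and alleles are ignored).
    """
    path = os.fspath(path)
    out: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if fmt == "vcf":
                if s.startswith("#"):
                    continue
                fields = s.split("\t")
                if len(fields) == 1:
                    fields = s.split()
                if len(fields) < 2:
                    raise ParseError(f"{path}, line {lineno}: truncated VCF record")
                try:
                    out.add((fields[0], int(fields[1]) - 1))
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: non-numeric POS field"
                    ) from None
            elif fmt == "bed":
                if not _is_data_line(s):
                    continue
                fields = s.split()
                if len(fields) < 2:
                    raise ParseError(f"{path}, line {lineno}: truncated BED record")
                try:
                    out.add((fields[0], int(fields[1])))
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: non-numeric coordinate"
                    ) from None
            else:
                raise ValueError(f"unknown SNP format {fmt!r}; expected 'bed' or 'vcf'")
    return out


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    path = os.fspath(path)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not _is_data_line(line):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}, line {lineno}: expected chrom and length")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}: non-numeric chromosome length"
                ) from None
    return sizes
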