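"""Single-cell methylome overlay on the recovered cell-cycle order.

Single-cell bisulfite coverage is too sparse for per-site rates, so each CpG
is binarized per cell by majority vote of methylated vs unmethylated read
counts (ties, including 0/0, are missing).  Per cell, a genome-wide level is
the fraction of methylated calls among measured sites; a region-set level
pools measured CpGs falling in promoter windows (+/- 3 kb around the
strand-aware TSS).  Levels ordered along the pseudotime are smoothed with a
9-point centered moving average.

Coordinate conventions: CpG tables are 1-based positions (bismark-coverage
dialect); BED input is 0-based half-open.  Conversion happens in one place
(:func:`read_bed_regions` / :func:`RegionSet.from_tss_bed`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusOrder
from .matrix import ValidationError

MISSING = -1  # sentinel for "no call" in integer call arrays


@dataclass
class CpgCallTable:
    """Per-cell CpG records: chrom, 1-based position, met/unmet counts, call."""

    table: pd.DataFrame  # columns: chrom, pos, met, unmet, call

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "met", "unmet"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"CpG table needs columns {sorted(required)}")
        if (self.table[["met", "unmet"]] < 0).any().any():
            raise ValidationError("negative CpG counts")
        if "call" not in self.table.columns:
            self.table = self.table.assign(
                call=[binarize_cpg(m, u) for m, u in zip(self.table["met"], self.table["unmet"])]
            )

    @classmethod
    def from_counts(cls, chrom, pos, met, unmet) -> "CpgCallTable":
        return cls(pd.DataFrame({"chrom": chrom, "pos": pos, "met": met, "unmet": unmet}))

    def measured(self) -> pd.DataFrame:
        return self.table[self.table["call"] != MISSING]


@dataclass
class RegionSet:
    """Genomic regions (0-based half-open) tagged with gene ids."""

    table: pd.DataFrame  # columns: chrom, start, end, gene, strand

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "gene"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"region table needs columns {sorted(required)}")
        if (self.table["start"] >= self.table["end"]).any():
            raise ValidationError("regions must satisfy start < end")

    @classmethod
    def from_tss_bed(cls, bed: pd.DataFrame, flank: int = 3000) -> "RegionSet":
        """Promoter windows: +/- ``flank`` bp around the strand-aware TSS.

        ``bed`` is BED6-like (chrom, start, end, name, score, strand) with
        0-based half-open gene intervals; TSS = start for + strand, end - 1
        for - strand.  Windows are clipped at the chromosome start.
        """
        strand = bed["strand"] if "strand" in bed.columns else pd.Series(["+"] * len(bed))
        tss = np.where(strand == "-", bed["end"].to_numpy() - 1, bed["start"].to_numpy())
        start = np.maximum(tss - flank, 0)
        end = tss + flank + 1
        return cls(
            pd.DataFrame(
                {
                    "chrom": bed["chrom"].to_numpy(),
                    "start": start,
                    "end": end,
                    "gene": bed["name"].to_numpy() if "name" in bed.columns else [
                        f"region_{i}" for i in range(len(bed))
                    ],
                    "strand": strand.to_numpy(),
                }
            )
        )

    def subset_genes(self, genes) -> "RegionSet":
        wanted = set(genes)
        sub = self.table[self.table["gene"].isin(wanted)]
        if sub.empty:
            raise ValidationError("no regions left after gene subset")
        return RegionSet(sub.reset_index(drop=True))


@dataclass
class MethylationTrack:
    """Per ordered cell: raw and 9-point-smoothed methylation level."""

    cell_ids: list[str]
    level: np.ndarray     # may contain NaN for cells with no measured CpGs
    smoothed: np.ndarray

    def __post_init__(self) -> None:
        self.level = np.asarray(self.level, dtype=float)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        ok = self.level[~np.isnan(self.level)]
        if ok.size and (ok.min() < 0 or ok.max() > 1):
            raise ValidationError("methylation levels must lie in [0, 1]")
        if self.smoothed.shape != self.level.shape:
            raise ValidationError("smoothed track length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "rank": np.arange(len(self.cell_ids)),
                "level": self.level,
                "smoothed": self.smoothed,
            }
        )


def binarize_cpg(met: int, unmet: int) -> int:
    """Binary call by majority: 1 if met > unmet, 0 if met < unmet, missing on
    ties (including 0/0 — no evidence either way)."""
    if met < 0 or unmet < 0:
        raise ValidationError("negative counts")
    if met > unmet:
        return 1
    if met < unmet:
        return 0
    return MISSING


def genome_level(table: CpgCallTable) -> float:
    """Fraction of methylated calls among all measured (non-missing) sites."""
    measured = table.measured()
    if measured.empty:
        raise ValidationError("no measured CpG sites")
    return float((measured["call"] == 1).mean())


def region_mean_level(
    table: CpgCallTable, regions: RegionSet, per_region: bool = False
) -> float:
    """Methylation level over a region set.

    Default is site-pooled: one ratio over all measured CpGs falling in any
    region (overlapping regions never double-count a site).  ``per_region``
    instead averages per-region ratios over regions with >= 1 measured CpG.
    Returns NaN when no measured CpG falls in the set.
    """
    measured = table.measured()
    if regions.table.empty:
        raise ValidationError("empty region set")
    if measured.empty:
        return float("nan")
    pooled_hits: list[pd.DataFrame] = []
    per_region_levels: list[float] = []
    for chrom, regs in regions.table.groupby("chrom"):
        sites = measured[measured["chrom"] == chrom]
        if sites.empty:
            continue
        pos0 = sites["pos"].to_numpy() - 1  # 1-based position -> 0-based coordinate
        covered = np.zeros(len(sites), dtype=bool)
        for start, end in regs[["start", "end"]].itertuples(index=False):
            inside = (pos0 >= start) & (pos0 < end)
            covered |= inside
            if per_region and inside.any():
                per_region_levels.append(float((sites["call"].to_numpy()[inside] == 1).mean()))
        pooled_hits.append(sites[covered])
    if per_region:
        return float(np.mean(per_region_levels)) if per_region_levels else float("nan")
    hits = pd.concat(pooled_hits) if pooled_hits else pd.DataFrame(columns=["call"])
    if hits.empty:
        return float("nan")
    return float((hits["call"] == 1).mean())


def smooth9(track: np.ndarray, window: int = 9) -> np.ndarray:
    """Centered moving average; edge windows truncate to the available points.

    NaN entries are ignored (a window averages its non-NaN members)."""
    if window % 2 == 0 or window < 1:
        raise ValidationError("window must be odd and positive")
    x = np.asarray(track, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        seg = x[max(0, i - half): i + half + 1]
        ok = seg[~np.isnan(seg)]
        out[i] = ok.mean() if ok.size else np.nan
    return out


def methylation_along_cycle(
    tables: dict[str, CpgCallTable],
    order: ConsensusOrder,
    regions: RegionSet | None = None,
    window: int = 9,
    per_region: bool = False,
) -> MethylationTrack:
    """Per ordered cell, the genome-wide (or region-set) methylation level,
    followed by the 9-point smoother."""
    missing = [c for c in order.cell_ids if c not in tables]
    if missing:
        raise ValidationError(f"no CpG table for cells: {missing[:3]}")
    ordered = [order.cell_ids[i] for i in order.linear_order]
    levels = np.empty(len(ordered))
    for i, cell in enumerate(ordered):
        if regions is None:
            levels[i] = genome_level(tables[cell])
        else:
            levels[i] = region_mean_level(tables[cell], regions, per_region=per_region)
    return MethylationTrack(ordered, levels, smooth9(levels, window))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cpg_table(path: str | os.PathLike) -> CpgCallTable:
    """Bismark-coverage-like TSV: chrom, 1-based position, met count, unmet count."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "met", "unmet"], comment="#"
    )
    return CpgCallTable(df)


def write_cpg_table(table: CpgCallTable, path: str | os.PathLike) -> None:
    table.table[["chrom", "pos", "met", "unmet"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed_regions(path: str | os.PathLike, flank: int = 3000) -> RegionSet:
    """Read a BED6 file of gene bodies and build TSS +/- flank promoter windows."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6), comment="#",
    )
    return RegionSet.from_tss_bed(bed, flank=flank)
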