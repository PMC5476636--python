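"""Synthetic unsynchronized single-cell transcriptomes with known phase.

The generator emulates the statistical structure the ordering method
assumes: every cell sits at a true phase phi on the unit circle; cycle genes
have a periodic, unimodal (von-Mises-bump) mean curve peaking at a gene-
specific phase; peak phases are drawn from a two-component mixture
concentrated at the G1 and G2 arcs (the two observed waves of cycle-gene
expression); counts are negative binomial around the mean curve, scaled by a
log-normal library size, with optional dropout.  An optional G0 arc holds
quiescent cells whose cycle-gene means are globally depressed — the
signature the stage HMM uses to call G0.

Everything is deterministic given the config seed, and ground truth (phase,
stage, library size, per-gene peaks) is returned alongside the matrix.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    ExpressionMatrix,
    GeneCatalog,
    ValidationError,
    write_catalog,
    write_expression_mtx,
    write_expression_tsv,
)
from .methylation import CpgCallTable, write_cpg_table

# fractions of the cycling part of the circle, in biological order
STAGE_FRACTIONS = {"G1": 0.4, "S": 0.3, "G2M": 0.3}
# six-way peak-stage partition of the cycling arc (for catalog annotation)
PEAK_STAGE_BOUNDS = [
    ("G1", 0.00, 0.25),
    ("G1/S", 0.25, 0.40),
    ("S", 0.40, 0.55),
    ("G2", 0.55, 0.75),
    ("G2/M", 0.75, 0.90),
    ("M", 0.90, 1.00),
]
# the two waves: peak-phase mixture centers on the cycling arc
WAVE_CENTERS = (0.20, 0.65)  # G1 checkpoint and G2 checkpoint
WAVE_KAPPA = 3.0


@dataclass
class CycleSimConfig:
    """Study conditions for the synthetic cycle."""

    n_cells: int = 300
    n_genes: int = 200
    seed: int = 0
    signal_fraction: float = 0.9     # fraction of genes with a cycle-dependent mean
    baseline_log_mean: float = 3.0   # ln-scale baseline expression (~20 counts)
    baseline_log_sd: float = 0.5
    amplitude_factor: float = 2.0    # peak height relative to baseline
    bump_kappa: float = 5.0          # concentration (width) of the mean curve bump
    dispersion: float = 0.2          # NB: var = mu + dispersion * mu^2
    library_log_sd: float = 0.3      # log-normal library-size spread (mean 1)
    dropout: float = 0.1             # dropout at zero expression; decays with the mean
    dropout_mid: float = 5.0         # expression scale of the dropout decay
    g0_fraction: float = 0.0         # arc fraction of quiescent cells
    g0_depression: float = 0.4       # multiplier on cycle-gene means in G0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValidationError("n_cells and n_genes must be positive")
        for name in ("signal_fraction", "dropout", "g0_fraction", "g0_depression"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.dispersion < 0 or self.library_log_sd < 0 or self.bump_kappa <= 0:
            raise ValidationError("invalid noise configuration")


@dataclass
class SimTruth:
    """Ground truth of one simulation."""

    phi: np.ndarray            # (n_cells,) true phase in [0, 1)
    stage: list[str]           # per-cell stage label consistent with phi
    library: np.ndarray        # (n_cells,) library-size factors
    gene_peak: np.ndarray      # (n_genes,) peak phase (NaN for non-signal genes)
    signal: np.ndarray         # (n_genes,) bool
    cell_ids: list[str]
    gene_ids: list[str]
    config: CycleSimConfig = field(repr=False, default=None)

    def to_json(self) -> str:
        return json.dumps(
            {
                "phi": self.phi.tolist(),
                "stage": self.stage,
                "library": self.library.tolist(),
                "gene_peak": [None if np.isnan(p) else p for p in self.gene_peak],
                "signal": self.signal.astype(bool).tolist(),
                "cell_ids": self.cell_ids,
                "gene_ids": self.gene_ids,
                "config": asdict(self.config) if self.config else None,
            }
        )


def stage_of_phase(phi: float, g0_fraction: float = 0.0) -> str:
    """Stage label of a phase under the declared arcs: an optional G0 arc at
    the start of the circle, then G1/S/G2M in 0.4/0.3/0.3 proportions."""
    if phi < g0_fraction:
        return "G0"
    u = (phi - g0_fraction) / (1.0 - g0_fraction)
    if u < STAGE_FRACTIONS["G1"]:
        return "G1"
    if u < STAGE_FRACTIONS["G1"] + STAGE_FRACTIONS["S"]:
        return "S"
    return "G2M"


def peak_stage_of_phase(u: float) -> str:
    """Six-way peak-stage annotation of a peak phase on the cycling arc."""
    for stage, lo, hi in PEAK_STAGE_BOUNDS:
        if lo <= u < hi:
            return stage
    return "M"


def _bump(phi: np.ndarray, peak: np.ndarray, kappa: float) -> np.ndarray:
    """Periodic unimodal bump in [0, 1], maximal (=1) at the peak phase."""
    return np.exp(kappa * (np.cos(2 * np.pi * (phi - peak)) - 1.0))


def mean_curve(config: CycleSimConfig, phi: np.ndarray, baseline: np.ndarray,
               amplitude: np.ndarray, peak: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Expected expression (genes x cells) at phases ``phi`` before noise."""
    mu = np.tile(baseline[:, None], (1, phi.size)).astype(float)
    sig = np.flatnonzero(signal)
    if sig.size:
        mu[sig] += amplitude[sig, None] * _bump(phi[None, :], peak[sig, None], config.bump_kappa)
    if config.g0_fraction > 0:
        # quiescent cells do not run the cycle program: cycle genes sit at a
        # depressed baseline with no cyclic component
        in_g0 = np.flatnonzero(phi < config.g0_fraction)
        mu[np.ix_(sig, in_g0)] = config.g0_depression * baseline[sig, None]
    return mu


def simulate_expression(config: CycleSimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw one synthetic expression matrix (counts, raw layer) with truth."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_cells, config.n_genes
    phi = rng.uniform(0, 1, n)
    stage = [stage_of_phase(p, config.g0_fraction) for p in phi]
    library = np.exp(rng.normal(-config.library_log_sd**2 / 2, config.library_log_sd, n))

    signal = rng.uniform(size=m) < config.signal_fraction
    wave = rng.integers(0, 2, m)
    peak_u = np.mod(
        rng.vonmises(2 * np.pi * (np.array(WAVE_CENTERS)[wave] - 0.5), WAVE_KAPPA, m)
        / (2 * np.pi) + 0.5,
        1.0,
    )
    # map cycling-arc position onto the full circle (past any G0 arc)
    peak = config.g0_fraction + peak_u * (1 - config.g0_fraction)
    peak[~signal] = np.nan

    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, m))
    amplitude = config.amplitude_factor * baseline

    mu = mean_curve(config, phi, baseline, amplitude, peak, signal) * library[None, :]
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    else:
        counts = rng.poisson(mu).astype(float)
    if config.dropout > 0:
        # dropout probability decays with the underlying mean, so highly
        # expressed genes stay detected in every cell (as in real protocols)
        p_drop = config.dropout * np.exp(-mu / config.dropout_mid)
        counts[rng.uniform(size=counts.shape) < p_drop] = 0.0

    cell_ids = [f"cell_{i:04d}" for i in range(n)]
    gene_ids = [f"gene_{g:04d}" for g in range(m)]
    mat = ExpressionMatrix(counts, gene_ids, cell_ids, unit="counts", layer="raw")
    truth = SimTruth(phi, stage, library, peak, signal, cell_ids, gene_ids, config)
    return mat, truth


def make_catalog(truth: SimTruth) -> GeneCatalog:
    """Cycle-gene catalog from the simulation truth: signal genes annotated by
    the six-way peak stage of their peak phase, ranked by amplitude order
    (the generator draws amplitude proportional to baseline, so rank follows
    the gene index order of decreasing baseline within each stage)."""
    cfg = truth.config
    records = []
    for g in np.flatnonzero(truth.signal):
        u = (truth.gene_peak[g] - cfg.g0_fraction) / (1 - cfg.g0_fraction)
        records.append({"gene": truth.gene_ids[g], "peak_stage": peak_stage_of_phase(u)})
    df = pd.DataFrame(records)
    df["rank"] = np.arange(1, len(df) + 1)
    return GeneCatalog(df)


def simulate_methylome(
    truth: SimTruth,
    peak_arc: tuple[float, float] = (0.35, 0.55),
    n_cpg: int = 400,
    seed: int = 0,
    base_level: float = 0.55,
    elevation: float = 0.25,
    mean_coverage: float = 3.0,
    site_rate: float = 0.6,
) -> dict[str, CpgCallTable]:
    """Per-cell CpG coverage tables whose global methylation probability is
    elevated for cells with true phase inside ``peak_arc``.

    Sites live on one synthetic chromosome; each cell measures a random
    ``site_rate`` fraction of them with 1 + Poisson coverage, and methylated
    counts are binomial at the cell's level.
    """
    lo, hi = peak_arc
    if not (0 <= lo < hi <= 1):
        raise ValidationError("peak_arc must be an interval inside [0, 1]")
    if not (0 <= base_level <= 1 and 0 <= base_level + elevation <= 1):
        raise ValidationError("methylation levels must stay in [0, 1]")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(1, 1_000_001), size=n_cpg, replace=False))
    tables: dict[str, CpgCallTable] = {}
    for i, cell in enumerate(truth.cell_ids):
        p = base_level + (elevation if lo <= truth.phi[i] < hi else 0.0)
        keep = rng.uniform(size=n_cpg) < site_rate
        pos = positions[keep]
        cov = 1 + rng.poisson(max(mean_coverage - 1, 0), pos.size)
        met = rng.binomial(cov, p)
        tables[cell] = CpgCallTable.from_counts(
            ["chr1"] * pos.size, pos, met, cov - met
        )
    return tables


def simulate_tss_bed(gene_ids: list[str], seed: int = 0) -> pd.DataFrame:
    """BED6-like frame of gene bodies on the synthetic chromosome."""
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.choice(np.arange(0, 980_000), size=len(gene_ids), replace=False))
    strands = rng.choice(["+", "-"], size=len(gene_ids))
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + 2000,
            "name": gene_ids,
            "score": 0,
            "strand": strands,
        }
    )


def simulate_score_track(
    means: np.ndarray, covars: np.ndarray, block_lengths: list[int], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Score-track emissions from known per-stage Gaussians in stage blocks.

    Returns (T, 9) observations and the true state index per position; used
    to study parameter and path recovery of the segmentation HMM.
    """
    means = np.asarray(means, dtype=float)
    covars = np.asarray(covars, dtype=float)
    rng = np.random.default_rng(seed)
    rows, states = [], []
    for s, length in enumerate(block_lengths):
        rows.append(rng.normal(means[s], np.sqrt(covars[s]), size=(length, means.shape[1])))
        states.extend([s] * length)
    return np.vstack(rows), np.asarray(states)


def write_fixture_bundle(
    out_dir: str | os.PathLike,
    config: CycleSimConfig | None = None,
    with_methylome: bool = True,
) -> dict[str, object]:
    """Write a complete synthetic input bundle readable by every loader.

    Files: expression.tsv, expression.mtx (+ genes.txt / cells.txt),
    catalog.tsv, labels.tsv, truth.json, tss.bed and cpg/<cell>.tsv tables.
    """
    config = config or CycleSimConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat, truth = simulate_expression(config)
    catalog = make_catalog(truth)
    write_expression_tsv(mat, out / "expression.tsv")
    write_expression_mtx(mat, out / "expression.mtx")
    write_catalog(catalog, out / "catalog.tsv")
    pd.DataFrame({"cell": mat.cell_ids, "label": truth.stage}).to_csv(
        out / "labels.tsv", sep="\t", index=False
    )
    (out / "truth.json").write_text(truth.to_json())
    paths: dict[str, object] = {
        "expression_tsv": out / "expression.tsv",
        "expression_mtx": out / "expression.mtx",
        "catalog": out / "catalog.tsv",
        "labels": out / "labels.tsv",
        "truth": out / "truth.json",
    }
    if with_methylome:
        bed = simulate_tss_bed(mat.gene_ids, seed=config.seed)
        bed.to_csv(out / "tss.bed", sep="\t", header=False, index=False)
        cpg_dir = out / "cpg"
        cpg_dir.mkdir(exist_ok=True)
        tables = simulate_methylome(truth, seed=config.seed)
        for cell, table in tables.items():
            write_cpg_table(table, cpg_dir / f"{cell}.tsv")
        paths["tss_bed"] = out / "tss.bed"
        paths["cpg_dir"] = cpg_dir
    return paths
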