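"""End-to-end workflow: ingest -> order -> scores -> stages -> genes -> methylome.

A :class:`RunConfig` (loadable from YAML) drives the full chain and writes
TSV/JSON artifacts plus a manifest with package version, seeds and a config
hash, so any artifact can be reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_frame, rank_cycle_genes
from .consensus import consensus_order
from .evaluation import evaluate_order
from .hmm import segment_stages, stage_proportions
from .matrix import read_catalog, read_expression, read_labels
from .methylation import methylation_along_cycle, read_bed_regions, read_cpg_table
from .preprocess import preprocess
from .scores import GenePairModel, MeanScoreSets, load_default_pair_model, score_track, train_gene_pairs

log = logging.getLogger("recat")


@dataclass
class RunConfig:
    expression: str
    out_dir: str
    catalog: str | None = None
    labels: str | None = None
    cpg_dir: str | None = None
    tss_bed: str | None = None
    pair_model: str | None = None
    format: str | None = None
    unit: str = "TPM"
    transpose: bool = False
    min_genes: int | None = None
    min_expr: float = 2.0
    min_mean: float = 2.0
    size_factor_normalize: bool = True
    k_min: int = 7
    k_max: int | None = None
    n_fold: int = 2
    seed: int = 0
    include_g0: bool = False
    granularity: str = "cell"
    fast_start: bool = False
    n_perm: int = 100
    smooth_association: bool = True
    flank: int = 3000

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the artifact directory.

    Stage failures raise with the failing stage named; artifacts written
    before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(("order", "hmm", "genes"), ss.spawn(3))}
    manifest["seeds"] = seeds

    def _stage(name: str):
        log.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time()}
        return time.time()

    def _done(name: str, t0: float):
        manifest["stages"][name]["seconds"] = round(time.time() - t0, 3)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        t0 = _stage("ingest")
        mat = read_expression(config.expression, format=config.format,
                              unit=config.unit, transpose=config.transpose)
        catalog = read_catalog(config.catalog) if config.catalog else None
        mat, qc = preprocess(
            mat, catalog, min_genes=config.min_genes, min_expr=config.min_expr,
            min_mean=config.min_mean, size_factor_normalize=config.size_factor_normalize,
        )
        manifest["stages"]["ingest"]["cells_kept"] = qc.cells_kept
        manifest["stages"]["ingest"]["genes_kept"] = mat.n_genes
        _done("ingest", t0)

        t0 = _stage("order")
        order = consensus_order(
            mat, k_min=config.k_min, k_max=config.k_max,
            n_fold=config.n_fold, seed=seeds["order"],
        )
        order_df = pd.DataFrame(
            {"cell_id": order.cell_ids, "theta": order.theta, "linear_rank": order.ranks()}
        )
        order_df.to_csv(out / "order.tsv", sep="\t", index=False)
        (out / "order_provenance.json").write_text(
            json.dumps(order.provenance, default=float, indent=2)
        )
        _done("order", t0)

        t0 = _stage("scores")
        labels = read_labels(config.labels) if config.labels else None
        if config.pair_model:
            pair_model = GenePairModel.from_json(Path(config.pair_model).read_text())
        elif labels is not None and set(labels.unique()) >= {"G1", "S", "G2M"}:
            train = labels[labels.isin(["G1", "S", "G2M"])]
            pair_model = train_gene_pairs(
                mat.subset_cells([mat.cell_ids.index(c) for c in train.index]), train
            )
        else:
            pair_model = load_default_pair_model()
        sets = (MeanScoreSets.from_catalog(catalog) if catalog
                else MeanScoreSets.from_catalog(_fallback_catalog(mat)))
        track = score_track(order, mat, pair_model, sets, granularity=config.granularity)
        track.to_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
        _done("scores", t0)

        t0 = _stage("stages")
        hmm, path = segment_stages(
            track, include_g0=config.include_g0, seed=seeds["hmm"],
            refit=not config.fast_start,
        )
        path_df = path.to_frame()
        path_df.to_csv(out / "stages.tsv", sep="\t", index=False)
        stage_proportions(path).to_csv(out / "stage_proportions.tsv", sep="\t")
        _done("stages", t0)

        t0 = _stage("genes")
        results = rank_cycle_genes(
            mat, order, n_perm=config.n_perm, seed=seeds["genes"],
            smooth=config.smooth_association,
        )
        association_frame(results).to_csv(out / "gene_ranking.tsv", sep="\t", index=False)
        _done("genes", t0)

        if config.cpg_dir:
            t0 = _stage("methylome")
            tables = {
                p.stem: read_cpg_table(p) for p in sorted(Path(config.cpg_dir).glob("*.tsv"))
            }
            track_m = methylation_along_cycle(tables, order)
            track_m.to_frame().to_csv(out / "methylation_genome.tsv", sep="\t", index=False)
            if config.tss_bed:
                regions = read_bed_regions(config.tss_bed, flank=config.flank)
                track_r = methylation_along_cycle(tables, order, regions=regions)
                track_r.to_frame().to_csv(out / "methylation_promoters.tsv", sep="\t", index=False)
            _done("methylome", t0)

        if labels is not None:
            t0 = _stage("evaluate")
            stage_to_int = {"G0": 1, "G1": 1, "S": 2, "G2M": 3, "G2/M": 3}
            int_labels = {c: stage_to_int.get(str(v), 1) for c, v in labels.items()
                          if c in set(order.cell_ids)}
            if len(int_labels) == order.n_cells:
                metrics = evaluate_order(order, int_labels)
                (out / "evaluation.json").write_text(json.dumps(metrics, indent=2))
            _done("evaluate", t0)
    except Exception as err:
        failing = [k for k, v in manifest["stages"].items() if "seconds" not in v]
        raise RuntimeError(f"pipeline failed at stage {failing[-1] if failing else '?'}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _fallback_catalog(mat):
    """Without a catalog, mean-score sets cannot be formed; fail loudly."""
    from .matrix import ValidationError

    raise ValidationError("a gene catalog is required to compute mean-scores")
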