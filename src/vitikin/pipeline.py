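"""End-to-end orchestration: one config, all reports.

Runs the full analysis on a VCF + metadata bundle: dataset-construction
filters, the dual wide/deep datasets, pairwise kinship on both, IBD sharing
matrices with both heatmap orderings when a segment file is supplied, a
descent report for every pair classified parent-offspring or duplicate, and
polygenic colour scores with panel-percentile placement when an effect
table is supplied.  All thresholds live in the :class:`RunConfig`; outputs
are deterministic given the config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import colorscore, descent, genotype, ibd, kinship

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    metadata: str | None = None
    ibd_segments: str | None = None
    effects: str | None = None
    out_dir: str = "vitikin_out"
    seed: int = 0
    filter_spec: genotype.FilterSpec = field(default_factory=genotype.FilterSpec)
    thresholds: kinship.KinshipThresholds = field(default_factory=kinship.KinshipThresholds)
    focal_samples: list[str] = field(default_factory=list)
    descent_allowance: float = 0.005
    min_ibd_lod: float = 3.0
    color_min_loci: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "filter_spec" in raw:
            raw["filter_spec"] = genotype.FilterSpec(**raw["filter_spec"])
        if "thresholds" in raw:
            raw["thresholds"] = kinship.KinshipThresholds(**raw["thresholds"])
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.vcf, self.metadata, self.ibd_segments, self.effects):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _stage(name: str, t0: float) -> None:
    logger.info("stage %-18s done in %.2fs", name, time.time() - t0)


def run_kinship_report(config: RunConfig) -> dict:
    """Filters, dual datasets, kinship tables, IBD sharing, descent reports."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    t0 = time.time()
    G = genotype.read_vcf(config.vcf)
    if config.metadata:
        genotype.attach_metadata(G, genotype.read_sample_metadata(config.metadata))
    logger.info("input: %d samples x %d loci", G.n_samples, G.n_loci)
    _stage("load", t0)

    focal = config.focal_samples or [
        s for s in G.sample_ids if G.samples.loc[s, "group"] == "archaeological"
    ]

    t0 = time.time()
    if focal:
        wide, deep, report = genotype.build_dual_datasets(G, focal, config.filter_spec)
        datasets = {"wide": wide, "deep": deep}
    else:
        wide, rep = genotype.apply_filters(G, config.filter_spec)
        report = {"wide": {"n_samples": wide.n_samples, "n_loci": wide.n_loci}}
        datasets = {"wide": wide}
    (out / "filter_report.json").write_text(json.dumps(report, indent=2) + "\n")
    artifacts["filter_report"] = out / "filter_report.json"
    _stage("filter", t0)

    t0 = time.time()
    close_pairs = []
    for name, D in datasets.items():
        table = kinship.kinship_matrix(D, config.thresholds)
        path = out / f"kinship_{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        artifacts[f"kinship_{name}"] = path
        if name == "wide":
            hits = table[table["category"].isin(["parent-offspring", "duplicate/clone"])]
            close_pairs = list(hits[["id1", "id2", "category"]].itertuples(index=False))
        logger.info("kinship (%s): %d pairs", name, len(table))
    _stage("kinship", t0)

    if config.ibd_segments:
        t0 = time.time()
        segs = ibd.parse_ibd(config.ibd_segments, min_lod=config.min_ibd_lod)
        M = ibd.sharing_matrix(segs, wide.sample_ids)
        M.write_tsv(out / "ibd_sharing.tsv")
        artifacts["ibd_sharing"] = out / "ibd_sharing.tsv"
        orders = {"hclust": ibd.order_samples(M, "hclust")}
        if focal:
            orders["closeness"] = ibd.order_samples(M, "closeness", focal=[
                f for f in focal if f in M.sample_ids
            ])
        (out / "ibd_orderings.json").write_text(
            json.dumps(orders, indent=2) + "\n"
        )
        from . import plots

        for mode, order in orders.items():
            plots.sharing_heatmap(M, order, str(out / f"ibd_heatmap_{mode}.png"),
                                  title=f"IBD sharing ({mode} order)")
        artifacts["ibd_orderings"] = out / "ibd_orderings.json"
        _stage("ibd", t0)
    else:
        logger.info("no IBD segment file supplied; skipping sharing matrix")

    t0 = time.time()
    descent_reports = {}
    for id1, id2, category in close_pairs:
        rep = descent.descent_report(wide, id1, id2, config.descent_allowance)
        rep["kinship_category"] = category
        descent_reports[f"{id1}__{id2}"] = rep
    if descent_reports:
        (out / "descent_reports.json").write_text(
            json.dumps(descent_reports, indent=2, default=str) + "\n"
        )
        artifacts["descent_reports"] = out / "descent_reports.json"
    _stage("descent", t0)

    artifacts["datasets"] = datasets
    artifacts["close_pairs"] = close_pairs
    return artifacts


def run_color_report(config: RunConfig) -> dict:
    """Polygenic colour scores and focal-sample percentile placement."""
    config.validate()
    if not config.effects:
        raise ValueError("run_color_report requires an effects table")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    G = genotype.read_vcf(config.vcf)
    if config.metadata:
        genotype.attach_metadata(G, genotype.read_sample_metadata(config.metadata))
    effects = colorscore.EffectTable.read_tsv(config.effects)
    scores = colorscore.polygenic_scores(G, effects, min_loci=config.color_min_loci)
    scores.to_csv(out / "color_scores.tsv", sep="\t", index=False)

    focal = config.focal_samples or [
        s for s in G.sample_ids if G.samples.loc[s, "group"] == "archaeological"
    ]
    colors = G.samples["color"]
    panel = scores[~scores["sample"].isin(focal) & scores["defined"]]
    reference = {
        cat: panel.loc[[colors.get(s) == cat for s in panel["sample"]], "score"].to_numpy()
        for cat in set(colors) - {""}
    }
    reference = {c: v for c, v in reference.items() if len(v)}

    placements = {}
    excluded = []
    s_by_id = scores.set_index("sample")
    for f in focal:
        if f not in s_by_id.index or not bool(s_by_id.loc[f, "defined"]):
            excluded.append(f)
            continue
        placements[f] = colorscore.percentile_placement(
            float(s_by_id.loc[f, "score"]), reference
        )
    (out / "color_placement.json").write_text(
        json.dumps({"placements": placements, "excluded": excluded}, indent=2) + "\n"
    )

    from . import plots

    cats = tuple(c for c in ("white", "gray", "rose", "red", "black") if c in reference)
    plots.score_distribution(
        scores[~scores["sample"].isin(excluded)], colors,
        [f for f in focal if f in placements],
        str(out / "color_scores.png"), categories=cats or ("white", "black"),
    )
    return {
        "scores": out / "color_scores.tsv",
        "placements": placements,
        "excluded": excluded,
    }


def run_all(config: RunConfig) -> dict:
    """Run kinship/descent and, when an effect table is supplied, colour."""
    np.random.seed(config.seed % (2**31))  # legacy global state, for any library draw
    artifacts = run_kinship_report(config)
    if config.effects:
        artifacts["color"] = run_color_report(config)
    return artifacts
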