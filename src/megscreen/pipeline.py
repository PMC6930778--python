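"""End-to-end orchestration of the screening pipeline.

Stages (each runnable individually, all file-based within one output
directory, so chaining the stages equals one ``run_pipeline`` call):

1. ``stage_simulate``  — optional: write a synthetic study (network, both
   cohorts, planted truth) into the output directory.
2. ``stage_degs``      — cross-sectional moderated t-test, BH adjustment,
   DEG selection at ``deg_alpha``.
3. ``stage_generank``  — network-weighted expression of the DEGs for every
   longitudinal sample (damping ``d``).
4. ``stage_screen``    — per response group: Kruskal-Wallis across time
   points, BH at ``kw_alpha``, monotone-pattern filter on the flagged genes.
5. ``stage_classify``  — join monotone and DE directions into good/bad
   response calls; write the run report.

Every output table carries ``#`` provenance comments (config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import classify_all
from .diffexpr import fit_moderated_t, select_degs
from .errors import InputError
from .generank import build_rank_system, generank_all_samples
from .io import (
    check_matched,
    read_expression,
    read_metadata,
    read_network,
    read_table,
    write_expression,
    write_metadata,
    write_network,
    write_table,
)
from .longitudinal import NONE, find_megs, screen_genes
from .simulate import SimulationConfig, generate_dataset, truth_frame

logger = logging.getLogger(__name__)

INPUT_FILES = {
    "cross_expression": "cross_expression.tsv",
    "cross_metadata": "cross_metadata.tsv",
    "long_expression": "long_expression.tsv",
    "long_metadata": "long_metadata.tsv",
    "network": "network.tsv",
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and provenance for one pipeline run.

    Input paths default to the conventional file names inside ``outdir``
    (which is where ``stage_simulate`` writes them).
    """

    outdir: Path
    simulation: SimulationConfig | None = None
    cross_expression: Path | None = None
    cross_metadata: Path | None = None
    long_expression: Path | None = None
    long_metadata: Path | None = None
    network: Path | None = None
    contrast: tuple[str, str] = ("case", "control")
    deg_alpha: float = 0.1
    kw_alpha: float = 0.1
    damping: float = 0.5
    tolerance: float = 0.0
    rank_scope: str = "degs"  # "degs": rank in the DEG-induced subgraph; "full": rank in the whole network, then subset
    plain_t: bool = False      # diagnostic: ordinary pooled-variance t instead of the moderated t
    screen_method: str = "kruskal"  # or "friedman" (patient-blocked sensitivity analysis)
    seed: int = 0

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if not 0.0 < self.deg_alpha < 1.0 or not 0.0 < self.kw_alpha < 1.0:
            raise InputError("alphas must be in (0, 1)")
        if not 0.0 <= self.damping < 1.0:
            raise InputError("damping must be in [0, 1)")
        if self.rank_scope not in ("degs", "full"):
            raise InputError("rank_scope must be 'degs' or 'full'")
        if self.screen_method not in ("kruskal", "friedman"):
            raise InputError("screen_method must be 'kruskal' or 'friedman'")

    def input_path(self, key: str) -> Path:
        override = getattr(self, key)
        return Path(override) if override is not None else self.outdir / INPUT_FILES[key]

    def config_hash(self) -> str:
        """Hash of the scientific parameters only (not paths), so identical
        analyses in different directories produce identical outputs."""
        payload = asdict(self)
        for key in ("outdir", *INPUT_FILES):
            payload.pop(key, None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def provenance(self) -> list[str]:
        return [f"megscreen {__version__} config_sha={self.config_hash()} seed={self.seed}"]


def stage_simulate(config: PipelineConfig) -> dict:
    if config.simulation is None:
        raise InputError("stage_simulate requires a simulation configuration")
    config.outdir.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(config.simulation)
    comments = config.provenance()
    write_expression(data["cross_expression"], config.outdir / INPUT_FILES["cross_expression"], comments)
    write_metadata(data["cross_metadata"], config.outdir / INPUT_FILES["cross_metadata"], comments)
    write_expression(data["long_expression"], config.outdir / INPUT_FILES["long_expression"], comments)
    write_metadata(data["long_metadata"], config.outdir / INPUT_FILES["long_metadata"], comments)
    write_network(data["network"], config.outdir / INPUT_FILES["network"], comments)
    write_table(truth_frame(data["truth"]), config.outdir / "truth.tsv", comments)
    return {"n_genes": int(len(data["cross_expression"])), "n_edges": data["network"].number_of_edges()}


def stage_degs(config: PipelineConfig) -> dict:
    expr = read_expression(config.input_path("cross_expression"))
    meta = read_metadata(config.input_path("cross_metadata"))
    check_matched(expr, meta, "cross-sectional")
    results = fit_moderated_t(expr, meta, config.contrast, moderate=not config.plain_t)
    degs = select_degs(results, config.deg_alpha)
    comments = config.provenance()
    config.outdir.mkdir(parents=True, exist_ok=True)
    write_table(results.reset_index(), config.outdir / "de_results.tsv", comments)
    write_table(degs.reset_index(), config.outdir / "degs.tsv", comments)
    n_up = int((degs["direction"] == "up").sum())
    n_down = int((degs["direction"] == "down").sum())
    logger.info("degs: %d selected (%d up, %d down) at alpha=%s", len(degs), n_up, n_down, config.deg_alpha)
    return {"n_genes": int(len(results)), "n_degs": int(len(degs)), "n_up": n_up, "n_down": n_down}


def _groups(meta: pd.DataFrame) -> list[str]:
    return sorted(meta["group"].unique())


def stage_generank(config: PipelineConfig) -> dict:
    degs = read_table(config.outdir / "degs.tsv", index_col="gene_id")
    expr = read_expression(config.input_path("long_expression"))
    meta = read_metadata(config.input_path("long_metadata"))
    check_matched(expr, meta, "longitudinal")
    network = read_network(config.input_path("network"))

    if network.number_of_nodes() > 0:
        overlap = len(set(expr.index) & set(network.nodes))
        if overlap == 0:
            raise InputError(
                "gene identifier namespaces of the expression matrix and the "
                f"network do not overlap (overlap size {overlap})"
            )

    deg_genes = sorted(degs.index)
    comments = config.provenance()
    counts = {}
    for group in _groups(meta):
        samples = [s for s in expr.columns if s in meta.index[meta["group"] == group]]
        if not deg_genes:
            ranks = pd.DataFrame(index=pd.Index([], name="gene_id"), columns=samples)
            logger.info("generank: empty DEG set; writing empty rank table for %s", group)
        else:
            missing = [g for g in deg_genes if g not in expr.index]
            if missing:
                raise InputError(f"DEGs missing from longitudinal expression: {missing[:5]}")
            if config.rank_scope == "degs":
                system = build_rank_system(network, deg_genes, config.damping)
                ranks = generank_all_samples(system, expr.loc[deg_genes, samples])
            else:
                order = sorted(expr.index)
                system = build_rank_system(network, order, config.damping)
                ranks = generank_all_samples(system, expr.loc[order, samples]).loc[deg_genes]
        write_expression(ranks, config.outdir / f"generanks_{group}.tsv", comments)
        counts[group] = len(samples)
    return {"n_ranked_genes": len(deg_genes), "samples_per_group": counts}


def stage_screen(config: PipelineConfig) -> dict:
    meta = read_metadata(config.input_path("long_metadata"))
    comments = config.provenance()
    counts = {}
    for group in _groups(meta):
        ranks = read_expression(config.outdir / f"generanks_{group}.tsv")
        group_meta = meta[meta["group"] == group]
        if ranks.empty:
            screen = pd.DataFrame(columns=["H", "p", "adj_p", "flagged", "pattern", "direction"])
            screen.index.name = "gene_id"
            megs = screen[["pattern", "direction"]]
        else:
            screen = screen_genes(ranks, group_meta, group, config.kw_alpha, method=config.screen_method)
            megs = find_megs(screen, ranks, group_meta, group, config.tolerance)
            screen["pattern"] = NONE
            screen["direction"] = ""
            screen.loc[megs.index, "pattern"] = megs["pattern"]
            screen.loc[megs.index, "direction"] = megs["direction"]
        write_table(screen.reset_index(), config.outdir / f"screen_{group}.tsv", comments)
        counts[group] = {"flagged": int(screen["flagged"].sum()) if len(screen) else 0, "megs": int(len(megs))}
        logger.info("screen %s: %d flagged, %d MEGs", group, counts[group]["flagged"], counts[group]["megs"])
    return counts


def stage_classify(config: PipelineConfig) -> dict:
    meta = read_metadata(config.input_path("long_metadata"))
    degs = read_table(config.outdir / "degs.tsv", index_col="gene_id")
    frames = []
    counts = {}
    for group in _groups(meta):
        screen = read_table(config.outdir / f"screen_{group}.tsv", index_col="gene_id")
        if len(screen):
            megs = screen[screen["pattern"].notna() & (screen["pattern"] != NONE)][["direction"]]
        else:
            megs = pd.DataFrame(columns=["direction"])
        classified = classify_all(megs, degs, group)
        frames.append(classified)
        counts[group] = {
            "megs": int(len(classified)),
            "good": int((classified["classification"] == "good").sum()),
            "bad": int((classified["classification"] == "bad").sum()),
        }
    combined = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["gene", "group", "meg_direction", "deg_direction", "classification"])
    )
    write_table(combined, config.outdir / "megs_classified.tsv", config.provenance())
    return counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write ``run_report.json``; returns the report."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "version": __version__,
        "seed": config.seed,
        "config_sha": config.config_hash(),
        "thresholds": {
            "deg_alpha": config.deg_alpha,
            "kw_alpha": config.kw_alpha,
            "damping": config.damping,
            "tolerance": config.tolerance,
        },
        "stages": {},
    }
    if config.simulation is not None:
        report["stages"]["simulate"] = stage_simulate(config)
    report["stages"]["degs"] = stage_degs(config)
    if report["stages"]["degs"]["n_degs"] == 0:
        logger.info("pipeline: empty DEG set; downstream outputs will be empty")
    report["stages"]["generank"] = stage_generank(config)
    report["stages"]["screen"] = stage_screen(config)
    report["stages"]["classify"] = stage_classify(config)
    with open(config.outdir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
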