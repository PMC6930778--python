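"""Synthetic study generator with known planted truth.

Emulates the two-cohort design used for treatment-response screening: a
cross-sectional case/control cohort on which differentially expressed genes
(DEGs) are found, and a longitudinal cohort of two response groups sampled
at several ordered time points, on which monotone trends are screened.
Expression values are nonnegative log2 intensities; a sparse undirected
interaction network (with a forced isolated subset) accompanies them.

One seed governs the whole study via independent derived substreams, so the
network, the cross-sectional matrix and the longitudinal matrix can be
regenerated independently and reproducibly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NONRESPONDER = "nonresponder"
CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and effect-size parameters for the generator.

    All expression parameters are on the log2-intensity scale. Defaults
    mirror the motivating study design: 26 cases vs 18 controls in the
    cross-sectional cohort, and two response groups of 9 patients sampled
    at 5 ordered time points in the longitudinal cohort.
    """

    n_genes: int = 150
    n_cases: int = 26
    n_controls: int = 18
    n_patients_per_group: int = 9
    n_timepoints: int = 5
    de_fraction: float = 0.1
    de_effect: float = 1.0
    trend_step: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    edge_prob: float = 0.05
    isolated_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_patients_per_group": self.n_patients_per_group,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.n_timepoints < 2:
            raise ConfigurationError("n_timepoints must be >= 2")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ConfigurationError("de_fraction must be in [0, 1)")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ConfigurationError("edge_prob must be in [0, 1]")
        if not 0.0 <= self.isolated_fraction <= 1.0:
            raise ConfigurationError("isolated_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.baseline_mean < 0:
            raise ConfigurationError("baseline_mean must be nonnegative (log2 intensity)")
        if self.baseline_mean - 6.0 * self.noise_sd < 0:
            logger.warning(
                "baseline_mean - 6*noise_sd < 0: generated intensities may be clipped at 0"
            )

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def substreams(self) -> dict[str, np.random.SeedSequence]:
        """Independent named substreams derived from the single seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("network", "cross", "long", "link"), children))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: cross-sectional DE directions and per-group
    monotone time trends."""

    de_up: frozenset = frozenset()
    de_down: frozenset = frozenset()
    monotone_up: dict = field(default_factory=dict)    # group -> frozenset of genes
    monotone_down: dict = field(default_factory=dict)  # group -> frozenset of genes

    def __post_init__(self):
        if self.de_up & self.de_down:
            raise ConfigurationError("a gene cannot be planted both up and down")
        for group in set(self.monotone_up) | set(self.monotone_down):
            up = self.monotone_up.get(group, frozenset())
            down = self.monotone_down.get(group, frozenset())
            if up & down:
                raise ConfigurationError(
                    f"group {group!r}: a gene cannot be planted both increasing and decreasing"
                )


def generate_network(config: SimulationConfig) -> nx.Graph:
    """Erdos-Renyi gene-interaction graph with a forced isolated subset.

    Isolated genes exercise the degree-0 branch of the network weighting
    (their weighted value reduces to ``(1 - d) * expression``).
    """
    config.validate()
    rng = np.random.default_rng(config.substreams()["network"])
    genes = config.gene_ids()
    n = config.n_genes

    graph = nx.Graph()
    graph.add_nodes_from(genes)

    n_isolated = math.ceil(config.isolated_fraction * n)
    isolated = set(rng.choice(n, size=n_isolated, replace=False).tolist()) if n_isolated else set()

    iu, ju = np.triu_indices(n, k=1)
    draw = rng.random(iu.shape[0]) < config.edge_prob
    for i, j in zip(iu[draw], ju[draw]):
        if i in isolated or j in isolated:
            continue
        graph.add_edge(genes[i], genes[j])
    return graph


def _clip_nonnegative(values: np.ndarray, context: str) -> np.ndarray:
    n_neg = int((values < 0).sum())
    if n_neg:
        logger.warning("%s: clipped %d negative intensities at 0", context, n_neg)
        values = np.clip(values, 0.0, None)
    return values


def _split_planted(genes: np.ndarray, n_planted: int, rng: np.random.Generator):
    """Draw a planted set and split it into an up half and a down half."""
    chosen = rng.choice(genes, size=n_planted, replace=False) if n_planted else np.array([], dtype=object)
    n_up = (n_planted + 1) // 2
    return frozenset(chosen[:n_up].tolist()), frozenset(chosen[n_up:].tolist())


def generate_cross_sectional(config: SimulationConfig):
    """Case/control expression matrix with planted up/down DEGs.

    Returns ``(expression, metadata, truth)``. Planted up genes are shifted
    ``+de_effect`` in cases, down genes ``-de_effect``; all other entries are
    ``baseline_mean`` plus Gaussian noise, clipped at 0.
    """
    config.validate()
    rng = np.random.default_rng(config.substreams()["cross"])
    genes = np.array(config.gene_ids(), dtype=object)

    n_de = round(config.de_fraction * config.n_genes)
    de_up, de_down = _split_planted(genes, n_de, rng)
    truth = SyntheticTruth(de_up=de_up, de_down=de_down)

    n_samples = config.n_cases + config.n_controls
    sample_ids = [f"CASE{i + 1:03d}" for i in range(config.n_cases)] + [
        f"CTRL{i + 1:03d}" for i in range(config.n_controls)
    ]
    values = config.baseline_mean + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    case_cols = np.arange(config.n_cases)
    up_rows = np.flatnonzero(np.isin(genes, list(de_up)))
    down_rows = np.flatnonzero(np.isin(genes, list(de_down)))
    values[np.ix_(up_rows, case_cols)] += config.de_effect
    values[np.ix_(down_rows, case_cols)] -= config.de_effect
    values = _clip_nonnegative(values, "cross-sectional matrix")

    expression = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": sample_ids,
            "group": [CASE] * config.n_cases + [CONTROL] * config.n_controls,
            "timepoint": [pd.NA] * n_samples,
        }
    ).set_index("sample_id")
    return expression, metadata, truth


def _random_planting(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Default per-group planting map: group -> {gene: +1 (up) or -1 (down)}."""
    genes = np.array(config.gene_ids(), dtype=object)
    planted: dict[str, dict[str, int]] = {}
    for group in (RESPONDER, NONRESPONDER):
        n_mono = round(config.de_fraction * config.n_genes) if config.trend_step != 0 else 0
        up, down = _split_planted(genes, n_mono, rng)
        planted[group] = {**{g: 1 for g in up}, **{g: -1 for g in down}}
    return planted


def generate_longitudinal(config: SimulationConfig, planted: dict | None = None):
    """Two response groups x repeated patients x ordered time points.

    A planted monotone-up gene in a group has population mean
    ``baseline_mean + k * trend_step`` at time point ``k`` (k = 0..T-1);
    monotone-down analogous with ``-trend_step``; non-planted genes are flat.

    ``planted`` optionally overrides the random planting map with
    ``{group: {gene_id: +1 | -1}}``; with ``trend_step == 0`` the truth sets
    are empty by construction.

    Returns ``(expression, metadata, truth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.substreams()["long"])
    genes = config.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}

    if planted is None:
        planted = _random_planting(config, rng)
    groups = sorted(planted)

    if config.trend_step == 0:
        truth = SyntheticTruth(
            monotone_up={g: frozenset() for g in groups},
            monotone_down={g: frozenset() for g in groups},
        )
    else:
        truth = SyntheticTruth(
            monotone_up={g: frozenset(k for k, v in planted[g].items() if v > 0) for g in groups},
            monotone_down={g: frozenset(k for k, v in planted[g].items() if v < 0) for g in groups},
        )

    prefix = {RESPONDER: "R", NONRESPONDER: "N"}
    columns, meta_rows = [], []
    blocks = []
    for group in groups:
        trend = np.zeros(config.n_genes)
        if config.trend_step != 0:
            for gene, direction in planted[group].items():
                trend[gene_index[gene]] = direction * config.trend_step
        tag = prefix.get(group, group[:1].upper())
        for p in range(config.n_patients_per_group):
            patient = f"{tag}{p + 1:02d}"
            for k in range(config.n_timepoints):
                sample = f"{patient}_T{k}"
                columns.append(sample)
                meta_rows.append((sample, patient, group, k))
                blocks.append(config.baseline_mean + k * trend)
    means = np.column_stack(blocks)
    values = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    values = _clip_nonnegative(values, "longitudinal matrix")

    expression = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=columns)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "patient_id", "group", "timepoint"]
    ).set_index("sample_id")
    return expression, metadata, truth


def generate_dataset(config: SimulationConfig):
    """Full self-contained study: network + both cohorts + merged truth.

    Longitudinal trends are planted on the planted DE genes (direction drawn
    per gene and group), so the downstream funnel DEG -> longitudinal screen
    -> monotone filter -> classification is exercisable end to end.
    """
    config.validate()
    network = generate_network(config)
    cross_expr, cross_meta, cross_truth = generate_cross_sectional(config)

    link_rng = np.random.default_rng(config.substreams()["link"])
    de_genes = sorted(cross_truth.de_up | cross_truth.de_down)
    planted = {}
    for group in (RESPONDER, NONRESPONDER):
        if config.trend_step != 0 and de_genes:
            planted[group] = {g: int(link_rng.choice([1, -1])) for g in de_genes}
        else:
            planted[group] = {}
    long_expr, long_meta, long_truth = generate_longitudinal(config, planted=planted)

    truth = SyntheticTruth(
        de_up=cross_truth.de_up,
        de_down=cross_truth.de_down,
        monotone_up=long_truth.monotone_up,
        monotone_down=long_truth.monotone_down,
    )
    return {
        "network": network,
        "cross_expression": cross_expr,
        "cross_metadata": cross_meta,
        "long_expression": long_expr,
        "long_metadata": long_meta,
        "truth": truth,
    }


def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Flatten a SyntheticTruth into a (gene_id, role, group) table."""
    rows = []
    for g in sorted(truth.de_up):
        rows.append((g, "de_up", ""))
    for g in sorted(truth.de_down):
        rows.append((g, "de_down", ""))
    for group in sorted(truth.monotone_up):
        for g in sorted(truth.monotone_up[group]):
            rows.append((g, "monotone_up", group))
    for group in sorted(truth.monotone_down):
        for g in sorted(truth.monotone_down[group]):
            rows.append((g, "monotone_down", group))
    return pd.DataFrame(rows, columns=["gene_id", "role", "group"])


def truth_from_frame(frame: pd.DataFrame) -> SyntheticTruth:
    """Inverse of :func:`truth_frame`."""
    de_up = frozenset(frame.loc[frame["role"] == "de_up", "gene_id"])
    de_down = frozenset(frame.loc[frame["role"] == "de_down", "gene_id"])
    mono_up: dict[str, frozenset] = {}
    mono_down: dict[str, frozenset] = {}
    for role, store in (("monotone_up", mono_up), ("monotone_down", mono_down)):
        sub = frame[frame["role"] == role]
        for group, part in sub.groupby("group"):
            store[str(group)] = frozenset(part["gene_id"])
    return SyntheticTruth(de_up=de_up, de_down=de_down, monotone_up=mono_up, monotone_down=mono_down)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of the configuration with a different seed."""
    return replace(config, seed=int(seed))
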