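"""Across-time screening and monotone-pattern detection.

Within one response group, each gene's weighted expression values are
compared across the ordered time points with a Kruskal-Wallis test;
Benjamini-Hochberg adjusted p-values below the threshold (default 0.1) flag
longitudinally differentially expressed genes. Among the flagged genes, a
monotonically expressed gene (MEG) is one whose per-timepoint mean weighted
expression forms a monotone chain:

    MIE (monotonically increasing): mean_1 <= mean_2 <= ... <= mean_T,
    MDE (monotonically decreasing): mean_1 >= mean_2 >= ... >= mean_T,

with at least one strict step, so an all-equal chain (which satisfies both
printed inequalities) is labelled ``none``. The Kruskal-Wallis test treats
the repeated measures per patient as independent groups, mirroring the
original screening procedure; it is rank-based, so strictly monotone
transformations of the values leave the statistic unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .errors import InputError

MIE = "MIE"
MDE = "MDE"
NONE = "none"

DEFAULT_ALPHA = 0.1


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H and its chi-square p for T >= 2 value collections.

    Uses mid-ranks with the standard tie correction; a fully tied input
    (zero rank variance) returns H = 0, p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InputError("Kruskal-Wallis needs at least two timepoint groups")
    if any(g.size == 0 for g in groups):
        raise InputError("empty timepoint group")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise InputError("Kruskal-Wallis needs at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def timepoint_means(ranks: pd.DataFrame, meta: pd.DataFrame, group: str) -> pd.DataFrame:
    """Per-gene mean weighted expression at each ordered time point.

    Returns genes x timepoints, columns sorted by time point order.
    """
    sub = meta[meta["group"] == group]
    if sub.empty:
        raise InputError(f"group {group!r} absent from metadata")
    if sub["timepoint"].isna().any():
        raise InputError(f"group {group!r} has samples without a timepoint")
    cols = [c for c in sub.index if c in ranks.columns]
    if len(cols) != len(sub):
        missing = sorted(set(sub.index) - set(ranks.columns))
        raise InputError(f"samples missing from the rank matrix: {missing[:5]}")
    by_tp = sub.loc[cols].groupby("timepoint", sort=True).groups
    means = {tp: ranks[list(samples)].mean(axis=1) for tp, samples in by_tp.items()}
    return pd.DataFrame(means).sort_index(axis=1)


def friedman(blocks: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square for a patients x timepoints block design.

    An alternative to Kruskal-Wallis that respects the pairing of repeated
    measures within a patient; requires every patient measured at every time
    point. Exposed for sensitivity analysis — the default screen ignores the
    pairing deliberately.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2 or blocks.shape[1] < 3:
        raise InputError("Friedman test needs a complete patients x timepoints block with T >= 3")
    if np.all(blocks == blocks.flat[0]):
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*[blocks[:, j] for j in range(blocks.shape[1])])
    return float(stat), float(p)


def screen_genes(
    ranks: pd.DataFrame,
    meta: pd.DataFrame,
    group: str,
    alpha: float = DEFAULT_ALPHA,
    method: str = "kruskal",
) -> pd.DataFrame:
    """Across-time test for every gene of one group.

    ``method="kruskal"`` (default) treats time points as independent groups;
    ``method="friedman"`` blocks on patient (needs complete, balanced
    sampling). BH adjustment is computed over exactly the genes tested
    within this group. Returns a gene-indexed frame with
    ``H, p, adj_p, flagged``.
    """
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must be in (0, 1)")
    if method not in ("kruskal", "friedman"):
        raise InputError("method must be 'kruskal' or 'friedman'")
    sub = meta[meta["group"] == group]
    if sub.empty:
        raise InputError(f"group {group!r} absent from metadata")
    if sub["timepoint"].isna().any():
        raise InputError(f"group {group!r} has samples without a timepoint")
    cols = [c for c in sub.index if c in ranks.columns]
    if len(cols) != len(sub):
        missing = sorted(set(sub.index) - set(ranks.columns))
        raise InputError(f"samples missing from the rank matrix: {missing[:5]}")

    timepoints = sorted(sub["timepoint"].unique())
    h_stats = np.empty(len(ranks.index))
    raw_p = np.empty(len(ranks.index))

    if method == "kruskal":
        sample_sets = [list(sub.index[sub["timepoint"] == tp]) for tp in timepoints]
        values = {tp: ranks[s].to_numpy() for tp, s in zip(timepoints, sample_sets)}
        for i in range(len(ranks.index)):
            h_stats[i], raw_p[i] = kruskal_wallis([values[tp][i] for tp in timepoints])
    else:
        patients = sorted(sub["patient_id"].unique())
        ordered = []
        for tp in timepoints:
            by_patient = sub[sub["timepoint"] == tp].reset_index().set_index("patient_id")["sample_id"]
            if sorted(by_patient.index) != patients:
                raise InputError("Friedman screen requires every patient at every time point")
            ordered.append(ranks[by_patient.loc[patients].tolist()].to_numpy())
        blocks = np.stack(ordered, axis=2)  # genes x patients x timepoints
        for i in range(len(ranks.index)):
            h_stats[i], raw_p[i] = friedman(blocks[i])

    adj = benjamini_hochberg(raw_p)
    return pd.DataFrame(
        {"H": h_stats, "p": raw_p, "adj_p": adj, "flagged": adj < alpha},
        index=ranks.index.copy(),
    )


def monotone_pattern(means, tolerance: float = 0.0) -> str:
    """Classify a chain of per-timepoint means as MIE, MDE or none.

    MIE: every consecutive difference >= -tolerance and at least one
    difference > tolerance; MDE symmetric. A chain with no step beyond the
    tolerance (in particular an all-equal chain) is ``none``.
    """
    means = np.asarray(means, dtype=float)
    if means.size < 2:
        raise InputError("need at least two timepoint means")
    if not np.all(np.isfinite(means)):
        raise InputError("non-finite timepoint mean")
    if tolerance < 0:
        raise InputError("tolerance must be nonnegative")
    diffs = np.diff(means)
    if np.all(diffs >= -tolerance) and np.any(diffs > tolerance):
        return MIE
    if np.all(diffs <= tolerance) and np.any(diffs < -tolerance):
        return MDE
    return NONE


def find_megs(
    screen: pd.DataFrame,
    ranks: pd.DataFrame,
    meta: pd.DataFrame,
    group: str,
    tolerance: float = 0.0,
) -> pd.DataFrame:
    """Monotone filter applied only to the genes flagged by the screen.

    Returns a gene-indexed frame with ``pattern`` (MIE/MDE) and
    ``direction`` (up for MIE, down for MDE), sorted by gene identifier.
    """
    flagged = screen.index[screen["flagged"]]
    if len(flagged) == 0:
        return pd.DataFrame(columns=["pattern", "direction"], index=pd.Index([], name=ranks.index.name))
    means = timepoint_means(ranks.loc[flagged], meta, group)
    rows = {}
    for gene in flagged:
        pattern = monotone_pattern(means.loc[gene].to_numpy(), tolerance)
        if pattern != NONE:
            rows[gene] = (pattern, "up" if pattern == MIE else "down")
    result = pd.DataFrame.from_dict(rows, orient="index", columns=["pattern", "direction"])
    result.index.name = ranks.index.name
    return result.sort_index()
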