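"""Cross-sectional differential expression with empirical-Bayes moderation.

The two-group contrast uses a moderated t-statistic: per-gene pooled sample
variances are shrunk toward a common prior variance ``s0^2`` with prior
degrees of freedom ``d0``, both estimated by moment matching on the log
sample variances. The moderated statistic

    t_g = (mean_1 - mean_2) / ( s~_g * sqrt(1/n1 + 1/n2) ),
    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

is referred to a t distribution with ``d0 + d_g`` degrees of freedom. When
the spread of the log variances does not exceed its expected sampling value,
``d0`` is infinite and every gene is tested against the common variance.

Multiple testing is controlled with the Benjamini-Hochberg step-up
procedure; genes with adjusted p below the cutoff (default 0.1) form the
DEG set, partitioned into up/down by the sign of the mean difference
(first contrast group minus second).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class EBayesHyperparams:
    """Moment-matched prior for the gene-wise variances."""

    prior_df: float      # d0, may be math.inf
    prior_var: float     # s0^2

    def __post_init__(self):
        if not self.prior_df > 0:
            raise InputError("prior degrees of freedom must be positive")
        if not self.prior_var > 0:
            raise InputError("prior variance must be positive")


def trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is positive, decreasing and convex on (0, inf), so Newton from
    the asymptotic start x = 0.5 + 1/y converges monotonically.
    """
    if y <= 0:
        raise InputError("trigamma_inverse requires a positive argument")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-8:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_ebayes_hyperparams(s2: np.ndarray, df_resid: int) -> EBayesHyperparams:
    """Moment-match (d0, s0^2) on z_g = log s_g^2.

    With s_g^2 ~ s0^2 * F(d, d0), E[z] = log s0^2 + psi(d/2) - log(d/2)
    - psi(d0/2) + log(d0/2) and Var[z] = psi'(d/2) + psi'(d0/2). Genes with
    zero sample variance are excluded from estimation (their log variance is
    undefined) but still receive a moderated variance. Fewer than four
    informative genes, or no excess spread in z, collapse to d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    d = float(df_resid)
    offset = float(special.digamma(d / 2.0)) - math.log(d / 2.0)

    if positive.sum() <= 3:
        logger.info("ebayes: <= 3 informative genes; using d0 = inf")
        pooled = float(s2[positive].mean()) if positive.any() else float(np.finfo(float).tiny)
        return EBayesHyperparams(math.inf, max(pooled, float(np.finfo(float).tiny)))

    e = np.log(s2[positive]) - offset
    excess = float(np.var(np.log(s2[positive]), ddof=1)) - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        logger.info("ebayes: no excess variance in log s^2; using d0 = inf")
        return EBayesHyperparams(math.inf, math.exp(float(e.mean())))

    d0 = 2.0 * trigamma_inverse(excess)
    log_s02 = float(e.mean()) + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    return EBayesHyperparams(d0, math.exp(log_s02))


def moderate_variances(s2: np.ndarray, df_resid: int, hyper: EBayesHyperparams) -> np.ndarray:
    """Posterior (shrunken) variances s~_g^2."""
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(hyper.prior_df):
        return np.full_like(s2, hyper.prior_var)
    d0, d = hyper.prior_df, float(df_resid)
    return (d0 * hyper.prior_var + d * s2) / (d0 + d)


def fit_moderated_t(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str] = ("case", "control"),
    *,
    moderate: bool = True,
    hyper: EBayesHyperparams | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test between the two contrast groups.

    Parameters
    ----------
    expr
        Genes x samples log2 expression, gene ids on the index.
    meta
        Sample table indexed by sample id, with a ``group`` column.
    contrast
        ``(group1, group2)``; mean differences are group1 minus group2.
    moderate
        With ``False`` the ordinary pooled-variance (Student) t is used
        instead of the empirical-Bayes statistic, for diagnostics.
    hyper
        Explicit hyperparameters; estimated from the data when omitted.

    Returns a gene-indexed frame with columns ``mean_diff, s2, df_resid,
    s2_mod, t, p, adj_p, direction`` and the fitted hyperparameters in
    ``.attrs["ebayes"]``.
    """
    g1, g2 = contrast
    cols1 = meta.index[meta["group"] == g1]
    cols2 = meta.index[meta["group"] == g2]
    if len(cols1) == 0 or len(cols2) == 0:
        raise InputError(f"contrast group missing from metadata: {g1!r} or {g2!r}")
    if len(cols1) < 2 or len(cols2) < 2:
        raise InputError("each contrast group needs at least 2 samples")
    missing = set(cols1).union(cols2) - set(expr.columns)
    if missing:
        raise InputError(f"samples in metadata but not in expression: {sorted(missing)[:5]}")

    x1 = expr[cols1].to_numpy(dtype=float)
    x2 = expr[cols2].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2

    mean_diff = x1.mean(axis=1) - x2.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d

    if moderate:
        if hyper is None:
            hyper = estimate_ebayes_hyperparams(s2, d)
        s2_mod = moderate_variances(s2, d, hyper)
        df_total = hyper.prior_df + d
    else:
        hyper = None
        s2_mod = s2
        df_total = float(d)

    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_diff / np.where(se > 0, se, 1.0), np.where(mean_diff == 0, 0.0, np.sign(mean_diff) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, 0.0, 1.0)

    result = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "s2": s2,
            "df_resid": d,
            "s2_mod": s2_mod,
            "t": t,
            "p": p,
            "adj_p": benjamini_hochberg(p),
            "direction": np.where(mean_diff > 0, "up", "down"),
        },
        index=expr.index.copy(),
    )
    result.attrs["ebayes"] = hyper
    return result


def benjamini_hochberg(raw_p) -> np.ndarray:
    """Step-up FDR adjustment, returned in the input order."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Genes with adjusted p below ``alpha``, ordered by gene identifier.

    The returned frame keeps ``mean_diff``, ``adj_p`` and ``direction``
    (up = overexpressed in the first contrast group).
    """
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must be in (0, 1)")
    selected = results.loc[results["adj_p"] < alpha, ["mean_diff", "adj_p", "direction"]]
    return selected.sort_index()
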