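"""Univariate statistics, the joint VIP/p/FC metabolite screen,
hierarchical-clustering ordering, and hypergeometric pathway
over-representation.

Intensity matrices follow the on-disk orientation (metabolites x
samples, header row of sample ids) and are transposed internally where
an estimator expects samples x features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator

from .exceptions import InputError
from .plsda import PLSDA, vip_scores

__all__ = [
    "univariate_stats",
    "screen_metabolites",
    "MetaboliteScreen",
    "hclust_heatmap_order",
    "ora_enrichment",
]

logger = logging.getLogger(__name__)


def _split_groups(
    X: pd.DataFrame, groups: pd.Series, treated: str, control: str
) -> tuple[np.ndarray, np.ndarray]:
    groups = pd.Series(groups)
    for g in (treated, control):
        if g not in set(groups):
            raise InputError(f"group label {g!r} absent from group map")
    t_cols = groups.index[groups == treated]
    c_cols = groups.index[groups == control]
    missing = set(t_cols).union(c_cols) - set(X.columns)
    if missing:
        raise InputError(f"samples missing from intensity matrix: {sorted(missing)}")
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise InputError("need >= 2 samples per group")
    return X[t_cols].to_numpy(dtype=float), X[c_cols].to_numpy(dtype=float)


def univariate_stats(
    X: pd.DataFrame,
    groups: pd.Series,
    treated: str = "treated",
    control: str = "control",
) -> pd.DataFrame:
    """Welch t-test p, fold change (treated mean / control mean) and trend
    per metabolite. X is metabolites x samples."""
    t_arr, c_arr = _split_groups(X, groups, treated, control)
    c_mean = c_arr.mean(axis=1)
    if (c_mean == 0).any():
        bad = X.index[c_mean == 0][:5].tolist()
        raise InputError(f"fold change undefined: zero control mean for {bad}")
    fc = t_arr.mean(axis=1) / c_mean
    p = stats.ttest_ind(t_arr, c_arr, axis=1, equal_var=False).pvalue
    return pd.DataFrame(
        {
            "p_value": np.asarray(p, dtype=float),
            "fc": fc,
            "trend": np.where(fc > 1, "up", "down"),
        },
        index=X.index.rename("metabolite"),
    )


def screen_metabolites(
    stats_table: pd.DataFrame,
    vip: pd.Series,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    fc_theta: float = 1.0,
    fc_mode: str = "two-sided",
) -> pd.DataFrame:
    """Apply the joint VIP / p / fold-change screen.

    ``passes`` requires ``vip > vip_threshold`` and ``p < p_threshold``
    and the fold-change criterion: two-sided by default
    (``fc > fc_theta`` or ``fc < 1/fc_theta``), or the literal one-sided
    rule (``fc > fc_theta``) with ``fc_mode="greater"``. The two-sided
    default keeps down-regulated metabolites, matching how published
    screens retain FC < 1 entries.
    """
    vip = pd.Series(vip)
    if set(stats_table.index) != set(vip.index):
        raise InputError("stats table and VIP scores are not aligned on ids")
    if fc_mode not in ("two-sided", "greater"):
        raise InputError(f"unknown fc_mode {fc_mode!r}")
    out = stats_table.copy()
    out.insert(0, "vip", vip.reindex(out.index))
    fc = out["fc"].to_numpy()
    if fc_mode == "two-sided":
        fc_ok = (fc > fc_theta) | (fc < 1.0 / fc_theta)
    else:
        fc_ok = fc > fc_theta
    out["passes"] = (
        (out["vip"].to_numpy() > vip_threshold)
        & (out["p_value"].to_numpy() < p_threshold)
        & fc_ok
    )
    return out


class MetaboliteScreen(BaseEstimator):
    """Joint multivariate + univariate differential-metabolite screen.

    Fits a PLS-DA model on the intensity matrix, scores VIP per
    metabolite, computes Welch-t p and fold change, and flags metabolites
    passing all three thresholds.

    Parameters mirror :func:`screen_metabolites`; ``n_components`` and
    ``scale`` are passed to the underlying :class:`~herbnet.plsda.PLSDA`.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Columns ``vip, p_value, fc, trend, passes`` per metabolite.
    model_ : PLSDA
        The fitted multivariate model.
    n_up_, n_down_ : int
        Counts of passing metabolites with fc > 1 / fc < 1.
    """

    def __init__(
        self,
        vip_threshold: float = 1.0,
        p_threshold: float = 0.05,
        fc_theta: float = 1.0,
        fc_mode: str = "two-sided",
        n_components: int = 2,
        scale: bool = True,
        treated: str = "treated",
        control: str = "control",
    ):
        self.vip_threshold = vip_threshold
        self.p_threshold = p_threshold
        self.fc_theta = fc_theta
        self.fc_mode = fc_mode
        self.n_components = n_components
        self.scale = scale
        self.treated = treated
        self.control = control

    def fit(self, X: pd.DataFrame, groups: pd.Series):
        stats_table = univariate_stats(X, groups, self.treated, self.control)
        groups = pd.Series(groups)
        cols = groups.index[groups.isin([self.treated, self.control])]
        self.model_ = PLSDA(n_components=self.n_components, scale=self.scale).fit(
            X[cols].T, groups.loc[cols]
        )
        vip = pd.Series(vip_scores(self.model_), index=X.index)
        self.results_ = screen_metabolites(
            stats_table,
            vip,
            vip_threshold=self.vip_threshold,
            p_threshold=self.p_threshold,
            fc_theta=self.fc_theta,
            fc_mode=self.fc_mode,
        )
        passing = self.results_[self.results_["passes"]]
        self.n_up_ = int((passing["fc"] > 1).sum())
        self.n_down_ = int((passing["fc"] < 1).sum())
        return self


def hclust_heatmap_order(X: pd.DataFrame) -> dict:
    """Deterministic average-linkage clustering orders for a heatmap.

    Metabolite rows are z-scored (mean 0, SD 1); zero-variance rows are
    excluded with a warning. Returns ``{"z": z-scored DataFrame,
    "row_order": [...], "col_order": [...]}`` with leaf orders from
    average-linkage Euclidean dendrograms.
    """
    if len(X) < 2:
        raise InputError("need >= 2 metabolite rows to cluster")
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning(
            "excluding %d zero-variance metabolite(s) from clustering",
            int((~keep).sum()),
        )
    Xk = X.loc[keep]
    z = Xk.sub(Xk.mean(axis=1), axis=0).div(Xk.std(axis=1, ddof=1), axis=0)
    row_idx = leaves_list(linkage(z.to_numpy(), method="average", metric="euclidean"))
    col_idx = leaves_list(
        linkage(z.to_numpy().T, method="average", metric="euclidean")
    )
    return {
        "z": z,
        "row_order": [z.index[i] for i in row_idx],
        "col_order": [z.columns[i] for i in col_idx],
    }


def ora_enrichment(
    hits,
    universe,
    pathways: dict,
    correct: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway.

    For a pathway of size K in a universe of size N with n hits of which
    k fall in the pathway, p = P(X >= k) under Hypergeometric(N, K, n).
    ``correct=True`` adds a Benjamini-Hochberg ``p_adj`` column.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise InputError("hits must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name in sorted(pathways):
        members = set(pathways[name])
        if not members <= universe:
            raise InputError(f"pathway {name!r} is not a subset of the universe")
        K = len(members)
        k = len(hits & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": name, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if correct and len(out):
        out["p_adj"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out
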