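"""Differential-expression screen: Wilcoxon rank-sum p with a log2
fold-change filter.

The screen flags gene *g* when ``p < p_threshold`` and
``|log2FC| > fc_threshold`` (strict inequalities). No multiple-testing
correction is applied by default; an optional Benjamini-Hochberg switch
is provided for reuse.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import InputError

__all__ = [
    "wilcoxon_rank_sum",
    "log2_fold_change",
    "screen_degs",
    "DifferentialExpressionScreen",
]

_EXACT_LIMIT = 16


@lru_cache(maxsize=None)
def _index_combinations(n_total: int, n_x: int) -> np.ndarray:
    """All C(n_total, n_x) index subsets as an integer array."""
    return np.array(list(combinations(range(n_total), n_x)), dtype=np.intp)


def _exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p for the rank-sum statistic.

    Enumerates every assignment of the pooled midranks to the x-group and
    counts assignments at least as extreme (|W - E[W]|) as observed.
    Handles ties through midranks, so it agrees with the tie-corrected
    normal approximation in the large-sample limit.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n_x = len(x)
    w_obs = ranks[:n_x].sum()
    mu = n_x * (len(pooled) + 1) / 2.0
    combos = _index_combinations(len(pooled), n_x)
    w_all = ranks[combos].sum(axis=1)
    # small epsilon guards float jitter in midrank sums
    extreme = np.abs(w_all - mu) >= np.abs(w_obs - mu) - 1e-9
    return float(extreme.sum() / len(w_all))


def wilcoxon_rank_sum(x, y, mode: str = "normal") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Parameters
    ----------
    x, y : array-like
        Non-empty sample vectors.
    mode : {"normal", "exact"}
        ``"exact"`` enumerates all rank assignments (requires
        ``len(x)+len(y) <= 16``); ``"normal"`` uses the tie-corrected
        normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both sample vectors must be non-empty")
    if mode == "exact":
        if x.size + y.size > _EXACT_LIMIT:
            raise InputError(
                f"exact mode supports n_x+n_y <= {_EXACT_LIMIT}; "
                "use mode='normal' for larger samples"
            )
        return _exact_p(x, y)
    if mode != "normal":
        raise InputError(f"unknown mode {mode!r}; expected 'exact' or 'normal'")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def log2_fold_change(x, y, pseudocount: float = 0.0) -> float:
    """log2 of the ratio of group means, with an optional pseudocount.

    ``log2((mean(x)+c) / (mean(y)+c))``; raises when both means and the
    pseudocount are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    if (x < 0).any() or (y < 0).any():
        raise InputError("values must be non-negative")
    mx, my = x.mean() + pseudocount, y.mean() + pseudocount
    if mx == 0.0 or my == 0.0:
        raise InputError(
            "fold change undefined: zero group mean with zero pseudocount"
        )
    return float(np.log2(mx / my))


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise InputError("sample with zero library size")
    return counts.div(lib, axis=1) * 1e6


class DifferentialExpressionScreen(BaseEstimator):
    """Per-gene Wilcoxon rank-sum + log2FC screen between two groups.

    Parameters
    ----------
    p_threshold : float, default 0.05
        Flag genes with ``p < p_threshold`` (strict).
    fc_threshold : float, default 2.0
        Flag genes with ``|log2FC| > fc_threshold`` (strict).
    normalize : {"cpm", "none"}, default "cpm"
        Library-size normalisation applied before testing and fold change.
    pseudocount : float, default 1.0
        Added to both group means in the fold-change ratio.
    group_a, group_b : str, default "tumor", "normal"
        Labels of the numerator and denominator groups.
    correct : {None, "bh"}, default None
        Optional Benjamini-Hochberg adjustment; flagging then uses the
        adjusted p-values.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per gene: ``log2fc, p_value, is_deg, direction``
        (volcano-plot-ready), indexed by gene id.
    """

    def __init__(
        self,
        p_threshold: float = 0.05,
        fc_threshold: float = 2.0,
        normalize: str = "cpm",
        pseudocount: float = 1.0,
        group_a: str = "tumor",
        group_b: str = "normal",
        correct: str | None = None,
    ):
        self.p_threshold = p_threshold
        self.fc_threshold = fc_threshold
        self.normalize = normalize
        self.pseudocount = pseudocount
        self.group_a = group_a
        self.group_b = group_b
        self.correct = correct

    def fit(self, counts: pd.DataFrame, groups: pd.Series):
        groups = pd.Series(groups)
        for g in (self.group_a, self.group_b):
            if g not in set(groups):
                raise InputError(f"group label {g!r} absent from group map")
        a_cols = groups.index[groups == self.group_a]
        b_cols = groups.index[groups == self.group_b]
        missing = set(a_cols).union(b_cols) - set(counts.columns)
        if missing:
            raise InputError(f"samples missing from count matrix: {sorted(missing)}")
        if len(a_cols) < 2 or len(b_cols) < 2:
            raise InputError("need >= 2 samples per group")

        if self.normalize == "cpm":
            mat = _cpm(counts)
        elif self.normalize == "none":
            mat = counts.astype(float)
        else:
            raise InputError(f"unknown normalize mode {self.normalize!r}")

        a = mat[a_cols].to_numpy()
        b = mat[b_cols].to_numpy()
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
        p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
        lfc = np.log2(
            (a.mean(axis=1) + self.pseudocount) / (b.mean(axis=1) + self.pseudocount)
        )

        p_for_flag = p
        out = pd.DataFrame(
            {"log2fc": lfc, "p_value": p}, index=counts.index.rename("gene_id")
        )
        if self.correct == "bh":
            out["p_adj"] = stats.false_discovery_control(p, method="bh")
            p_for_flag = out["p_adj"].to_numpy()
        elif self.correct is not None:
            raise InputError(f"unknown correction {self.correct!r}")

        out["is_deg"] = (p_for_flag < self.p_threshold) & (
            np.abs(lfc) > self.fc_threshold
        )
        out["direction"] = np.where(
            ~out["is_deg"], "none", np.where(lfc > 0, "up", "down")
        )
        self.results_ = out
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        """Return the screened table (alias for ``results_`` after fit)."""
        if not hasattr(self, "results_"):
            raise InputError("screen not fitted")
        return self.results_


def screen_degs(
    counts: pd.DataFrame,
    groups: pd.Series,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    normalize: str = "cpm",
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper around :class:`DifferentialExpressionScreen`."""
    screen = DifferentialExpressionScreen(
        p_threshold=p_threshold,
        fc_threshold=fc_threshold,
        normalize=normalize,
        **kwargs,
    )
    return screen.fit(counts, groups).results_
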