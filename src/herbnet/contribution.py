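"""Network contribution index (CI) over a component-target network.

For each compound *i* in the bipartite C-T network, with C_i its degree,
T_edge the total edge count, CA_i/CB_i its herb-attributed degrees and
P_j the degree of target *j*:

    omega_i = C_i / T_edge                         (edge share)
    A_i     = omega_i + |(CA_i + CB_i)/(CA_i - CB_i)|   (affinity)
    NE_i    = C_i * A_i * sum_{j ~ i} P_j          (network effect)
    CI_i    = 100 * (NE_i/sum NE + C_i/sum C) / 2  (percent, sums to 100)

When CA_i = CB_i the affinity ratio is degenerate; it is replaced by
CA_i + CB_i (finite, monotone in shared degree) and logged. The default
CI normalisation averages the two shares so CI is a percentage summing
to 100; a "literal" mode reproducing the unnormalised linear reading
(NE share plus 100x degree share) is available for comparison.

Ranking is by descending CI with lexicographic component-id tie-breaks;
cumulative CI accumulates in rank order, so the contribution of the top
k compounds is one table lookup.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError
from .network import CTNetwork

__all__ = [
    "compute_omega",
    "compute_affinity",
    "compute_ne",
    "compute_ci",
    "top_k_cumulative",
]

logger = logging.getLogger(__name__)

CI_MODES = ("balanced", "literal")


def compute_omega(net: CTNetwork, component_id: str) -> float:
    """Edge share omega_i = C_i / T_edge, in (0, 1]."""
    if net.tedge == 0:
        raise InputError("empty network: T_edge = 0")
    if component_id not in net.ci:
        raise InputError(f"unknown component {component_id!r}")
    return net.ci[component_id] / net.tedge


def compute_affinity(net: CTNetwork, component_id: str) -> float:
    """Affinity A_i = omega_i + |(CA_i+CB_i)/(CA_i-CB_i)|.

    For a single-herb compound the ratio is exactly 1, so A_i =
    omega_i + 1. The degenerate CA_i = CB_i case (dual-herb compound
    with equal attribution) replaces the ratio by CA_i + CB_i.
    """
    ca, cb = net.ca[component_id], net.cb[component_id]
    if ca + cb == 0:
        raise InputError(f"component {component_id!r} has no herb-attributed degree")
    omega = compute_omega(net, component_id)
    if ca == cb:
        logger.info(
            "degenerate affinity denominator for %s (CA=CB=%d): using CA+CB",
            component_id,
            ca,
        )
        ratio = float(ca + cb)
    else:
        ratio = abs((ca + cb) / (ca - cb))
    return omega + ratio


def compute_ne(net: CTNetwork, component_id: str) -> float:
    """Network effect NE_i = C_i * A_i * sum of P_j over i's targets."""
    if net.ci.get(component_id, 0) < 1:
        raise InputError(f"component {component_id!r} has no targets")
    p_sum = sum(net.pj[t] for t in net.targets_of(component_id))
    return net.ci[component_id] * compute_affinity(net, component_id) * p_sum


def compute_ci(net: CTNetwork, mode: str = "balanced") -> pd.DataFrame:
    """Score, rank and accumulate the contribution index of every compound.

    Returns a DataFrame sorted by rank with columns ``component_id,
    omega_e, affinity, ne, ci, rank, cumulative_ci``. In the default
    "balanced" mode the ci column sums to exactly 100.
    """
    if mode not in CI_MODES:
        raise ParameterError(f"unknown CI mode {mode!r}; expected one of {CI_MODES}")
    if net.tedge == 0 or not net.components:
        raise InputError("cannot score an empty network")

    ids = sorted(net.components)
    omega = np.array([compute_omega(net, c) for c in ids])
    affinity = np.array([compute_affinity(net, c) for c in ids])
    ne = np.array([compute_ne(net, c) for c in ids])
    deg = np.array([net.ci[c] for c in ids], dtype=float)

    ne_share = ne / ne.sum()
    deg_share = deg / deg.sum()
    if mode == "balanced":
        ci = 100.0 * (ne_share + deg_share) / 2.0
    else:  # literal linear reading: NE share plus 100x degree share
        ci = ne_share + deg_share * 100.0

    out = pd.DataFrame(
        {
            "component_id": ids,
            "omega_e": omega,
            "affinity": affinity,
            "ne": ne,
            "ci": ci,
        }
    )
    out = out.sort_values(
        ["ci", "component_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["cumulative_ci"] = out["ci"].cumsum()
    return out


def top_k_cumulative(results: pd.DataFrame, k: int) -> float:
    """Summed CI (percent) of the k top-ranked compounds."""
    n = len(results)
    if not 1 <= k <= n:
        raise ParameterError(f"k must lie in [1, {n}], got {k}")
    return float(results.sort_values("rank").iloc[:k]["ci"].sum())
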