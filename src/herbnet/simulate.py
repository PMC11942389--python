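"""Seeded generators for the three synthetic inputs the pipeline consumes.

Each generator mirrors the statistical structure its downstream stage
assumes: negative-binomial RNA-seq-like counts with planted fold-change
genes, a two-herb bipartite component-target network with one planted
high-degree "core" component, and strictly positive log-normal metabolite
intensities with planted group differences. Truth sets are returned with
the data so recovery can be scored.

All randomness flows from the explicit ``seed`` field of each spec; no
global RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "CountSimSpec",
    "NetworkSimSpec",
    "MetaboSimSpec",
    "gen_counts",
    "gen_ct_network",
    "gen_metabolites",
]


@dataclass(frozen=True)
class CountSimSpec:
    """Parameters for a tumor-vs-normal RNA-seq count simulation.

    Counts are gamma-Poisson (negative binomial) with variance
    ``mu + dispersion * mu**2``; ``n_deg`` genes get their tumor-group mean
    multiplied by ``2**planted_log2fc``.
    """

    n_genes: int = 500
    n_tumor: int = 20
    n_normal: int = 20
    n_deg: int = 20
    planted_log2fc: float = 3.0
    dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (10.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_tumor <= 0 or self.n_normal <= 0:
            raise ParameterError("n_genes, n_tumor and n_normal must be positive")
        if not 0 <= self.n_deg <= self.n_genes:
            raise ParameterError("n_deg must lie in [0, n_genes]")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be positive")
        lo, hi = self.base_mean_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ParameterError("base_mean_range must be positive and ordered")


@dataclass(frozen=True)
class NetworkSimSpec:
    """Parameters for a two-herb bipartite component-target network.

    One designated core component receives exactly
    ``core_component_degree`` distinct targets; every background component
    draws its degree from a Poisson(``background_degree_mean``) truncated
    at >= 1, so no component is isolated. OB/DL values are assigned so
    that ``ob_dl_pass_fraction`` of components pass the ADME filter
    (OB >= 30, DL >= 0.18); the core always passes.
    """

    n_components_A: int = 18
    n_components_B: int = 18
    n_targets: int = 60
    core_component_degree: int = 15
    background_degree_mean: float = 3.0
    ob_dl_pass_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components_A < 0 or self.n_components_B < 0:
            raise ParameterError("component counts must be non-negative")
        if self.n_components_A + self.n_components_B < 1:
            raise ParameterError("need at least one component")
        if self.n_targets <= 0:
            raise ParameterError("n_targets must be positive")
        if self.core_component_degree <= 0:
            raise ParameterError("core_component_degree must be positive")
        if self.core_component_degree > self.n_targets:
            raise ParameterError(
                "core_component_degree cannot exceed n_targets "
                f"({self.core_component_degree} > {self.n_targets})"
            )
        if self.background_degree_mean <= 0:
            raise ParameterError("background_degree_mean must be positive")
        if self.core_component_degree <= self.background_degree_mean:
            raise ParameterError(
                "core_component_degree must exceed background_degree_mean"
            )
        if not 0.0 <= self.ob_dl_pass_fraction <= 1.0:
            raise ParameterError("ob_dl_pass_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class MetaboSimSpec:
    """Parameters for a treated-vs-control metabolite intensity simulation.

    Intensities are multiplicative log-normal around a per-metabolite base
    level with coefficient of variation ``cv_noise``; ``n_diff``
    metabolites get their treated-group mean multiplied by ``planted_fc``.
    """

    n_metabolites: int = 200
    n_per_group: int = 10
    n_diff: int = 10
    planted_fc: float = 4.0
    cv_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metabolites <= 0 or self.n_per_group <= 0:
            raise ParameterError("n_metabolites and n_per_group must be positive")
        if not 0 <= self.n_diff <= self.n_metabolites:
            raise ParameterError("n_diff must lie in [0, n_metabolites]")
        if self.planted_fc <= 0:
            raise ParameterError("planted_fc must be positive")
        if math.isclose(self.planted_fc, 1.0):
            raise ParameterError("planted_fc must differ from 1")
        if self.cv_noise <= 0:
            raise ParameterError("cv_noise must be positive")


def gen_counts(spec: CountSimSpec) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Simulate a gene x sample count matrix with planted DEGs.

    Returns ``(counts, groups, truth)`` where *counts* is an integer
    DataFrame (genes x samples), *groups* maps sample id to
    ``"tumor"``/``"normal"``, and *truth* lists the planted gene ids.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    lo, hi = spec.base_mean_range
    base = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=n)

    planted_idx = np.sort(rng.choice(n, size=spec.n_deg, replace=False))
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    truth = [gene_ids[i] for i in planted_idx]

    mu_normal = base.copy()
    mu_tumor = base.copy()
    mu_tumor[planted_idx] *= 2.0 ** spec.planted_log2fc

    shape = 1.0 / spec.dispersion

    def _nb(mu: np.ndarray, n_samples: int) -> np.ndarray:
        lam = rng.gamma(shape, mu[:, None] / shape, size=(len(mu), n_samples))
        return rng.poisson(lam)

    tumor = _nb(mu_tumor, spec.n_tumor)
    normal = _nb(mu_normal, spec.n_normal)

    samples = [f"T{i + 1:03d}" for i in range(spec.n_tumor)] + [
        f"N{i + 1:03d}" for i in range(spec.n_normal)
    ]
    counts = pd.DataFrame(
        np.hstack([tumor, normal]), index=gene_ids, columns=samples, dtype=np.int64
    )
    groups = pd.Series(
        ["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal,
        index=samples,
        name="group",
    )
    return counts, groups, truth


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1, drawn by rejection."""
    out = rng.poisson(mean, size=size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(mean, size=int(zero.sum()))


def gen_ct_network(
    spec: NetworkSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Simulate a component table and component-target edge list.

    Returns ``(components, edges, core_id)``. *components* has columns
    ``component_id, herb, ob, dl``; *edges* has columns
    ``component_id, target_id``. The core component sits in herb A when
    herb A has any components, otherwise herb B, and always passes the
    OB/DL filter.
    """
    rng = np.random.default_rng(spec.seed)
    comp_ids = [f"A{i + 1:03d}" for i in range(spec.n_components_A)] + [
        f"B{i + 1:03d}" for i in range(spec.n_components_B)
    ]
    herbs = ["A"] * spec.n_components_A + ["B"] * spec.n_components_B
    target_ids = np.array([f"t{j + 1:03d}" for j in range(spec.n_targets)])
    core_id = comp_ids[0]

    n_comp = len(comp_ids)
    degrees = np.minimum(
        _truncated_poisson(rng, spec.background_degree_mean, n_comp),
        spec.n_targets,
    )
    degrees[0] = spec.core_component_degree

    rows = []
    for cid, deg in zip(comp_ids, degrees):
        chosen = rng.choice(spec.n_targets, size=int(deg), replace=False)
        for j in np.sort(chosen):
            rows.append((cid, target_ids[j]))
    edges = pd.DataFrame(rows, columns=["component_id", "target_id"])

    n_pass = max(1, int(round(spec.ob_dl_pass_fraction * n_comp)))
    order = rng.permutation(n_comp)
    passing = set(order[:n_pass].tolist())
    passing.add(0)  # core always passes

    ob = np.empty(n_comp)
    dl = np.empty(n_comp)
    for i in range(n_comp):
        if i in passing:
            ob[i] = rng.uniform(30.0, 100.0)
            dl[i] = rng.uniform(0.18, 1.0)
        else:
            # fail at least one criterion, chosen at random
            which = rng.integers(3)
            ob[i] = rng.uniform(1.0, 29.0) if which in (0, 2) else rng.uniform(30.0, 100.0)
            dl[i] = rng.uniform(0.01, 0.17) if which in (1, 2) else rng.uniform(0.18, 1.0)

    components = pd.DataFrame(
        {
            "component_id": comp_ids,
            "herb": herbs,
            "ob": np.round(ob, 3),
            "dl": np.round(dl, 4),
        }
    )
    return components, edges, core_id


def gen_metabolites(
    spec: MetaboSimSpec,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Simulate a metabolite x sample intensity matrix with planted shifts.

    Returns ``(intensities, groups, truth)``. Intensities are strictly
    positive; planted metabolites have treated/control mean ratio equal to
    ``planted_fc`` in expectation (log-normal noise is drawn with mean
    correction ``-sigma**2/2`` so arithmetic group means hit their
    targets exactly).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_metabolites
    base = 10.0 ** rng.uniform(4.0, 7.0, size=n)

    planted_idx = np.sort(rng.choice(n, size=spec.n_diff, replace=False))
    met_ids = [f"m{i + 1:04d}" for i in range(n)]
    truth = [met_ids[i] for i in planted_idx]

    mu_control = base.copy()
    mu_treated = base.copy()
    mu_treated[planted_idx] *= spec.planted_fc

    sigma = math.sqrt(math.log1p(spec.cv_noise**2))

    def _lognormal(mu: np.ndarray, n_samples: int) -> np.ndarray:
        noise = rng.normal(-0.5 * sigma**2, sigma, size=(len(mu), n_samples))
        return mu[:, None] * np.exp(noise)

    treated = _lognormal(mu_treated, spec.n_per_group)
    control = _lognormal(mu_control, spec.n_per_group)

    samples = [f"F{i + 1:03d}" for i in range(spec.n_per_group)] + [
        f"C{i + 1:03d}" for i in range(spec.n_per_group)
    ]
    intensities = pd.DataFrame(
        np.hstack([treated, control]), index=met_ids, columns=samples
    )
    groups = pd.Series(
        ["treated"] * spec.n_per_group + ["control"] * spec.n_per_group,
        index=samples,
        name="group",
    )
    return intensities, groups, truth
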