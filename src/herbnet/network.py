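"""ADME filtering, bipartite component-target network construction, and
target/disease-gene intersection.

A component-target (C-T) network links herbal compounds from a two-herb
formula (herb A and herb B) to their predicted protein targets. The
degree bookkeeping here — per-component degree C_i, per-target degree
P_j, and the herb-attributed degrees CA_i / CB_i — feeds the
contribution-index scoring in :mod:`herbnet.contribution`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .exceptions import InputError

__all__ = [
    "ComponentRecord",
    "CTNetwork",
    "filter_components",
    "build_ct_network",
    "intersect_targets",
]

logger = logging.getLogger(__name__)

VALID_HERBS = frozenset({"A", "B"})


@dataclass(frozen=True)
class ComponentRecord:
    """One herbal compound with its herb attribution and ADME properties.

    ``herbs`` is a non-empty subset of {"A", "B"}; compounds present in
    both herbs (e.g. shared flavonoids) carry both labels and their edges
    count toward both herb-attributed degrees.
    """

    component_id: str
    herbs: frozenset = field(default_factory=lambda: frozenset({"A"}))
    ob: float = 0.0  # oral bioavailability, percent
    dl: float = 0.0  # drug-likeness, unitless

    def __post_init__(self) -> None:
        herbs = frozenset(self.herbs)
        object.__setattr__(self, "herbs", herbs)
        if not herbs or not herbs <= VALID_HERBS:
            raise InputError(
                f"herbs must be a non-empty subset of {{'A','B'}}, got {set(herbs)}"
            )
        if self.ob < 0 or self.dl < 0:
            raise InputError("ob and dl must be non-negative")


@dataclass
class CTNetwork:
    """Bipartite component-target network with degree bookkeeping.

    Attributes
    ----------
    components : dict
        ``component_id -> ComponentRecord`` (isolated components dropped).
    targets : list
        Sorted target ids.
    edges : list
        Sorted unique ``(component_id, target_id)`` pairs.
    tedge : int
        Total number of edges.
    ci, ca, cb : dict
        Per-component degree and its herb-A / herb-B attributed parts.
    pj : dict
        Per-target degree.
    """

    components: dict
    targets: list
    edges: list
    tedge: int
    ci: dict
    ca: dict
    cb: dict
    pj: dict

    def targets_of(self, component_id: str) -> list:
        """Sorted targets adjacent to one component."""
        return sorted(t for c, t in self.edges if c == component_id)

    def to_graph(self) -> nx.Graph:
        """Export as a networkx bipartite graph (for external viewers)."""
        g = nx.Graph()
        for cid, rec in self.components.items():
            g.add_node(cid, bipartite="component", herbs="".join(sorted(rec.herbs)),
                       ob=rec.ob, dl=rec.dl)
        for t in self.targets:
            g.add_node(t, bipartite="target")
        g.add_edges_from(self.edges)
        return g

    def node_table(self) -> pd.DataFrame:
        """Node-attribute table (components then targets, sorted ids)."""
        rows = [
            {
                "node_id": cid,
                "role": "component",
                "herbs": "".join(sorted(rec.herbs)),
                "degree": self.ci[cid],
            }
            for cid, rec in sorted(self.components.items())
        ] + [
            {"node_id": t, "role": "target", "herbs": "", "degree": self.pj[t]}
            for t in self.targets
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["component_id", "target_id"])


def filter_components(
    records: Iterable[ComponentRecord],
    ob_min: float = 30.0,
    dl_min: float = 0.18,
) -> list:
    """Keep compounds with OB >= ob_min and DL >= dl_min (both inclusive)."""
    return [r for r in records if r.ob >= ob_min and r.dl >= dl_min]


def build_ct_network(
    components: Iterable[ComponentRecord],
    edges: Iterable[Sequence],
) -> CTNetwork:
    """Assemble a :class:`CTNetwork` from components and an edge list.

    Duplicate edges (the same pair reported by several target-prediction
    sources) are collapsed to one with a logged count; components left
    with zero edges are dropped with a warning, since downstream scoring
    is undefined on degree-0 components. Unknown component ids raise.
    """
    comp_map = {}
    for rec in components:
        if rec.component_id in comp_map:
            raise InputError(f"duplicate component id {rec.component_id!r}")
        comp_map[rec.component_id] = rec

    seen = set()
    n_dup = 0
    for c, t in edges:
        if c not in comp_map:
            raise InputError(f"edge references unknown component {c!r}")
        if (c, t) in seen:
            n_dup += 1
        seen.add((c, str(t)))
    if n_dup:
        logger.warning("deduplicated %d duplicate component-target edges", n_dup)

    edge_list = sorted(seen)
    g = nx.Graph()
    g.add_nodes_from(comp_map, bipartite=0)
    g.add_edges_from(edge_list)

    isolated = [cid for cid in comp_map if g.degree(cid) == 0]
    if isolated:
        logger.warning(
            "dropping %d isolated component(s): %s", len(isolated), sorted(isolated)
        )
        for cid in isolated:
            g.remove_node(cid)
            del comp_map[cid]

    targets = sorted({t for _, t in edge_list})
    ci = {cid: g.degree(cid) for cid in comp_map}
    pj = {t: g.degree(t) for t in targets}
    ca = {cid: (ci[cid] if "A" in rec.herbs else 0) for cid, rec in comp_map.items()}
    cb = {cid: (ci[cid] if "B" in rec.herbs else 0) for cid, rec in comp_map.items()}

    return CTNetwork(
        components=comp_map,
        targets=targets,
        edges=edge_list,
        tedge=len(edge_list),
        ci=ci,
        ca=ca,
        cb=cb,
        pj=pj,
    )


def components_from_table(table: pd.DataFrame) -> list:
    """Build ComponentRecords from a table with columns
    ``component_id, herb, ob, dl`` (herb given as "A", "B" or "AB")."""
    records = []
    for row in table.itertuples(index=False):
        records.append(
            ComponentRecord(
                component_id=str(row.component_id),
                herbs=frozenset(str(row.herb)),
                ob=float(row.ob),
                dl=float(row.dl),
            )
        )
    return records


def intersect_targets(component_targets: Iterable, disease_genes: Iterable) -> list:
    """Exact set intersection, returned in deterministic sorted order."""
    return sorted(set(component_targets) & set(disease_genes))
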