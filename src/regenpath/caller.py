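"""Initiator-to-effector chain calls over pathway graphs.

A pathway is *comprehensively upregulated* when at least one complete
directed chain from an initiator node to an effector node consists entirely
of satisfied nodes.  A node is satisfied (OR semantics over its gene-family
members) when at least one member is upregulated in the requested mode:
``early`` (P7), ``late`` (P28), or ``any`` (either — the headline mode,
matching "at P7 and/or P28").  Downregulation never satisfies a node; it is
annotated only.

The one-complete-chain reading, rather than all-nodes-satisfied, is
deliberate: a pathway can be called comprehensive even when a parallel
branch is unchanged (the Hippo case, whose core-kinase chain ends at an
unchanged YAP1/WWTR1 node while the TGFB-SMAD branch is fully upregulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .classify import GeneStatus
from .pathway import PathwayCatalog, PathwayGraph, PathwayNode

MODES = ("early", "late", "any")

NODE_STATUSES = ("early", "late", "both", "down", "unchanged", "no_data")

#: default cap on the number of satisfied chains listed per pathway
DEFAULT_CHAIN_CAP = 100


def as_status_frame(statuses) -> pd.DataFrame:
    """Normalize a status table to a DataFrame indexed by gene_id.

    Accepts the frame produced by :func:`regenpath.classify.classify_all`, a
    mapping ``gene_id -> GeneStatus``, or an iterable of
    :class:`~regenpath.classify.GeneStatus`.
    """
    if isinstance(statuses, pd.DataFrame):
        frame = statuses
    else:
        if isinstance(statuses, Mapping):
            records = list(statuses.values())
        else:
            records = list(statuses)
        frame = pd.DataFrame(
            {
                "gene_id": [s.gene_id for s in records],
                "early_up": [s.early_up for s in records],
                "late_up": [s.late_up for s in records],
                "late_down": [s.late_down for s in records],
            }
        ).set_index("gene_id")
    for col in ("early_up", "late_up"):
        if col not in frame.columns:
            raise ValueError(f"status table missing column {col!r}")
    if "late_down" not in frame.columns:
        frame = frame.assign(late_down=False)
    return frame


def node_satisfied(node: PathwayNode, statuses, mode: str = "any") -> bool:
    """True iff at least one member gene is upregulated in ``mode``.

    Genes absent from the status table count as not upregulated.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    frame = as_status_frame(statuses)
    for gene in node.members:
        if gene not in frame.index:
            continue
        row = frame.loc[gene]
        early, late = bool(row["early_up"]), bool(row["late_up"])
        if mode == "early" and early:
            return True
        if mode == "late" and late:
            return True
        if mode == "any" and (early or late):
            return True
    return False


def _node_status(node: PathwayNode, frame: pd.DataFrame) -> str:
    present = [g for g in node.members if g in frame.index]
    if not present:
        return "no_data"
    early = any(bool(frame.loc[g, "early_up"]) for g in present)
    late = any(bool(frame.loc[g, "late_up"]) for g in present)
    down = any(bool(frame.loc[g, "late_down"]) for g in present)
    if early and late:
        return "both"
    if early:
        return "early"
    if late:
        return "late"
    if down:
        return "down"
    return "unchanged"


@dataclass(frozen=True)
class PathwayCall:
    pathway_id: str
    comprehensive: bool
    satisfied_chains: tuple[tuple[str, ...], ...]
    node_status: dict[str, str]
    initiators_persistent: bool
    effectors_persistent: bool
    chains_truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "comprehensive": self.comprehensive,
            "satisfied_chains": [list(c) for c in self.satisfied_chains],
            "node_status": dict(self.node_status),
            "initiators_persistent": self.initiators_persistent,
            "effectors_persistent": self.effectors_persistent,
            "chains_truncated": self.chains_truncated,
        }


def comprehensive_call(
    g: PathwayGraph,
    statuses,
    mode: str = "any",
    chain_cap: int = DEFAULT_CHAIN_CAP,
) -> PathwayCall:
    """Decide whether a complete satisfied initiator-to-effector chain exists.

    Satisfied chains are simple directed paths through satisfied nodes only,
    listed in lexicographic node-id order up to ``chain_cap`` (the search is
    deterministic; cycles in the graph are handled by the simple-path
    restriction).  Persistence flags report whether every initiator
    (resp. effector) that appears on at least one satisfied chain is also
    satisfied in ``late`` mode.
    """
    frame = as_status_frame(statuses)
    initiators, effectors = g.initiators(), g.effectors()

    satisfied = {
        nid for nid, node in g.nodes.items() if node_satisfied(node, frame, mode)
    }
    digraph = g.to_networkx()
    sub = digraph.subgraph(satisfied)

    chains: list[tuple[str, ...]] = []
    for init in sorted(initiators):
        if init not in satisfied:
            continue
        for eff in sorted(effectors):
            if eff not in satisfied:
                continue
            if init == eff:
                chains.append((init,))
                continue
            for path in nx.all_simple_paths(sub, init, eff):
                chains.append(tuple(path))
    chains.sort()
    truncated = len(chains) > chain_cap
    kept = tuple(chains[:chain_cap])

    node_status = {nid: _node_status(node, frame) for nid, node in g.nodes.items()}

    chain_nodes = {nid for chain in chains for nid in chain}
    init_on_chains = [n for n in initiators if n in chain_nodes]
    eff_on_chains = [n for n in effectors if n in chain_nodes]
    init_persistent = bool(init_on_chains) and all(
        node_satisfied(g.nodes[n], frame, "late") for n in init_on_chains
    )
    eff_persistent = bool(eff_on_chains) and all(
        node_satisfied(g.nodes[n], frame, "late") for n in eff_on_chains
    )

    return PathwayCall(
        pathway_id=g.pathway_id,
        comprehensive=bool(chains),
        satisfied_chains=kept,
        node_status=node_status,
        initiators_persistent=init_persistent,
        effectors_persistent=eff_persistent,
        chains_truncated=truncated,
    )


@dataclass(frozen=True)
class CatalogReport:
    calls: tuple[PathwayCall, ...]
    not_called: tuple[str, ...]
    n_comprehensive: int
    n_called: int
    n_catalog: int

    def summary(self) -> dict:
        return {
            "n_comprehensive": self.n_comprehensive,
            "n_called": self.n_called,
            "n_catalog": self.n_catalog,
            "comprehensive": sorted(
                c.pathway_id for c in self.calls if c.comprehensive
            ),
            "not_called": list(self.not_called),
        }

    def to_frame(self) -> pd.DataFrame:
        """Catalog summary table (one row per catalog entry)."""
        by_id = {c.pathway_id: c for c in self.calls}
        rows = []
        for pid in sorted(set(by_id) | set(self.not_called)):
            call = by_id.get(pid)
            rows.append(
                {
                    "pathway_id": pid,
                    "called": call is not None,
                    "comprehensive": call.comprehensive if call else False,
                    "n_satisfied_chains": len(call.satisfied_chains) if call else 0,
                    "initiators_persistent": call.initiators_persistent
                    if call
                    else False,
                    "effectors_persistent": call.effectors_persistent
                    if call
                    else False,
                }
            )
        return pd.DataFrame(rows).set_index("pathway_id")


def call_catalog(
    cat: PathwayCatalog,
    statuses,
    mode: str = "any",
    chain_cap: int = DEFAULT_CHAIN_CAP,
) -> CatalogReport:
    """Run :func:`comprehensive_call` on every detailed catalog entry.

    Entries without a detailed graph are listed as *not called* — absence of
    a node list is not evidence against upregulation.
    """
    frame = as_status_frame(statuses)
    calls = []
    not_called = []
    for entry in cat.entries:
        if entry.has_detailed_graph:
            graph = cat.load_graph(entry.pathway_id)
            calls.append(comprehensive_call(graph, frame, mode, chain_cap))
        else:
            not_called.append(entry.pathway_id)
    return CatalogReport(
        calls=tuple(calls),
        not_called=tuple(not_called),
        n_comprehensive=sum(c.comprehensive for c in calls),
        n_called=len(calls),
        n_catalog=len(cat.entries),
    )
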