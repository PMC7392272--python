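"""Signaling-pathway graph model, JSON dialect, and packaged fixtures.

A pathway is a small directed graph of nodes, each of which represents a
gene or a gene family (OR semantics: the node ``MAPK1/3`` is satisfied when
either MAPK1 or MAPK3 qualifies).  Nodes carry one of three roles —
``initiator`` (master regulator: ligand/receptor), ``intermediate``, or
``effector`` (terminal transcription factor or proliferative gene) — and a
pathway may name subpathways as subsets of its nodes.

The package ships fixtures for the five signaling pathways analyzed in
detail for the neonatal-infarction model (MAPK, Hippo, cAMP, JAK-STAT, Ras)
and a 20-entry catalog of candidate cell-cycle/cell-fate pathways; the 15
catalog entries without a detailed graph are reported downstream as
"not called" rather than "not upregulated".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .expression import FormatError

ROLES = ("initiator", "intermediate", "effector")


@dataclass(frozen=True)
class PathwayNode:
    node_id: str
    label: str
    role: str
    members: tuple[str, ...]
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(f"node {self.node_id!r}: unknown role {self.role!r}")
        if not self.members:
            raise FormatError(f"node {self.node_id!r}: empty member set")


@dataclass(frozen=True)
class PathwayGraph:
    pathway_id: str
    name: str
    nodes: dict[str, PathwayNode]
    edges: tuple[tuple[str, str], ...]
    subpathways: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, (u, v) in enumerate(self.edges):
            for end in (u, v):
                if end not in self.nodes:
                    raise FormatError(
                        f"/edges/{i}: endpoint {end!r} is not a declared node"
                    )
        for name, ids in self.subpathways.items():
            for nid in ids:
                if nid not in self.nodes:
                    raise FormatError(
                        f"/subpathways/{name}: unknown node {nid!r}"
                    )
        if not self.initiators():
            raise FormatError(f"pathway {self.pathway_id!r} has no initiator node")
        if not self.effectors():
            raise FormatError(f"pathway {self.pathway_id!r} has no effector node")

    def initiators(self) -> list[str]:
        return sorted(n.node_id for n in self.nodes.values() if n.role == "initiator")

    def effectors(self) -> list[str]:
        return sorted(n.node_id for n in self.nodes.values() if n.role == "effector")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def members_of(self, node_id: str) -> tuple[str, ...]:
        return self.nodes[node_id].members

    def all_members(self) -> set[str]:
        return {m for n in self.nodes.values() for m in n.members}

    def unreachable_effectors(self) -> list[str]:
        """Effectors not reachable from any initiator (reported, not enforced:
        a fixture may deliberately encode a broken chain)."""
        g = self.to_networkx()
        reach: set[str] = set()
        for init in self.initiators():
            reach |= nx.descendants(g, init) | {init}
        return sorted(e for e in self.effectors() if e not in reach)

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "name": self.name,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "label": n.label,
                    "role": n.role,
                    "members": list(n.members),
                    **({"annotation": n.annotation} if n.annotation else {}),
                }
                for n in self.nodes.values()
            ],
            "edges": [list(e) for e in self.edges],
            "subpathways": {k: list(v) for k, v in self.subpathways.items()},
        }


def pathway_from_dict(data: dict) -> PathwayGraph:
    """Build and validate a graph from the JSON dialect (see module docs)."""
    for key in ("pathway_id", "name", "nodes", "edges"):
        if key not in data:
            raise FormatError(f"/{key}: missing required field")
    nodes: dict[str, PathwayNode] = {}
    for i, nd in enumerate(data["nodes"]):
        for key in ("node_id", "label", "role", "members"):
            if key not in nd:
                raise FormatError(f"/nodes/{i}: missing field {key!r}")
        nid = nd["node_id"]
        if nid in nodes:
            raise FormatError(f"/nodes/{i}: duplicate node_id {nid!r}")
        if not nd["members"]:
            raise FormatError(f"/nodes/{i}/members: empty member set")
        nodes[nid] = PathwayNode(
            node_id=nid,
            label=nd["label"],
            role=nd["role"],
            members=tuple(nd["members"]),
            annotation=nd.get("annotation"),
        )
    edges = tuple((str(u), str(v)) for u, v in data["edges"])
    subpathways = {
        str(k): tuple(v) for k, v in (data.get("subpathways") or {}).items()
    }
    return PathwayGraph(
        pathway_id=data["pathway_id"],
        name=data["name"],
        nodes=nodes,
        edges=edges,
        subpathways=subpathways,
    )


def load_pathway(path: str | Path) -> PathwayGraph:
    """Load and validate a pathway JSON file."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: invalid JSON ({e})") from None
    return pathway_from_dict(data)


def write_pathway(g: PathwayGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(g.to_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class CatalogEntry:
    pathway_id: str
    name: str
    graph_file: Optional[str] = None

    @property
    def has_detailed_graph(self) -> bool:
        return self.graph_file is not None


@dataclass(frozen=True)
class PathwayCatalog:
    entries: tuple[CatalogEntry, ...]
    base_dir: Optional[Path] = None
    notes: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [e.pathway_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate pathway_id in catalog: {dup!r}")

    def detailed(self) -> list[CatalogEntry]:
        return [e for e in self.entries if e.has_detailed_graph]

    def graph_path(self, entry: CatalogEntry) -> Path:
        assert entry.graph_file is not None
        base = self.base_dir or Path(".")
        return base / entry.graph_file

    def load_graph(self, pathway_id: str) -> PathwayGraph:
        for e in self.entries:
            if e.pathway_id == pathway_id:
                if not e.has_detailed_graph:
                    raise KeyError(f"pathway {pathway_id!r} has no detailed graph")
                return load_pathway(self.graph_path(e))
        raise KeyError(f"unknown pathway: {pathway_id!r}")


def load_catalog(path: str | Path) -> PathwayCatalog:
    """Load a catalog JSON; referenced graph files must exist and validate."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: invalid JSON ({e})") from None
    if "entries" not in data or not data["entries"]:
        raise FormatError(f"{path}: catalog must have a non-empty entries list")
    entries = []
    for i, e in enumerate(data["entries"]):
        for key in ("pathway_id", "name"):
            if key not in e:
                raise FormatError(f"/entries/{i}: missing field {key!r}")
        entries.append(
            CatalogEntry(
                pathway_id=e["pathway_id"],
                name=e["name"],
                graph_file=e.get("graph_file"),
            )
        )
    cat = PathwayCatalog(
        entries=tuple(entries), base_dir=path.parent, notes=data.get("notes")
    )
    for entry in cat.detailed():
        gpath = cat.graph_path(entry)
        if not gpath.exists():
            raise FormatError(
                f"catalog entry {entry.pathway_id!r} references missing graph "
                f"file {gpath}"
            )
        load_pathway(gpath)  # validates eagerly
    return cat


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_dir() -> Path:
    return Path(str(resources.files("regenpath").joinpath("data")))


def packaged_catalog_path() -> Path:
    return _data_dir() / "pathways" / "catalog.json"


def load_packaged_catalog() -> PathwayCatalog:
    """The 20-entry candidate-pathway catalog shipped with the package."""
    return load_catalog(packaged_catalog_path())


def load_packaged_pathway(pathway_id: str) -> PathwayGraph:
    """One of the five detailed packaged graphs (mapk, hippo, camp, jak_stat, ras)."""
    return load_packaged_catalog().load_graph(pathway_id)
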