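"""Network reduction: from a genome-scale model to a Jacobian sparsity pattern.

A metabolic model is turned into a weighted directed metabolite graph
(currency metabolites removed; forward reaction steps cost 1, reverse
steps a user weight plus a thermodynamic penalty; co-reactants linked
because they share a rate law).  Cost-bounded shortest superpathways
between every ordered pair of measured metabolites then define which
Jacobian entries are admissible: an accepted route from metabolite j to
metabolite i marks entry (i, j), matching J_ij = df_i/dM_j.  Routes
passing through another measured metabolite are discarded as indirect —
their influence is already represented by the two sub-routes.
"""

from __future__ import annotations

import heapq
import logging
import math
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model_io import (
    DEFAULT_COMPARTMENT_PATTERN,
    MetabolicModel,
    ReactionThermo,
    SideMetaboliteList,
)

log = logging.getLogger(__name__)

__all__ = [
    "WeightedReactionGraph",
    "PathResult",
    "JacobianStructure",
    "build_graph",
    "shortest_paths",
    "prune_and_structure",
    "export_interaction_sbml",
    "import_interaction_sbml",
    "structure_compare",
    "structure_to_csv",
    "superpathway_table",
]

THERMO_PENALTY_THRESHOLD = 100.0  # kcal/mol; beyond this the reverse step pays log10(dG)


@dataclass
class WeightedReactionGraph:
    """Directed metabolite graph; edge attrs: weight > 0, provenance list.

    Provenance entries are (reaction id, direction flag, relation) with
    relation one of 'substrate->product', 'co-substrate', 'co-product'.
    Parallel edges are collapsed to the minimum weight with merged
    provenance.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_edge(self, u: str, v: str, weight: float,
                 provenance: tuple[str, str, str]) -> None:
        if weight <= 0:
            raise ValueError(f"edge {u}->{v}: weight must be positive")
        if self.graph.has_edge(u, v):
            data = self.graph[u][v]
            data["weight"] = min(data["weight"], weight)
            if provenance not in data["provenance"]:
                data["provenance"].append(provenance)
        else:
            self.graph.add_edge(u, v, weight=weight, provenance=[provenance])

    def nodes(self):
        return list(self.graph.nodes)

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]


@dataclass
class PathResult:
    source: str
    target: str
    cost: float
    nodes: list[str]                       # metabolite sequence, source..target
    route: list[object]                    # alternating metabolite / provenance list

    def reaction_ids(self) -> list[str]:
        out = []
        for item in self.route:
            if isinstance(item, list):
                out.extend(p[0] for p in item)
        return list(dict.fromkeys(out))


@dataclass
class JacobianStructure:
    """Ordered labels, boolean admissibility mask, per-entry route annotation."""

    labels: list[str]
    mask: np.ndarray
    annotation: dict[tuple[int, int], PathResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.labels)
        if self.mask.shape != (n, n):
            raise ValueError("mask shape does not match label count")
        if not self.mask.diagonal().all():
            raise ValueError("all diagonal entries must be admissible")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_entries(self) -> int:
        return int(self.mask.sum())


def build_graph(model: MetabolicModel, thermo: dict[str, ReactionThermo] | None = None,
                sides: SideMetaboliteList | None = None, reverse_weight: float = 2.0,
                use_thermo: bool = True,
                compartment_pattern: str = DEFAULT_COMPARTMENT_PATTERN,
                ) -> WeightedReactionGraph:
    """Weighted directed metabolite graph from reaction stoichiometry.

    Per reaction (after currency-metabolite removal): substrate->product
    edges at weight 1; for reversible reactions product->substrate edges
    at ``reverse_weight``, plus log10(dG) when the ModelSEED Gibbs energy
    exceeds 100 kcal/mol; co-substrates are linked both ways at the
    forward weight, co-products of reversible reactions at the reverse
    weight, because each reactant's level perturbs the shared rate.
    """
    if reverse_weight < 1:
        raise ValueError("reverse_weight must be >= 1")
    side_ids = {s.lower() for s in sides.ids} if sides else set()
    g = WeightedReactionGraph()

    def is_side(mid: str) -> bool:
        base = re.sub(compartment_pattern, "", mid)
        return base.lower() in side_ids or mid.lower() in side_ids

    for r in sorted(model.reactions, key=lambda r: r.id):
        subs = sorted(m for m in r.substrates() if not is_side(m))
        prods = sorted(m for m in r.products() if not is_side(m))
        wf = 1.0
        wr = float(reverse_weight)
        th = thermo.get(r.id) if thermo else None
        if use_thermo and th is not None and th.delta_g is not None \
                and th.delta_g > THERMO_PENALTY_THRESHOLD:
            wr += math.log10(th.delta_g)
        if subs and prods:
            for s in subs:
                for p in prods:
                    if s != p:
                        g.add_edge(s, p, wf, (r.id, "forward", "substrate->product"))
            if r.reversible:
                for p in prods:
                    for s in subs:
                        if s != p:
                            g.add_edge(p, s, wr, (r.id, "reverse", "substrate->product"))
        for a in subs:
            for b in subs:
                if a < b:
                    g.add_edge(a, b, wf, (r.id, "forward", "co-substrate"))
                    g.add_edge(b, a, wf, (r.id, "forward", "co-substrate"))
        if r.reversible:
            for a in prods:
                for b in prods:
                    if a < b:
                        g.add_edge(a, b, wr, (r.id, "reverse", "co-product"))
                        g.add_edge(b, a, wr, (r.id, "reverse", "co-product"))
    return g


def _lex_dijkstra(graph: nx.DiGraph, source: str) -> dict[str, tuple[float, tuple[str, ...]]]:
    """Single-source shortest paths with deterministic lexicographic ties.

    Heap entries carry (cost, node sequence); among equal-cost routes the
    lexicographically smallest node sequence wins.
    """
    settled: dict[str, tuple[float, tuple[str, ...]]] = {}
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled[node] = (cost, path)
        for _, nbr, data in graph.out_edges(node, data=True):
            w = data["weight"]
            assert w >= 0, "negative edge weight"
            if nbr not in settled:
                heapq.heappush(heap, (cost + w, path + (nbr,)))
    return settled


def shortest_paths(graph: WeightedReactionGraph, targets: list[str]) -> list[PathResult]:
    """Minimum-cost route for every ordered pair of target metabolites."""
    g = graph.graph
    present = [t for t in targets if t in g]
    absent = [t for t in targets if t not in g]
    if absent:
        log.warning("targets absent from graph (kept isolated): %s", absent)
    target_set = set(present)
    results: list[PathResult] = []
    for s in present:
        settled = _lex_dijkstra(g, s)
        for t in present:
            if t == s or t not in settled:
                continue
            cost, nodes = settled[t]
            route: list[object] = [nodes[0]]
            for u, v in zip(nodes, nodes[1:]):
                route.append(list(g[u][v]["provenance"]))
                route.append(v)
            results.append(PathResult(source=s, target=t, cost=cost,
                                      nodes=list(nodes), route=route))
    # deterministic output order: by target list order
    order = {t: i for i, t in enumerate(targets)}
    results.sort(key=lambda p: (order[p.source], order[p.target]))
    assert target_set >= {p.source for p in results}
    return results


def prune_and_structure(paths: list[PathResult], targets: list[str],
                        cost_threshold: float = 3.0) -> JacobianStructure:
    """Keep direct, cheap routes and emit the Jacobian admissibility mask.

    A route survives iff its cost is <= ``cost_threshold`` (equality
    kept; "higher than" is strict) and no interior metabolite is itself
    a target.  A kept route j -> i marks mask entry (i, j); the diagonal
    is always admissible.
    """
    n = len(targets)
    index = {t: i for i, t in enumerate(targets)}
    mask = np.eye(n, dtype=bool)
    annotation: dict[tuple[int, int], PathResult] = {}
    target_set = set(targets)
    for p in paths:
        if p.source not in index or p.target not in index:
            raise ValueError(f"path endpoint {p.source}->{p.target} not in target list")
        if p.cost > cost_threshold:
            continue
        interior = p.nodes[1:-1]
        if any(m in target_set for m in interior):
            continue
        i, j = index[p.target], index[p.source]
        mask[i, j] = True
        annotation[(i, j)] = p
    return JacobianStructure(labels=list(targets), mask=mask, annotation=annotation)


def structure_compare(found: JacobianStructure, reference: JacobianStructure) -> dict:
    """Partition off-diagonal entries into found-only / reference-only / shared."""
    if found.labels != reference.labels:
        raise ValueError("structures have different label orders")
    off = ~np.eye(found.n, dtype=bool)
    f = found.mask & off
    r = reference.mask & off
    added = [tuple(p) for p in np.argwhere(f & ~r)]
    missing = [tuple(p) for p in np.argwhere(~f & r)]
    shared = [tuple(p) for p in np.argwhere(f & r)]
    return {"added": len(added), "missing": len(missing), "shared": len(shared),
            "added_entries": added, "missing_entries": missing, "shared_entries": shared}


_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(label: str) -> str:
    sid = _SID_BAD.sub("_", label)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "M_" + sid
    return sid


def export_interaction_sbml(structure: JacobianStructure, path) -> None:
    """Save the interaction network as SBML L3: one species per label,
    one modifier-style reaction per off-diagonal admissible entry, with
    route annotation (cost, contributing reaction ids) in the notes."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("interaction_network")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    sids = {}
    for label in structure.labels:
        sid = _sid(label)
        base = sid
        k = 1
        while sid in sids.values():
            sid = f"{base}_{k}"
            k += 1
        sids[label] = sid
        sp = model.createSpecies()
        sp.setId(sid)
        sp.setName(label)
        sp.setCompartment("c")
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
    n = structure.n
    for i in range(n):
        for j in range(n):
            if i == j or not structure.mask[i, j]:
                continue
            rx = model.createReaction()
            rx.setId(f"I_{sids[structure.labels[j]]}__{sids[structure.labels[i]]}")
            rx.setReversible(False)
            ref = rx.createReactant()
            ref.setSpecies(sids[structure.labels[j]])
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
            ref = rx.createProduct()
            ref.setSpecies(sids[structure.labels[i]])
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
            ann = structure.annotation.get((i, j))
            if ann is not None:
                notes = (f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                         f"<p>cost: {ann.cost}</p>"
                         f"<p>reactions: {' '.join(ann.reaction_ids())}</p></body>")
                rx.setNotes(notes)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


def import_interaction_sbml(path) -> JacobianStructure:
    """Re-read an exported interaction network (labels and mask)."""
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(f"SBML parse error in {path}")
    model = doc.getModel()
    labels = []
    sid_to_idx = {}
    for k, sp in enumerate(model.getListOfSpecies()):
        labels.append(sp.getName() or sp.getId())
        sid_to_idx[sp.getId()] = k
    n = len(labels)
    mask = np.eye(n, dtype=bool)
    for rx in model.getListOfReactions():
        j = sid_to_idx[rx.getReactant(0).getSpecies()]
        i = sid_to_idx[rx.getProduct(0).getSpecies()]
        mask[i, j] = True
    return JacobianStructure(labels=labels, mask=mask)


def structure_to_csv(structure: JacobianStructure, path) -> None:
    import pandas as pd

    pd.DataFrame(structure.mask.astype(int), index=structure.labels,
                 columns=structure.labels).to_csv(path)


def superpathway_table(structure: JacobianStructure, model: MetabolicModel | None = None):
    """Per-edge table: from, to, cost, reaction ids, genes."""
    import pandas as pd

    rows = []
    gene_map = {}
    if model is not None:
        gene_map = {r.id: r.gene_association for r in model.reactions}
    for (i, j), p in sorted(structure.annotation.items()):
        rids = p.reaction_ids()
        genes = sorted({g for rid in rids for g in gene_map.get(rid, [])})
        rows.append({"from": structure.labels[j], "to": structure.labels[i],
                     "cost": p.cost, "reactions": "|".join(rids),
                     "genes": "|".join(genes)})
    return pd.DataFrame(rows, columns=["from", "to", "cost", "reactions", "genes"])
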