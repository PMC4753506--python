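"""Intra-molecular residue interaction networks seeded at functional residues.

Starting from one or more seed residues, every residue sharing at least one
classified contact (same tables as the protein-DNA classifier, no DNA moiety)
is collected by breadth-first expansion. Sequence-adjacent pairs (i, i+1) in
the same chain are excluded by default: their backbone proximity is trivial
and the networks of interest are side-chain mediated.

Edges touching residues with incomplete or grafted side chains are flagged
``provisional`` so that claims resting on modeled coordinates stay visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .contacts import Contact, ContactCutoffs, DEFAULT_CUTOFFS, classify_pair
from .structure import NumberingMap, ResidueKey, StructureModel, missing_sidechain_residues

__all__ = ["InteractionGraph", "residue_pair_contacts", "neighborhood", "build_network"]


@dataclass
class InteractionGraph:
    """Residue-level network of typed contacts (undirected, no self-edges)."""

    graph: nx.Graph
    seeds: frozenset[ResidueKey]
    numbering: NumberingMap = field(default_factory=NumberingMap)

    @property
    def nodes(self) -> set[ResidueKey]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[ResidueKey, ResidueKey]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def has_edge(self, a: ResidueKey, b: ResidueKey) -> bool:
        return self.graph.has_edge(a, b)

    def ordered_nodes(self) -> list[ResidueKey]:
        return sorted(
            self.graph.nodes,
            key=lambda k: (self.numbering.ref_position(k.chain_id, k.resnum), k),
        )

    def to_edge_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in sorted(self.edges):
            data = self.graph.edges[a, b]
            rows.append(
                {
                    "residue_a": str(a),
                    "residue_b": str(b),
                    "contact_class": data["contact_class"],
                    "min_distance": round(data["min_distance"], 3),
                    "provisional": data.get("provisional", False),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["residue_a", "residue_b", "contact_class", "min_distance", "provisional"],
        )

    def to_tsv(self) -> str:
        return self.to_edge_frame().to_csv(sep="\t", index=False)

    def to_graphml(self) -> str:
        g = nx.Graph()
        for node in self.ordered_nodes():
            g.add_node(
                str(node),
                resname=node.resname,
                chain=node.chain_id,
                resnum=node.resnum,
                seed=node in self.seeds,
                sidechain_complete=bool(self.graph.nodes[node].get("sidechain_complete", True)),
                grafted=bool(self.graph.nodes[node].get("grafted", False)),
            )
        for a, b in sorted(self.edges):
            data = self.graph.edges[a, b]
            g.add_edge(
                str(a), str(b),
                contact_class=data["contact_class"],
                min_distance=float(data["min_distance"]),
                provisional=bool(data.get("provisional", False)),
            )
        return "\n".join(nx.generate_graphml(g))


def residue_pair_contacts(
    model: StructureModel,
    res_a: ResidueKey,
    res_b: ResidueKey,
    cutoffs: ContactCutoffs = DEFAULT_CUTOFFS,
) -> list[Contact]:
    """All classified heavy-atom contacts between two protein residues."""
    if res_a == res_b:
        raise ValueError("residue pair must be two distinct residues")
    atoms_a, atoms_b = model.atoms(res_a), model.atoms(res_b)
    d = cdist(model.coords(res_a), model.coords(res_b))
    max_cut = max(cutoffs.hydrogen_bond, cutoffs.salt_bridge, cutoffs.nonpolar)
    contacts = []
    for i, j in zip(*np.nonzero(d <= max_cut)):
        cls = classify_pair(
            res_a.resname, atoms_a[i].name,
            res_b.resname, atoms_b[j].name,
            float(d[i, j]), cutoffs,
        )
        if cls is not None:
            contacts.append(
                Contact(
                    protein_atom=(res_a, atoms_a[i].name),
                    dna_atom=(res_b, atoms_b[j].name),
                    distance=float(d[i, j]),
                    contact_class=cls,
                    dna_moiety=None,
                )
            )
    return contacts


def _sequence_adjacent(a: ResidueKey, b: ResidueKey) -> bool:
    return a.chain_id == b.chain_id and abs(a.resnum - b.resnum) == 1 and a.icode == b.icode


def _protein_residues(model: StructureModel) -> list[ResidueKey]:
    keys = []
    for cid in model.protein_chains():
        keys.extend(model.chains[cid])
    return keys


def _annotate(graph: nx.Graph, model: StructureModel) -> None:
    incomplete = set(missing_sidechain_residues(model))
    grafted = model.metadata.get("grafted_residues", set())
    for node in graph.nodes:
        graph.nodes[node]["sidechain_complete"] = node not in incomplete
        graph.nodes[node]["grafted"] = node in grafted
    for a, b in graph.edges:
        graph.edges[a, b]["provisional"] = bool(
            {a, b} & (incomplete | set(grafted))
        )


def neighborhood(
    model: StructureModel,
    seed: ResidueKey,
    cutoffs: ContactCutoffs = DEFAULT_CUTOFFS,
    exclude_adjacent: bool = True,
    numbering: NumberingMap | None = None,
) -> InteractionGraph:
    """Radius-1 interaction graph around one seed residue."""
    return build_network(
        model, [seed], depth=1, cutoffs=cutoffs,
        exclude_adjacent=exclude_adjacent, numbering=numbering,
    )


def build_network(
    model: StructureModel,
    seeds: list[ResidueKey],
    depth: int = 1,
    cutoffs: ContactCutoffs = DEFAULT_CUTOFFS,
    exclude_adjacent: bool = True,
    numbering: NumberingMap | None = None,
) -> InteractionGraph:
    """Breadth-first union of contact neighborhoods to the given depth."""
    if not seeds:
        raise ValueError("need at least one seed residue")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    all_protein = _protein_residues(model)
    for seed in seeds:
        if seed not in set(all_protein):
            raise KeyError(f"unknown seed residue {seed}")
    incomplete = set(missing_sidechain_residues(model))
    for seed in seeds:
        if seed in incomplete:
            warnings.warn(f"seed {seed} has an incomplete side chain; edges provisional")
    g = nx.Graph()
    g.add_nodes_from(seeds)
    frontier = set(seeds)
    visited: set[ResidueKey] = set()
    for _ in range(depth):
        next_frontier: set[ResidueKey] = set()
        for res in sorted(frontier):
            if res in visited:
                continue
            visited.add(res)
            for other in all_protein:
                if other == res:
                    continue
                if exclude_adjacent and _sequence_adjacent(res, other):
                    continue
                contacts = residue_pair_contacts(model, res, other, cutoffs)
                if not contacts:
                    continue
                best = min(contacts, key=lambda c: c.distance)
                g.add_edge(
                    res, other,
                    contact_class=best.contact_class,
                    min_distance=best.distance,
                    n_contacts=len(contacts),
                )
                if other not in visited:
                    next_frontier.add(other)
        frontier = next_frontier
        if not frontier:
            break
    _annotate(g, model)
    return InteractionGraph(
        graph=g, seeds=frozenset(seeds), numbering=numbering or NumberingMap()
    )
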