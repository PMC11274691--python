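"""Inter-site communication pathways on the residue-interaction graph.

The graph has one node per residue of the dimer plus a single node for the
bound cofactor; edges join residues in heavy-atom contact (including
inter-chain interface contacts, which is what lets pathways cross between
monomers) and the ligand to the residues it touches.  The analysis is
asymmetric: the cofactor sits in the binding site of monomer A while the
site of monomer B is empty, and all shortest paths (unit edge weights, so
path length = residue count) are enumerated from the holo site to the apo
site with Dijkstra plus the predecessor DAG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .sites import (
    CONTACT_THRESHOLD,
    LigandCluster,
    ResidueContactMap,
    residues_to_msa_numbers,
)
from .structure import Residue, StructureModel

LIGAND_NODE = "__ligand__"


class PathwayError(ValueError):
    pass


@dataclass
class ResidueGraph:
    """Undirected residue-interaction graph with source/target site sets.

    Node labels are indices into ``residues`` plus the special ligand
    node, present only on the holo side."""

    graph: nx.Graph
    residues: list[Residue]
    sources: set[int]  # holo-site residues (contact the bound ligand, chain A)
    targets: set[int]  # apo-site residues (GS of chain B before ligand removal)


def build_residue_graph(
    dimer: StructureModel,
    contact_map: ResidueContactMap,
    holo_cluster: LigandCluster,
    apo_site_residues: list[Residue],
    threshold: float = CONTACT_THRESHOLD,
    distance_weighted: bool = False,
) -> ResidueGraph:
    """Assemble the graph for the asymmetric holo→apo configuration.

    ``holo_cluster`` is the ligand cluster bound in monomer A; its contact
    residues become the source set.  ``apo_site_residues`` is the binding
    site of monomer B (identified from B's own ligand cluster before that
    ligand is removed); they become the target set.
    """
    if not holo_cluster.members:
        raise PathwayError("no source set: holo ligand cluster is empty")
    residues = contact_map.residues
    index_of = {res.key: i for i, res in enumerate(residues)}
    G = nx.Graph()
    G.add_nodes_from(range(len(residues)))
    coords_cache = {i: residues[i].coords() for i in range(len(residues))}
    for (i, j), npairs in contact_map.contacts.items():
        if distance_weighted:
            di = coords_cache[i]
            dj = coords_cache[j]
            dmin = np.min(np.linalg.norm(di[:, None, :] - dj[None, :, :], axis=-1))
            G.add_edge(i, j, weight=float(dmin), n_atom_pairs=npairs)
        else:
            G.add_edge(i, j, weight=1.0, n_atom_pairs=npairs)

    # ligand node joined to every residue it touches
    lig_coords = np.vstack([m.coords() for m in holo_cluster.members])
    sources: set[int] = set()
    for i, res in enumerate(residues):
        rc = coords_cache[i]
        dmin = np.min(np.linalg.norm(rc[:, None, :] - lig_coords[None, :, :], axis=-1))
        if dmin < threshold:
            sources.add(i)
            G.add_node(LIGAND_NODE)
            G.add_edge(LIGAND_NODE, i, weight=1.0)
    if not sources:
        raise PathwayError("no source set: ligand contacts no residue")
    targets = {index_of[res.key] for res in apo_site_residues if res.key in index_of}
    if not targets:
        raise PathwayError("no target set: apo site is empty")
    return ResidueGraph(graph=G, residues=residues, sources=sources, targets=targets)


@dataclass
class PathwayResult:
    """All minimum-length source→target paths and their statistics."""

    paths: list[list[int]]  # residue-index sequences, source first
    residues: list[Residue]
    visit_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    @property
    def path_length(self) -> int | None:
        """Number of residues in each minimal path (all share it)."""
        return len(self.paths[0]) if self.paths else None

    @property
    def visited_residues(self) -> set[int]:
        return set().union(*self.paths) if self.paths else set()

    def msa_visit_counts(self, model: StructureModel, aln, row_id: str) -> dict[int, int]:
        """Visit counts re-keyed by MSA number (homodimer chains pooled)."""
        out: dict[int, int] = {}
        for idx, count in self.visit_counts.items():
            nums = residues_to_msa_numbers(model, [self.residues[idx]], aln, row_id)
            for n in nums:
                out[n] = out.get(n, 0) + count
        return out


def shortest_paths(
    rgraph: ResidueGraph,
    sources: set[int] | None = None,
    targets: set[int] | None = None,
) -> PathwayResult:
    """Enumerate every minimum-length path between the site sets.

    A virtual super-source and super-sink (zero-cost hops onto the real
    sets) reduce the set-to-set problem to single-pair Dijkstra; all
    shortest paths are read off the predecessor DAG.  Unreachable targets
    yield an empty result rather than an exception.
    """
    sources = rgraph.sources if sources is None else sources
    targets = rgraph.targets if targets is None else targets
    if not sources or not targets:
        raise PathwayError("empty source or target set")
    G = rgraph.graph.copy()
    G.remove_node(LIGAND_NODE) if G.has_node(LIGAND_NODE) else None
    SRC, DST = "__src__", "__dst__"
    for s in sources:
        G.add_edge(SRC, s, weight=1.0)
    for t in targets:
        G.add_edge(DST, t, weight=1.0)
    result = PathwayResult(paths=[], residues=rgraph.residues)
    try:
        raw = list(nx.all_shortest_paths(G, SRC, DST, weight="weight"))
    except nx.NetworkXNoPath:
        return result
    seen = set()
    for path in raw:
        inner = tuple(path[1:-1])
        if inner and inner not in seen:
            seen.add(inner)
            result.paths.append(list(inner))
    result.paths.sort()
    for path in result.paths:
        for node in path:
            result.visit_counts[node] = result.visit_counts.get(node, 0) + 1
    return result


def pathway_stats(
    per_structure: dict[str, dict[int, int]],
    path_lengths: dict[str, int | None],
) -> tuple[dict[int, int], dict[str, int | None], set[int]]:
    """Aggregate per-structure MSA visit profiles.

    Returns the pooled per-MSA-number visit profile (N_path), the mean
    path length per structure (residue count), and the most-visited MSA
    number(s) — a set, since ties are reported together."""
    profile: dict[int, int] = {}
    for counts in per_structure.values():
        for num, c in counts.items():
            profile[num] = profile.get(num, 0) + c
    most_visited: set[int] = set()
    if profile:
        best = max(profile.values())
        most_visited = {n for n, c in profile.items() if c == best}
    return profile, dict(path_lengths), most_visited
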