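"""Clone inference from locBC co-occurrence across cells.

Cells grown from the same founder share an identical set of genomic
integrations, hence an identical set of locBCs — up to dropout. Per cell,
the ranked locBC UMI counts are cut at a knee point (maximum perpendicular
distance to the chord of the rank vs log1p(count) curve) to remove
low-count contaminating barcodes. Retained locBCs seen in strictly more
than ``min_cells_per_locbc`` cells become nodes of an undirected graph with
edges between locBCs that co-occur in the same cell; connected components
are clones. A cell whose retained locBCs all fall in one component is
assigned to it; cells spanning two or more components are flagged
"ambiguous" (presumptive doublets) and excluded from per-clone statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class ClonePartition:
    """locBC clusters (clones) and cell -> clone assignments."""

    clones: dict[str, frozenset[str]]  # clone id -> locBC set
    assignments: pd.Series  # cell -> clone id | "ambiguous" | "unassigned"

    @property
    def clone_sizes(self) -> pd.Series:
        assigned = self.assignments[
            ~self.assignments.isin(["ambiguous", "unassigned"])
        ]
        return assigned.value_counts().sort_index()

    def summary(self) -> dict:
        sizes = self.clone_sizes
        multi = sum(1 for locs in self.clones.values() if len(locs) > 1)
        return {
            "n_clones": len(self.clones),
            "n_multi_integration_clones": multi,
            "n_cells_assigned": int(sizes.sum()),
            "n_ambiguous": int((self.assignments == "ambiguous").sum()),
            "n_unassigned": int((self.assignments == "unassigned").sum()),
            "mean_integrations_per_clone": (
                float(np.mean([len(v) for v in self.clones.values()]))
                if self.clones
                else float("nan")
            ),
        }


def knee_index(counts_desc: np.ndarray) -> int:
    """Knee of a descending count curve: max perpendicular distance to the
    chord of the (rank, log1p count) curve. Returns the last retained index
    (inclusive). Degenerate curves (flat, or <=2 points) retain everything.
    """
    n = len(counts_desc)
    if n <= 2:
        return n - 1
    y = np.log1p(counts_desc.astype(float))
    x = np.arange(n, dtype=float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    if norm == 0 or dy == 0:  # flat curve: no knee, keep all
        return n - 1
    dist = np.abs(dx * (y - y[0]) - dy * (x - x[0])) / norm
    return int(np.argmax(dist))


def knee_filter_locbcs(counts: pd.DataFrame) -> dict[str, set[str]]:
    """Per cell, retain the locBCs above the knee of its ranked UMI counts.

    Cells with <= 2 detected locBCs retain all of them (a chord over two
    points carries no knee information).
    """
    retained: dict[str, set[str]] = {}
    cols = counts.columns.to_numpy()
    for cell, row in zip(counts.index, counts.to_numpy()):
        nz = np.flatnonzero(row)
        if nz.size == 0:
            retained[cell] = set()
            continue
        order = nz[np.argsort(-row[nz], kind="stable")]
        k = knee_index(row[order])
        retained[cell] = set(cols[order[: k + 1]])
    return retained


def build_clone_graph(
    retained: dict[str, set[str]],
    min_cells_per_locbc: int = 5,
    edge_min: int = 1,
) -> nx.Graph:
    """Link locBCs that co-occur in the same cells.

    Nodes are locBCs retained in strictly more than ``min_cells_per_locbc``
    cells; an edge joins two locBCs co-occurring in at least ``edge_min``
    cells, weighted by the co-occurrence count.
    """
    cell_count: dict[str, int] = {}
    for locs in retained.values():
        for loc in locs:
            cell_count[loc] = cell_count.get(loc, 0) + 1
    nodes = {loc for loc, c in cell_count.items() if c > min_cells_per_locbc}
    graph = nx.Graph()
    graph.add_nodes_from(
        (loc, {"n_cells": cell_count[loc]}) for loc in sorted(nodes)
    )
    weights: dict[tuple[str, str], int] = {}
    for locs in retained.values():
        kept = sorted(locs & nodes)
        for a, b in combinations(kept, 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1
    graph.add_weighted_edges_from(
        (a, b, w) for (a, b), w in weights.items() if w >= edge_min
    )
    return graph


def assign_cells_to_clones(
    graph: nx.Graph, retained: dict[str, set[str]]
) -> ClonePartition:
    """Clones are connected components; cells map to the unique component
    containing their retained locBCs, or "ambiguous" when they span several.
    """
    components = sorted(
        nx.connected_components(graph), key=lambda c: (-len(c), min(c))
    )
    clone_ids = [f"clone_{i:03d}" for i in range(len(components))]
    clones = {
        cid: frozenset(comp) for cid, comp in zip(clone_ids, components)
    }
    loc_to_clone = {
        loc: cid for cid, comp in clones.items() for loc in comp
    }
    labels = {}
    for cell, locs in retained.items():
        hit = {loc_to_clone[loc] for loc in locs if loc in loc_to_clone}
        if not hit:
            labels[cell] = "unassigned"
        elif len(hit) == 1:
            labels[cell] = hit.pop()
        else:
            labels[cell] = "ambiguous"
    assignments = pd.Series(labels, name="clone_id").sort_index()
    return ClonePartition(clones, assignments)


def identify_clones(
    counts: pd.DataFrame,
    min_cells_per_locbc: int = 5,
    edge_min: int = 1,
) -> tuple[ClonePartition, nx.Graph]:
    """Knee-filter, build the clonal graph, and assign cells, in one call."""
    retained = knee_filter_locbcs(counts)
    graph = build_clone_graph(retained, min_cells_per_locbc, edge_min)
    return assign_cells_to_clones(graph, retained), graph
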