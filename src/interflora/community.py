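"""Genus-level interaction networks and donor clustering.

Interacting KO pairs are projected to genus pairs (each genus contributes one
side of the pair), per-donor presence of each genus pair is recorded,
near-universal pairs are split off as the community-wide core, and donors are
hierarchically clustered on the remaining group-specific pairs.  Each donor
cluster then yields its own genus interaction network.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class GenusPair:
    """A genus pair supported by one or more interacting KO pairs."""

    genus_a: str
    genus_b: str
    supporting_ko_pairs: list[tuple[str, str]] = field(default_factory=list)
    supporter_scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genus_a > self.genus_b:
            raise ValueError("genus pair not canonically ordered")

    @property
    def key(self) -> tuple[str, str]:
        return (self.genus_a, self.genus_b)

    @property
    def aggregate_score(self) -> float:
        return float(sum(self.supporter_scores))

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.supporter_scores)) if self.supporter_scores else 0.0


@dataclass
class DonorPresenceMatrix:
    donors: list[str]
    pair_keys: list[tuple[str, str]]
    matrix: np.ndarray  # (n_donors, n_pairs) int8 in {0,1}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.donors), len(self.pair_keys)):
            raise ValueError("presence matrix shape mismatch")


@dataclass
class DonorClustering:
    donors: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    assignment: dict[str, int]
    n_clusters: int

    def members(self, cluster_id: int) -> list[str]:
        return [d for d, c in self.assignment.items() if c == cluster_id]


def _genus_carriers(ko_by_genus: pd.DataFrame, ko: str, epsilon: float) -> set[str]:
    if ko not in ko_by_genus.index:
        return set()
    row = ko_by_genus.loc[ko]
    return set(row.index[row > epsilon])


def ko_pairs_to_genus_pairs(
    interacting: Sequence,
    ko_by_genus: pd.DataFrame,
    epsilon: float = 0.0,
    strict_complement: bool = False,
) -> list[GenusPair]:
    """Project interacting KO pairs to genus pairs.

    For KO pair (A, B) a genus pair (g, h), g != h, is emitted whenever g
    carries A and h carries B or vice versa.  ``strict_complement`` requires
    the contributing genus to *lack* the partner KO, enforcing true
    complementarity.  Each (genus pair, KO pair) combination counts once.
    """
    acc: dict[tuple[str, str], GenusPair] = {}
    seen: set[tuple[tuple[str, str], tuple[str, str]]] = set()
    for sp in interacting:
        ka, kb, score = sp.ko_a, sp.ko_b, sp.score
        ga0 = _genus_carriers(ko_by_genus, ka, epsilon)
        gb0 = _genus_carriers(ko_by_genus, kb, epsilon)
        if strict_complement:
            ga, gb = ga0 - gb0, gb0 - ga0
        else:
            ga, gb = ga0, gb0
        for side_a, side_b in ((ga, gb), (gb, ga)):
            for g in side_a:
                for h in side_b:
                    if g == h:
                        continue
                    gp_key = tuple(sorted((g, h)))
                    tag = (gp_key, (ka, kb))
                    if tag in seen:
                        continue
                    seen.add(tag)
                    if gp_key not in acc:
                        acc[gp_key] = GenusPair(gp_key[0], gp_key[1])
                    acc[gp_key].supporting_ko_pairs.append((ka, kb))
                    acc[gp_key].supporter_scores.append(score)
    return [acc[k] for k in sorted(acc)]


def donor_presence(
    genus_pairs: Sequence[GenusPair],
    donor_tables: Mapping[str, pd.DataFrame],
    epsilon: float = 0.0,
) -> DonorPresenceMatrix:
    """Per-donor presence of each genus pair.

    ``donor_tables`` maps donor id to a KO x genus abundance table.  A genus
    pair is present in a donor when at least one supporting KO pair has one
    KO detected in genus_a and the other in genus_b (either orientation)
    above ``epsilon``.
    """
    donors = sorted(donor_tables)
    keys = [gp.key for gp in genus_pairs]
    mat = np.zeros((len(donors), len(keys)), dtype=np.int8)
    for i, donor in enumerate(donors):
        table = donor_tables[donor]
        cache: dict[tuple[str, str], bool] = {}

        def detected(ko: str, genus: str) -> bool:
            k = (ko, genus)
            if k not in cache:
                cache[k] = (
                    ko in table.index
                    and genus in table.columns
                    and table.at[ko, genus] > epsilon
                )
            return cache[k]

        for j, gp in enumerate(genus_pairs):
            hit = False
            for ka, kb in gp.supporting_ko_pairs:
                if (detected(ka, gp.genus_a) and detected(kb, gp.genus_b)) or (
                    detected(kb, gp.genus_a) and detected(ka, gp.genus_b)
                ):
                    hit = True
                    break
            mat[i, j] = 1 if hit else 0
    return DonorPresenceMatrix(donors=donors, pair_keys=keys, matrix=mat)


def split_common(
    matrix: DonorPresenceMatrix, common_fraction: float = 0.9
) -> tuple[list[tuple[str, str]], DonorPresenceMatrix]:
    """Split genus pairs present in >= ``common_fraction`` of donors
    (the community-wide core) from the group-specific remainder."""
    if not (0 < common_fraction <= 1):
        raise ValueError("common_fraction must be in (0, 1]")
    frac = matrix.matrix.mean(axis=0)
    common_mask = frac >= common_fraction
    common = [k for k, m in zip(matrix.pair_keys, common_mask) if m]
    specific = DonorPresenceMatrix(
        donors=list(matrix.donors),
        pair_keys=[k for k, m in zip(matrix.pair_keys, common_mask) if not m],
        matrix=matrix.matrix[:, ~common_mask],
    )
    return common, specific


def cluster_donors(
    specific_matrix: DonorPresenceMatrix,
    n_clusters: Optional[int] = None,
    linkage_method: str = "average",
    distance_metric: str = "jaccard",
    cut_height: Optional[float] = None,
) -> DonorClustering:
    """Agglomerative clustering of donors on binary genus-pair presence.

    Default Jaccard distance with average linkage; the tree is cut either to
    ``n_clusters`` or at ``cut_height``.  scipy's linkage resolves equal
    merge distances deterministically by index order, so results are stable
    for a fixed input ordering.
    """
    n = len(specific_matrix.donors)
    if n == 0 or specific_matrix.matrix.size == 0:
        raise ValueError("empty presence matrix")
    if n_clusters is None and cut_height is None:
        raise ValueError("one of n_clusters or cut_height is required")
    if n_clusters is not None and n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds donor count {n}")
    data = specific_matrix.matrix.astype(bool)
    with np.errstate(invalid="ignore"):
        dists = pdist(data, metric=distance_metric)
    dists = np.nan_to_num(dists, nan=0.0)  # two all-zero donors are identical
    z = hierarchy.linkage(dists, method=linkage_method)
    if n_clusters is not None:
        labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
        k = int(labels.max())
    else:
        labels = hierarchy.fcluster(z, t=cut_height, criterion="distance")
        k = int(labels.max())
    assignment = {d: int(c) for d, c in zip(specific_matrix.donors, labels)}
    return DonorClustering(
        donors=list(specific_matrix.donors), linkage=z, assignment=assignment, n_clusters=k
    )


def dendrogram_newick(clustering: DonorClustering) -> str:
    """Serialize the donor dendrogram as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(clustering.linkage)
    names = clustering.donors

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def export_cluster_network(
    cluster_donor_ids: Sequence[str],
    genus_pairs: Sequence[GenusPair],
    presence: DonorPresenceMatrix,
    edge_min_aggregate: float = 15.0,
    keep_isolated: bool = False,
) -> nx.Graph:
    """Build the genus interaction network of one donor cluster.

    Edges are genus pairs present in at least one of the cluster's donors
    with aggregate (summed supporter) score >= ``edge_min_aggregate``; edge
    weight is the aggregate score, ``mean_score`` the average supporter
    score.  Node weight is the total aggregate of its displayed incident
    edges.  ``keep_isolated`` retains genera whose every pair fell below the
    filter.
    """
    donor_idx = [presence.donors.index(d) for d in cluster_donor_ids]
    key_idx = {k: j for j, k in enumerate(presence.pair_keys)}
    graph = nx.Graph()
    for gp in genus_pairs:
        j = key_idx.get(gp.key)
        if j is None:
            continue
        present = bool(presence.matrix[donor_idx, j].any()) if donor_idx else False
        if not present:
            continue
        if gp.aggregate_score >= edge_min_aggregate:
            graph.add_edge(
                gp.genus_a,
                gp.genus_b,
                weight=gp.aggregate_score,
                mean_score=gp.mean_score,
                n_supporters=len(gp.supporting_ko_pairs),
            )
        elif keep_isolated:
            graph.add_node(gp.genus_a)
            graph.add_node(gp.genus_b)
    for node in graph.nodes:
        graph.nodes[node]["weight"] = float(
            sum(d["weight"] for _, _, d in graph.edges(node, data=True))
        )
    return graph


# ---------------------------------------------------------------------------
# I/O

def write_network_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def write_network_tsv(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["genus_a", "genus_b", "aggregate_score", "mean_score", "n_supporters"])
        for u, v, d in sorted(graph.edges(data=True)):
            a, b = sorted((u, v))
            w.writerow([a, b, d["weight"], d["mean_score"], d["n_supporters"]])


def write_assignment_tsv(clustering: DonorClustering, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["donor", "cluster"])
        for d in clustering.donors:
            w.writerow([d, clustering.assignment[d]])
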