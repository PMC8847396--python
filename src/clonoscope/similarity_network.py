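"""CDR3 amino-acid edit-distance similarity networks across repertoires.

Every (clone, sample) pair is a node; identical clonotypes from two mice
are distinct nodes joined at distance 0.  Edges connect clones whose CDR3
amino-acid sequences are within an edit-distance threshold, either on the
sum of the TRB and TRA distances (default) or per chain.  Connectivity
within versus between condition groups quantifies whether clonal
convergence tracks the condition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from ._errors import ValidationError
from .model import AMINO_ACIDS, Repertoire

_AA_RE = re.compile(f"^[{AMINO_ACIDS}]*$")

MODES = ("sum", "per_chain")


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost insert/delete/substitute) between
    two amino-acid strings.

    Symmetric; 0 iff the strings are equal.  Empty strings are allowed.
    """
    for s in (a, b):
        if not _AA_RE.match(s):
            bad = sorted(set(s) - set(AMINO_ACIDS))
            raise ValidationError(f"non-amino-acid characters in {s!r}: {bad}")
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _distance_matrix(strings: list[str]) -> np.ndarray:
    """All-pairs Levenshtein distances between unique strings."""
    n = len(strings)
    d = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = edit_distance(strings[i], strings[j])
    return d


@dataclass
class SimilarityNetwork:
    """An undirected clone-similarity graph plus its construction parameters.

    Node keys are ``(sample_id, clone_id)``; node attributes carry
    group_label and both CDR3 amino-acid sequences; edge attributes carry
    dist_b, dist_a and dist_total.
    """

    graph: nx.Graph
    threshold: int
    mode: str

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "clone_id": c, **attrs}
            for (s, c), attrs in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "clone_id", "group_label", "cdr3b_aa", "cdr3a_aa"]
        )

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, attrs in self.graph.edges(data=True):
            u, v = sorted((u, v))
            rows.append({
                "sample_i": u[0], "clone_i": u[1],
                "sample_j": v[0], "clone_j": v[1],
                "dist_b": attrs["dist_b"], "dist_a": attrs["dist_a"],
                "dist_total": attrs["dist_total"],
            })
        cols = ["sample_i", "clone_i", "sample_j", "clone_j", "dist_b", "dist_a", "dist_total"]
        return pd.DataFrame(sorted(rows, key=lambda r: tuple(r.values())), columns=cols)

    def write_graphml(self, path) -> None:
        g = nx.relabel_nodes(self.graph, {n: f"{n[0]}|{n[1]}" for n in self.graph.nodes})
        nx.write_graphml(g, path)


def build_network(
    reps: list[Repertoire],
    threshold: int = 7,
    mode: str = "sum",
    dedupe: bool = False,
) -> SimilarityNetwork:
    """Build the cross-sample CDR3 similarity network.

    mode="sum" draws an edge when dist_b + dist_a <= threshold (the
    default); mode="per_chain" when both dist_b <= threshold and
    dist_a <= threshold.  With ``dedupe``, clonotypes identical at the
    amino-acid level within one sample collapse to a single node.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")

    nodes: list[tuple[tuple[str, str], dict]] = []
    seen_aa: set[tuple[str, str, str]] = set()
    for rep in reps:
        for clone in sorted(rep.clones, key=lambda c: c.clone_id):
            if dedupe:
                key = (rep.sample_id, clone.cdr3b_aa, clone.cdr3a_aa)
                if key in seen_aa:
                    continue
                seen_aa.add(key)
            nodes.append((
                (rep.sample_id, clone.clone_id),
                {"group_label": rep.group_label,
                 "cdr3b_aa": clone.cdr3b_aa, "cdr3a_aa": clone.cdr3a_aa},
            ))

    g = nx.Graph()
    g.add_nodes_from(nodes)
    if nodes:
        # distances are computed once per unique sequence, then broadcast
        b_seqs = sorted({attrs["cdr3b_aa"] for _, attrs in nodes})
        a_seqs = sorted({attrs["cdr3a_aa"] for _, attrs in nodes})
        b_index = {s: i for i, s in enumerate(b_seqs)}
        a_index = {s: i for i, s in enumerate(a_seqs)}
        db = _distance_matrix(b_seqs)
        da = _distance_matrix(a_seqs)
        bi = np.array([b_index[attrs["cdr3b_aa"]] for _, attrs in nodes])
        ai = np.array([a_index[attrs["cdr3a_aa"]] for _, attrs in nodes])
        db_full = db[np.ix_(bi, bi)]
        da_full = da[np.ix_(ai, ai)]
        if mode == "sum":
            adj = (db_full.astype(np.int64) + da_full) <= threshold
        else:
            adj = (db_full <= threshold) & (da_full <= threshold)
        ii, jj = np.where(np.triu(adj, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g.add_edge(
                nodes[i][0], nodes[j][0],
                dist_b=int(db_full[i, j]), dist_a=int(da_full[i, j]),
                dist_total=int(db_full[i, j]) + int(da_full[i, j]),
            )
    return SimilarityNetwork(graph=g, threshold=threshold, mode=mode)


@dataclass
class EdgeGroupSummary:
    """Edge counts partitioned by endpoint group labels."""

    within_group_edges: int
    between_group_edges: int
    group_pair_counts: pd.DataFrame  # symmetric group x group matrix
    degree_table: pd.DataFrame

    @property
    def total_edges(self) -> int:
        return self.within_group_edges + self.between_group_edges


def edge_group_summary(net: SimilarityNetwork) -> EdgeGroupSummary:
    """Partition edges into within-group and between-group counts."""
    g = net.graph
    groups = sorted({attrs["group_label"] for _, attrs in g.nodes(data=True)})
    pair_counts = pd.DataFrame(0, index=groups, columns=groups)
    within = between = 0
    for u, v in g.edges():
        gu, gv = g.nodes[u]["group_label"], g.nodes[v]["group_label"]
        pair_counts.loc[gu, gv] += 1
        if gu != gv:
            pair_counts.loc[gv, gu] += 1
            between += 1
        else:
            within += 1
    degree = pd.DataFrame(
        [{"sample_id": n[0], "clone_id": n[1], "degree": d}
         for n, d in sorted(g.degree())],
        columns=["sample_id", "clone_id", "degree"],
    )
    return EdgeGroupSummary(
        within_group_edges=within,
        between_group_edges=between,
        group_pair_counts=pair_counts,
        degree_table=degree,
    )


def threshold_sweep(
    reps: list[Repertoire], thresholds: list[int], mode: str = "sum"
) -> pd.DataFrame:
    """Edge counts (total / within / between group) over a threshold range."""
    if not thresholds:
        raise ValidationError("thresholds must be non-empty")
    rows = []
    for t in sorted(thresholds):
        if not reps:
            continue
        net = build_network(reps, threshold=t, mode=mode)
        summary = edge_group_summary(net)
        rows.append({
            "threshold": t, "n_edges": net.n_edges,
            "within": summary.within_group_edges,
            "between": summary.between_group_edges,
        })
    return pd.DataFrame(rows, columns=["threshold", "n_edges", "within", "between"])
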