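"""Signal-transduction network construction and key-gene ranking.

The network intersects two evidence sources: (1) expression-based edges —
all unordered gene pairs whose Pearson correlation across samples is
significant under the two-sided t-test t = r * sqrt(d-2) / sqrt(1-r^2) —
and (2) a curated catalog of directed, typed interactions (activation,
phosphorylation, ...).  A catalog relation survives only if its gene pair
is significantly co-expressed; the result is a directed typed graph on
which degree (distinct neighbors, direction-blind), indegree (number of
source genes), outdegree (number of target genes) and normalized
betweenness centrality are computed.  Key genes are ranked by betweenness,
the fraction of shortest paths between other node pairs that pass through a
node — the intermediary-capacity criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, InteractionCatalog


def correlation_pvalue(r: float, d: int) -> float:
    """Two-sided p for a Pearson correlation from d points (t transform)."""
    if d < 3:
        raise ValueError("need at least 3 points")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(d - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), d - 2))


def correlation_edges(
    matrix: ExpressionMatrix,
    genes: Iterable[str],
    alpha: float = 0.05,
    use_abs: bool = True,
    on_means: bool = False,
) -> pd.DataFrame:
    """Significantly correlated unordered gene pairs.

    Correlations are computed on log2 signals across all samples by default
    (``on_means`` switches to per-condition means, rarely advisable for a
    three-condition series where 3-point correlations are degenerate).
    With ``use_abs`` on, inclusion uses the two-sided test so strong
    negative correlations qualify; off, only positively correlated pairs
    with one-sided p < alpha are kept.  The signed r is always reported.
    Zero-variance genes are skipped with a warning.
    """
    genes = list(dict.fromkeys(genes))
    log = matrix.log2().loc[genes]
    if on_means:
        data = pd.DataFrame(
            {c: log[matrix.samples_of(c)].mean(axis=1) for c in matrix.condition_order}
        ).to_numpy(dtype=float)
    else:
        data = log.to_numpy(dtype=float)
    d = data.shape[1]
    if d < 3:
        raise ValueError("need at least 3 expression points per gene")
    sd = data.std(axis=1)
    keep = sd > 0.0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-variance gene(s) skipped in correlation",
            RuntimeWarning, stacklevel=2,
        )
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "p"])
    sub = data[idx]
    corr = np.clip(np.corrcoef(sub), -1.0, 1.0)
    ii, jj = np.triu_indices(idx.size, k=1)
    r = corr[ii, jj]
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(d - 2) / np.sqrt(1.0 - r * r)
    two_sided = 2.0 * stats.t.sf(np.abs(t), d - 2)
    two_sided[np.abs(r) == 1.0] = 0.0
    if use_abs:
        p = two_sided
        ok = p < alpha
    else:
        p = np.where(r > 0, two_sided / 2.0, 1.0 - two_sided / 2.0)
        ok = (r > 0) & (p < alpha)
    names = np.array([genes[i] for i in idx])
    return pd.DataFrame(
        {"gene_a": names[ii[ok]], "gene_b": names[jj[ok]], "r": r[ok], "p": p[ok]},
        columns=["gene_a", "gene_b", "r", "p"],
    )


@dataclass
class GeneNetwork:
    """Directed typed gene graph with per-node centrality statistics."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def degree(self, node: str) -> int:
        """Distinct neighbors regardless of edge direction."""
        return len(set(self.graph.predecessors(node)) | set(self.graph.successors(node)))

    def indegree(self, node: str) -> int:
        return len(set(self.graph.predecessors(node)))

    def outdegree(self, node: str) -> int:
        return len(set(self.graph.successors(node)))

    def node_table(self, treat_as: Literal["directed", "undirected"] = "undirected") -> pd.DataFrame:
        bc = betweenness_centrality(self, treat_as=treat_as)
        rows = [
            {
                "gene": n,
                "degree": self.degree(n),
                "indegree": self.indegree(n),
                "outdegree": self.outdegree(n),
                "bc": bc[n],
            }
            for n in self.nodes
        ]
        return pd.DataFrame(rows, columns=["gene", "degree", "indegree", "outdegree", "bc"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "relations": ";".join(d["relations"])}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "relations"])


def build_signal_net(edges: pd.DataFrame, catalog: InteractionCatalog) -> GeneNetwork:
    """Restrict the interaction catalog to significantly correlated pairs.

    A catalog relation u -> v survives if {u, v} is a correlated pair in
    either orientation; nodes with no surviving relation are dropped.  An
    empty catalog (or empty edge set) yields the empty network.
    """
    pairs: set[frozenset[str]] = {
        frozenset((a, b)) for a, b in zip(edges.get("gene_a", []), edges.get("gene_b", []))
    }
    g = nx.DiGraph()
    for src, kind, dst in catalog.relations:
        if frozenset((src, dst)) in pairs:
            if g.has_edge(src, dst):
                rel = g[src][dst]["relations"]
                if kind not in rel:
                    g[src][dst]["relations"] = rel + (kind,)
            else:
                g.add_edge(src, dst, relations=(kind,))
    return GeneNetwork(graph=g)


def betweenness_centrality(
    network: GeneNetwork, treat_as: Literal["directed", "undirected"] = "undirected"
) -> dict[str, float]:
    """Normalized betweenness centrality of every node.

    Shortest paths are unweighted (Brandes accumulation); normalization is
    (N-1)(N-2)/2 pair terms for the undirected view and (N-1)(N-2) for the
    directed one, so values lie in [0, 1].  Networks with fewer than three
    nodes have no interior pairs: all centralities are 0 by convention.
    """
    g: nx.Graph | nx.DiGraph
    if treat_as == "undirected":
        g = network.graph.to_undirected(as_view=False)
    elif treat_as == "directed":
        g = network.graph
    else:
        raise ValueError("treat_as must be 'directed' or 'undirected'")
    if g.number_of_nodes() < 3:
        return {n: 0.0 for n in g.nodes}
    return nx.betweenness_centrality(g, normalized=True)


def rank_key_genes(
    network: GeneNetwork,
    top_k: int | None = None,
    treat_as: Literal["directed", "undirected"] = "undirected",
) -> pd.DataFrame:
    """Rank genes by descending betweenness, ties by descending degree then
    lexicographic gene id; return the top_k with full node statistics."""
    table = network.node_table(treat_as=treat_as)
    if table.empty:
        return table
    table = table.sort_values(
        ["bc", "degree", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return table
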