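"""Weighted gene-gene and miRNA-target networks: construction, the
differential-expression weight update, and the shuffling nulls used for
empirical FDR control.

A network maps each source gene (the mutated-gene side) to partner genes
(the expression side) with weights in (0, 1], interpreted downstream as
the prior probability that the partner is dysregulated given a functional
mutation in the source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mapping import MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "MiRNATargetRecord",
    "build_mirna_network",
    "update_weights",
    "shuffle_network",
    "shuffle_mutation_matrix",
    "induced_subgraphs",
    "read_edge_list",
    "write_edge_list",
    "read_mirna_targets",
]


@dataclass(frozen=True)
class MiRNATargetRecord:
    """One predicted miRNA-target interaction.

    ``t_score`` is the target-site context-score percentile in [0, 100];
    ``n_sites`` the number of predicted binding sites in the target.
    """

    mirna_id: str
    target: str
    n_sites: int
    t_score: float

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (0 <= self.t_score <= 100):
            raise ValueError(f"t_score {self.t_score} outside [0, 100]")


class WeightedNetwork:
    """source -> {partner: weight} adjacency with weights in (0, 1]."""

    def __init__(self, edges: Mapping[str, Mapping[str, float]] | None = None):
        self.adj: dict[str, dict[str, float]] = {}
        if edges:
            for src, partners in edges.items():
                for p, w in partners.items():
                    self.add_edge(src, p, w)

    def add_edge(self, source: str, partner: str, weight: float) -> None:
        if not (0 < weight <= 1):
            raise ValueError(f"weight {weight} outside (0, 1]")
        d = self.adj.setdefault(source, {})
        if partner in d:
            raise ValueError(f"duplicate edge ({source}, {partner})")
        d[partner] = float(weight)

    def partners(self, source: str) -> dict[str, float]:
        return self.adj.get(source, {})

    def sources(self) -> list[str]:
        return list(self.adj)

    @property
    def n_edges(self) -> int:
        return sum(len(d) for d in self.adj.values())

    def weights(self) -> list[float]:
        return [w for d in self.adj.values() for w in d.values()]

    def partner_universe(self) -> list[str]:
        return sorted({p for d in self.adj.values() for p in d})

    def edges(self) -> list[tuple[str, str, float]]:
        return [(s, p, w) for s, d in self.adj.items() for p, w in d.items()]

    def copy(self) -> "WeightedNetwork":
        out = WeightedNetwork()
        out.adj = {s: dict(d) for s, d in self.adj.items()}
        return out


def build_mirna_network(records: Iterable[MiRNATargetRecord]) -> WeightedNetwork:
    """miRNA -> target network from predicted interactions.

    Targets with fewer than two predicted binding sites are filtered out
    (false-positive control); edge weight is t_score / 100; zero-weight
    edges are dropped.
    """
    net = WeightedNetwork()
    for r in records:
        if r.n_sites < 2:
            continue
        w = r.t_score / 100.0
        if w <= 0:
            continue
        net.add_edge(r.mirna_id, r.target, w)
    return net


def update_weights(
    net: WeightedNetwork,
    mut_matrix: MutationMatrix,
    expr_values: pd.DataFrame,
    alpha: float = 0.05,
    global_adjust: bool = False,
) -> WeightedNetwork:
    """Sharpen network priors with cohort differential expression.

    For each mutated source gene g, each partner p is tested for
    differential expression between g-mutated and non-mutated samples
    (two-sided Wilcoxon rank-sum).  P-values are BH-adjusted across g's
    partners (or globally with ``global_adjust``).  If any partner reaches
    adjusted p <= alpha, those partners' weights become 1 and g's other
    partners are dropped; otherwise g's edges pass through unchanged.
    Sources with fewer than 2 mutated or 2 non-mutated samples also pass
    through unchanged.
    """
    if not set(mut_matrix.samples) <= set(expr_values.columns):
        raise ValueError("mutation-matrix samples not all present in expression")
    expr = expr_values[list(mut_matrix.samples)]
    out = WeightedNetwork()
    tests: list[tuple[str, str, float]] = []  # (source, partner, p)
    per_source: dict[str, list[tuple[str, float, float]]] = {}
    for src in net.sources():
        partners = net.partners(src)
        if src not in mut_matrix.genes:
            for p, w in partners.items():
                out.add_edge(src, p, w)
            continue
        mut_mask = mut_matrix.values.loc[src].to_numpy() == 1
        if mut_mask.sum() < 2 or (~mut_mask).sum() < 2:
            for p, w in partners.items():
                out.add_edge(src, p, w)
            continue
        rows = []
        for p, w in partners.items():
            if p not in expr.index:
                continue
            v = expr.loc[p].to_numpy(dtype=float)
            stat_p = stats.ranksums(v[mut_mask], v[~mut_mask]).pvalue
            rows.append((p, w, float(stat_p)))
            tests.append((src, p, float(stat_p)))
        if rows:
            per_source[src] = rows
        else:
            for p, w in partners.items():
                out.add_edge(src, p, w)
    if global_adjust and tests:
        adj = dict(
            zip(
                [(s, p) for s, p, _ in tests],
                multipletests([pv for _, _, pv in tests], method="fdr_bh")[1],
            )
        )
    for src, rows in per_source.items():
        if global_adjust:
            padj = np.array([adj[(src, p)] for p, _, _ in rows])
        else:
            padj = multipletests([pv for _, _, pv in rows], method="fdr_bh")[1]
        sig = padj <= alpha
        if sig.any():
            for (p, _, _), s in zip(rows, sig):
                if s:
                    out.add_edge(src, p, 1.0)
        else:
            for p, w in net.partners(src).items():
                out.add_edge(src, p, w)
    return out


def shuffle_network(net: WeightedNetwork, seed: int) -> WeightedNetwork:
    """Degree-preserving null network.

    Each source keeps its edge count; partner slots are refilled by uniform
    sampling without replacement from the partner universe, and the global
    multiset of weights is permuted onto the new edges.
    """
    rng = np.random.default_rng(seed)
    universe = np.array(net.partner_universe())
    weights = np.array(net.weights())
    rng.shuffle(weights)
    out = WeightedNetwork()
    k = 0
    for src in net.sources():
        deg = len(net.partners(src))
        if deg > len(universe):
            raise ValueError(
                f"source {src} degree {deg} exceeds partner universe "
                f"size {len(universe)}"
            )
        chosen = rng.choice(universe, size=deg, replace=False)
        for p in chosen:
            out.add_edge(src, str(p), float(weights[k]))
            k += 1
    return out


def shuffle_mutation_matrix(m: MutationMatrix, seed: int) -> MutationMatrix:
    """Null mutation matrix: permute gene labels across rows.

    Per-sample mutation burden (column sums) and the total number of
    mutated (gene, sample) pairs are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(m.genes)
    perm = rng.permutation(len(genes))
    shuffled = m.values.copy()
    shuffled.index = genes[perm]
    return MutationMatrix(shuffled.sort_index(), m.channel)


def induced_subgraphs(
    genes: Iterable[str], net: WeightedNetwork
) -> tuple[list[set[str]], list[str]]:
    """Connected components of the undirected subgraph induced by ``genes``.

    Returns (components of size >= 2, isolated nodes); predicted genes not
    connected to any other predicted gene count as isolated.
    """
    genes = set(genes)
    g = nx.Graph()
    g.add_nodes_from(genes)
    for src, p, _w in net.edges():
        if src in genes and p in genes and src != p:
            g.add_edge(src, p)
    comps = [set(c) for c in nx.connected_components(g)]
    clusters = sorted((c for c in comps if len(c) >= 2), key=min)
    isolated = sorted(n for c in comps if len(c) == 1 for n in c)
    return clusters, isolated


# ---------------------------------------------------------------------------
# I/O

def read_edge_list(path: str | Path) -> WeightedNetwork:
    """3-column TSV (source, partner, weight) with header."""
    df = pd.read_csv(path, sep="\t")
    net = WeightedNetwork()
    for r in df.itertuples(index=False):
        net.add_edge(str(r[0]), str(r[1]), float(r[2]))
    return net


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\tpartner\tweight\n")
        for s, p, w in net.edges():
            fh.write(f"{s}\t{p}\t{w:.6g}\n")


def read_mirna_targets(path: str | Path) -> list[MiRNATargetRecord]:
    """TSV (mirna, target, n_sites, t_score_percentile) with header."""
    df = pd.read_csv(path, sep="\t")
    return [
        MiRNATargetRecord(str(r[0]), str(r[1]), int(r[2]), float(r[3]))
        for r in df.itertuples(index=False)
    ]
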