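"""Disease-disease similarity from pathway-profile overlap.

Two diseases whose profiles share more enriched pathways than chance
expects are connected.  Significance comes from the hypergeometric
upper tail: with a universe of N pathways, n1 enriched in one disease
and n2 in the other, the p-value is P(X >= k) for the observed overlap
k, where X is hypergeometric(N, n1, n2).  Edges with p below a cutoff
(default 0.05, uncorrected, with optional BH across pairs) form an
undirected network weighted by -log10(p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
from scipy.stats import hypergeom

from .enrichment import bh_fdr
from .profiles import PathwayProfile, _check_universe

__all__ = [
    "ProfileCorrelation",
    "DiseaseNetwork",
    "hypergeom_overlap_p",
    "correlate_profiles",
    "build_network",
    "to_networkx",
    "write_edge_list_tsv",
    "write_graphml",
]


@dataclass(frozen=True)
class ProfileCorrelation:
    """Hypergeometric overlap test between two disease profiles."""

    disease_a: str
    disease_b: str
    N: int
    n1: int
    n2: int
    k: int
    p_value: float


@dataclass(frozen=True)
class DiseaseNetwork:
    """Significance-thresholded, undirected disease-similarity network."""

    nodes: tuple
    edges: tuple  # (a, b, weight, p_value)


def hypergeom_overlap_p(N: int, n1: int, n2: int, k: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ hypergeom(N, n1, n2).

    Symmetric in n1 and n2; P(X >= 0) = 1 exactly.
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError(f"need 0 <= n1, n2 <= N; got N={N}, n1={n1}, n2={n2}")
    if not (0 <= k <= min(n1, n2)):
        raise ValueError(f"need 0 <= k <= min(n1, n2); got k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, n1, n2))


def correlate_profiles(profiles: Sequence[PathwayProfile]) -> list:
    """Score every unordered pair of profiles on their shared universe."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    universe = _check_universe(profiles)
    labels = [p.disease_label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate disease labels")
    N = len(universe)
    out = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            a, b = profiles[i], profiles[j]
            sa, sb = a.enriched_set, b.enriched_set
            out.append(
                ProfileCorrelation(
                    disease_a=a.disease_label,
                    disease_b=b.disease_label,
                    N=N,
                    n1=len(sa),
                    n2=len(sb),
                    k=len(sa & sb),
                    p_value=hypergeom_overlap_p(N, len(sa), len(sb), len(sa & sb)),
                )
            )
    return out


def build_network(
    correlations: Sequence[ProfileCorrelation],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> DiseaseNetwork:
    """Keep edges with p < alpha (strict); weight = -log10(p).

    ``bh_correct=True`` applies Benjamini-Hochberg across all pairs and
    thresholds the q-values instead.  All diseases appear as nodes even
    when isolated.
    """
    import math

    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    correlations = list(correlations)
    nodes = sorted({c.disease_a for c in correlations} | {c.disease_b for c in correlations})
    pvals = [c.p_value for c in correlations]
    crit = bh_fdr(pvals) if bh_correct else pvals
    edges = tuple(
        (c.disease_a, c.disease_b, -math.log10(c.p_value), c.p_value)
        for c, v in zip(correlations, crit)
        if v < alpha
    )
    return DiseaseNetwork(nodes=tuple(nodes), edges=edges)


def to_networkx(network: DiseaseNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for a, b, weight, p in network.edges:
        g.add_edge(a, b, weight=weight, p_value=p)
    return g


def write_edge_list_tsv(correlations: Sequence[ProfileCorrelation], path, alpha: float | None = None, header_comment: str | None = None) -> None:
    """All pairwise overlap tests as TSV; flag marks p < alpha when given."""
    import math

    with open(path, "wt", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("disease_a\tdisease_b\tk\tn1\tn2\tN\tp_value\tweight\tsignificant\n")
        for c in sorted(correlations, key=lambda c: (c.p_value, c.disease_a, c.disease_b)):
            sig = "" if alpha is None else str(int(c.p_value < alpha))
            fh.write(
                f"{c.disease_a}\t{c.disease_b}\t{c.k}\t{c.n1}\t{c.n2}\t{c.N}\t"
                f"{c.p_value:.6g}\t{-math.log10(c.p_value):.6g}\t{sig}\n"
            )


def write_graphml(network: DiseaseNetwork, path) -> None:
    nx.write_graphml(to_networkx(network), path)
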