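"""Within-module relevance networks from residual correlations.

A relevance network connects genes whose pairwise correlation magnitude
clears a fixed threshold (default |r| >= 0.6). Edges are restricted to
pairs within the same co-expression module; the signed correlation is kept
on every edge because direction matters for interpretation even though the
threshold is on |r|. Components smaller than ``min_component_size``
(default 5) are retained in the data structure but flagged not-depicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from eggprint.dataio import ExpressionMatrix
from eggprint.fingerprint import ModulePartition, ResidualMatrix

__all__ = ["RelevanceNetwork", "build_relevance_networks", "write_sif", "write_graphml"]


class NetworkError(ValueError):
    pass


@dataclass
class RelevanceNetwork:
    """Graph over genes with signed-correlation edges and component labels.

    Node attributes: ``module``. Edge attributes: ``r`` (signed), ``abs_r``.
    ``components`` lists node sets, largest first; ``depicted`` marks those
    meeting the minimum size.
    """

    graph: nx.Graph
    threshold: float
    min_component_size: int

    @property
    def components(self) -> list[set]:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))

    @property
    def depicted_components(self) -> list[set]:
        return [c for c in self.components if len(c) >= self.min_component_size]

    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["r"]) for a, b, d in self.graph.edges(data=True)]


def build_relevance_networks(
    residuals: ResidualMatrix | ExpressionMatrix,
    partition: ModulePartition,
    threshold: float = 0.6,
    min_component_size: int = 5,
    correlation: str = "pearson",
    within_module_only: bool = True,
) -> RelevanceNetwork:
    """Threshold pairwise residual correlations into a gene graph.

    For each module, every member pair with |Pearson r| >= ``threshold``
    becomes an edge carrying the signed r. ``within_module_only=False``
    allows exploratory cross-module edges.
    """
    if not 0.0 < threshold <= 1.0:
        raise NetworkError("threshold must be in (0, 1]")
    if isinstance(residuals, ResidualMatrix):
        gene_ids, data = residuals.gene_ids, residuals.residuals
    else:
        gene_ids, data = residuals.probe_ids, residuals.values
    missing = [g for g in gene_ids if g not in partition.module_of]
    if missing:
        raise NetworkError(f"genes without module assignment: {missing[:5]}")

    if correlation == "spearman":
        from scipy.stats import rankdata

        data = rankdata(data, axis=1)
    r = np.corrcoef(data)
    labels = partition.labels(gene_ids)

    g = nx.Graph()
    for gene, mod in zip(gene_ids, labels):
        g.add_node(gene, module=int(mod))
    n = len(gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    strong = np.abs(r[iu, ju]) >= threshold
    if within_module_only:
        strong &= labels[iu] == labels[ju]
    for i, j in zip(iu[strong], ju[strong]):
        rv = float(r[i, j])
        g.add_edge(gene_ids[i], gene_ids[j], r=rv, abs_r=abs(rv))
    return RelevanceNetwork(g, threshold, min_component_size)


def write_sif(net: RelevanceNetwork, path) -> None:
    """Three-column SIF (gene relation gene); relation encodes the
    correlation sign (``pos``/``neg``). Isolated nodes get a bare line."""
    with open(path, "w") as fh:
        isolated = set(net.graph.nodes)
        for a, b, r in net.edges():
            fh.write(f"{a}\t{'pos' if r >= 0 else 'neg'}\t{b}\n")
            isolated.discard(a)
            isolated.discard(b)
        for node in sorted(isolated):
            fh.write(f"{node}\n")


def write_graphml(net: RelevanceNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
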