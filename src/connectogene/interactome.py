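"""Closeness-centrality assessment of candidate genes in an interaction network.

Candidate genes from the spatial-similarity screen are located within a
composite gene-gene interaction network; genes sitting centrally (high
closeness) in the combined network corroborate the screen.  Distances are
hop counts by default — interaction weights are confidences, not metric
lengths — with an inverse-weight option.  Disconnected graphs use the
Wasserman-Faust component scaling, so closeness of a gene in a component of
size m within an n-node graph is ((m - 1) / sum of distances) * ((m - 1) / (n - 1)).
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["read_edge_list", "write_edge_list", "closeness"]

logger = logging.getLogger(__name__)


def read_edge_list(path) -> nx.Graph:
    """TSV of (gene_a, gene_b[, weight]); missing weight defaults to 1,
    duplicate edges keep the maximum weight, self-loops are skipped."""
    G = nx.Graph()
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        w = float(row[2]) if len(row) > 2 and pd.notna(row[2]) else 1.0
        if a == b:
            logger.info("skipping self-loop on %s", a)
            continue
        if w <= 0:
            raise ValueError(f"non-positive weight on edge {a}-{b}")
        if G.has_edge(a, b):
            G[a][b]["weight"] = max(G[a][b]["weight"], w)
        else:
            G.add_edge(a, b, weight=w)
    return G


def write_edge_list(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in G.edges(data=True):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0)}\n")


def closeness(network: nx.Graph, genes: Iterable | None = None, weighted: bool = False) -> pd.DataFrame:
    """Closeness centrality per gene; absent genes get NaN with a logged notice.

    Returns a DataFrame (gene, component_size, closeness) indexed by gene.
    """
    if weighted:
        H = network.copy()
        for _, _, d in H.edges(data=True):
            d["length"] = 1.0 / d.get("weight", 1.0)
        cc = nx.closeness_centrality(H, distance="length", wf_improved=True)
    else:
        cc = nx.closeness_centrality(network, wf_improved=True)
    comp_of = {}
    for comp in nx.connected_components(network):
        for g in comp:
            comp_of[g] = len(comp)
    genes = list(genes) if genes is not None else list(network.nodes())
    rows = []
    for g in genes:
        if g in cc:
            rows.append((g, comp_of[g], cc[g]))
        else:
            logger.info("gene %s absent from the interaction network", g)
            rows.append((g, 0, np.nan))
    return pd.DataFrame(rows, columns=["gene", "component_size", "closeness"]).set_index("gene")
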