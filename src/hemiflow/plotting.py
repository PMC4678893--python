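"""Small static plots of networks and degree tables."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402
import pandas as pd  # noqa: E402

from .network import SignificantNetwork  # noqa: E402


def plot_network(net: SignificantNetwork, path) -> None:
    """Directed network with bidirectional pairs drawn in red."""
    g = net.to_networkx()
    pos = nx.circular_layout(g)
    bidir = [(u, v) for u, v in g.edges if g.has_edge(v, u)]
    uni = [e for e in g.edges if e not in bidir]
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#ddddee", node_size=900)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    nx.draw_networkx_edges(g, pos, edgelist=uni, ax=ax, edge_color="#8b5a2b",
                           connectionstyle="arc3,rad=0.08")
    nx.draw_networkx_edges(g, pos, edgelist=bidir, ax=ax, edge_color="red",
                           connectionstyle="arc3,rad=0.08")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_degrees(degree_table: pd.DataFrame, path) -> None:
    """In-Out degree bar chart in the table's (sorted) node order."""
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.bar(degree_table["node"], degree_table["in_out"], color="#4878a8")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("In - Out degree")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
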