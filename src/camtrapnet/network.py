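"""Assembly and export of the species association network.

Nodes are the abundance-screened species, annotated with RAI, occupancy and
breadth.  Two edge layers are kept distinct:

* undirected signed edges — species pairs whose Yates chi-square reaches at
  least the p = 0.05 class, carrying φ, χ², the significance class and the
  association sign (negative significant edges are retained and flagged);
* directed edges — asymmetric predictability links (predictor → predicted)
  whose bootstrap lower prediction limit λ_BO exceeds zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["AssociationNetwork", "build_network", "export_network", "read_graphml"]


@dataclass
class AssociationNetwork:
    """Two-layer species association network (undirected signed + directed)."""

    undirected: nx.Graph = field(default_factory=nx.Graph)
    directed: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.undirected.nodes)

    def node_table(self) -> pd.DataFrame:
        rows = {n: dict(self.undirected.nodes[n]) for n in self.nodes}
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("species")

    def edge_table(self) -> pd.DataFrame:
        """Both layers as one long edge list (column ``layer`` distinguishes)."""
        rows = []
        for u, v, d in sorted(self.undirected.edges(data=True)):
            rows.append({"layer": "undirected", "source": u, "target": v, **d})
        for u, v, d in sorted(self.directed.edges(data=True)):
            rows.append({"layer": "directed", "source": u, "target": v, **d})
        cols = ["layer", "source", "target", "phi", "chi2_yates", "sign", "class", "L_B", "lambda_BO"]
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df.columns:
                df[c] = pd.NA
        return df[cols] if len(df) else pd.DataFrame(columns=cols)

    def focal_subgraph(self, focal: str) -> "AssociationNetwork":
        """Edges touching the focal species, with their endpoint nodes."""
        if focal not in self.undirected:
            raise KeyError(f"{focal!r} is not a network node")
        keep = {focal}
        keep |= set(self.undirected.neighbors(focal))
        keep |= {v for _, v in self.directed.out_edges(focal)}
        keep |= {u for u, _ in self.directed.in_edges(focal)}
        sub = AssociationNetwork()
        sub.undirected = self.undirected.subgraph(keep).copy()
        sub.undirected.remove_edges_from(
            [(u, v) for u, v in sub.undirected.edges if focal not in (u, v)]
        )
        sub.directed = self.directed.subgraph(keep).copy()
        sub.directed.remove_edges_from(
            [(u, v) for u, v in sub.directed.edges if focal not in (u, v)]
        )
        return sub


def build_network(
    abundance: pd.DataFrame,
    associations: pd.DataFrame,
    lambdas: pd.DataFrame | None = None,
    breadth: pd.DataFrame | None = None,
    include_nonsignificant: bool = False,
    occupancy: pd.Series | None = None,
) -> AssociationNetwork:
    """Assemble the association network from the upstream result tables.

    Parameters
    ----------
    abundance : output of :func:`camtrapnet.niche.rai_table`; rows with
        ``selected`` True become the node set.
    associations : output of
        :func:`camtrapnet.association.pairwise_association_table`.
    lambdas : optional output of :func:`camtrapnet.association.lambda_table`;
        rows with ``significant`` True become directed edges.
    include_nonsignificant : keep all tested pairs as undirected edges
        instead of only the significant classes.

    Species appearing in an edge table but absent from the node set raise a
    KeyError naming the offenders.
    """
    net = AssociationNetwork()
    selected = abundance[abundance["selected"]]
    for sp, row in selected.iterrows():
        attrs = {"rai": float(row["rai"]), "n_events": int(row["n_events"])}
        if occupancy is not None and sp in occupancy.index:
            attrs["occupancy"] = int(occupancy[sp])
        if breadth is not None and sp in breadth.index:
            attrs["B_L"] = float(breadth.loc[sp, "B_L"])
            attrs["B_S"] = float(breadth.loc[sp, "B_S"])
        net.undirected.add_node(sp, **attrs)
        net.directed.add_node(sp, **attrs)

    node_set = set(net.undirected.nodes)
    edge_species = set(associations["species_a"]) | set(associations["species_b"])
    if lambdas is not None and len(lambdas):
        edge_species |= set(lambdas["predictor"]) | set(lambdas["predicted"])
    strays = sorted(edge_species - node_set)
    if strays:
        raise KeyError(f"edge species not in the selected node set: {strays}")

    for d in associations.to_dict("records"):
        cls = d["class"]
        if cls == "undefined" or pd.isna(d["phi"]):
            continue
        if cls == "none" and not include_nonsignificant:
            continue
        net.undirected.add_edge(
            d["species_a"],
            d["species_b"],
            phi=float(d["phi"]),
            chi2_yates=float(d["chi2_yates"]),
            sign=str(d["sign"]),
            **{"class": str(cls)},
        )

    if lambdas is not None:
        for d in lambdas.to_dict("records"):
            if bool(d.get("significant")):
                net.directed.add_edge(
                    d["predictor"],
                    d["predicted"],
                    L_B=float(d["L_B"]),
                    lambda_BO=float(d["lambda_BO"]),
                )
    return net


def export_network(net: AssociationNetwork, out_dir: str | Path, graphml: bool = True) -> dict[str, Path]:
    """Write edge-list CSV, node-attribute CSV, and (optionally) GraphML files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "network_edges.csv",
        "nodes": out / "network_nodes.csv",
    }
    net.edge_table().to_csv(paths["edges"], index=False)
    net.node_table().to_csv(paths["nodes"])
    if graphml:
        paths["graphml_undirected"] = out / "network_undirected.graphml"
        paths["graphml_directed"] = out / "network_directed.graphml"
        nx.write_graphml(net.undirected, paths["graphml_undirected"])
        nx.write_graphml(net.directed, paths["graphml_directed"])
    return paths


def read_graphml(undirected_path: str | Path, directed_path: str | Path) -> AssociationNetwork:
    """Round-trip loader for networks written by :func:`export_network`."""
    net = AssociationNetwork()
    net.undirected = nx.read_graphml(undirected_path)
    net.directed = nx.read_graphml(directed_path)
    if not isinstance(net.directed, nx.DiGraph):
        net.directed = nx.DiGraph(net.directed)
    return net
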