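"""Graph and grouped-table views of mined rules.

Two representations mirror the usual ways rule sets are displayed:

* a bipartite rule network — gene nodes and one node per rule, with
  directed edges gene -> rule (antecedent membership) and rule -> gene
  (consequent membership).  Rules with multi-gene antecedents are
  represented losslessly without hyper-edges, and hub genes (shared
  consequents of many rules) stand out by in-degree.
* a grouped incidence table — antecedent itemsets clustered into at most
  ``n_groups`` groups (identical antecedents merged first, then greedy
  Jaccard-nearest merging), one row per (group, consequent item) cell
  with the rule count and the best measure value, ready for a
  balloon-style plot.
"""

from __future__ import annotations

import math
from typing import Sequence

import networkx as nx
import pandas as pd

from .arm import Rule

__all__ = [
    "rules_to_graph",
    "export_graph",
    "rules_to_grouped_table",
    "plot_rule_graph",
    "plot_grouped_table",
]

GRAPH_FORMATS = ("graphml", "dot")


def _rule_id(rule: Rule) -> str:
    return "{%s}=>{%s}" % (",".join(sorted(rule.lhs)), ",".join(sorted(rule.rhs)))


def rules_to_graph(rules: Sequence[Rule]) -> nx.DiGraph:
    """Build the bipartite gene/rule digraph for a rule list.

    Gene nodes carry ``kind='gene'`` (and ``layer`` when the ID ends in a
    ``.1``/``.2`` layer suffix); rule nodes carry ``kind='rule'`` and the
    rule's metrics rounded to 6 decimals.  Node insertion order is
    deterministic: genes sorted lexicographically, then rules in input
    order.
    """
    g = nx.DiGraph()
    genes = sorted({item for r in rules for item in r.items})
    for gene in genes:
        attrs = {"kind": "gene"}
        if gene.endswith(".1") or gene.endswith(".2"):
            attrs["layer"] = int(gene[-1])
        g.add_node(gene, **attrs)
    for r in rules:
        rid = _rule_id(r)
        attrs = {"kind": "rule"}
        for name in ("support", "confidence", "lift", "wcs", "lamda3"):
            v = getattr(r.metrics, name)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                attrs[name] = round(float(v), 6)
        g.add_node(rid, **attrs)
        for a in r.lhs:
            g.add_edge(a, rid)
        for c in r.rhs:
            g.add_edge(rid, c)
    return g


def export_graph(g: nx.DiGraph, path, format: str = "graphml") -> None:
    """Write the rule graph as GraphML or DOT."""
    if format not in GRAPH_FORMATS:
        raise ValueError(f"format must be one of {GRAPH_FORMATS}, got {format!r}")
    if format == "graphml":
        nx.write_graphml(g, path)
        return
    with open(path, "w") as fh:
        fh.write("digraph rules {\n")
        for node, attrs in g.nodes(data=True):
            shape = "box" if attrs.get("kind") == "rule" else "ellipse"
            fh.write(f'  "{node}" [shape={shape}];\n')
        for u, v in g.edges():
            fh.write(f'  "{u}" -> "{v}";\n')
        fh.write("}\n")


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def rules_to_grouped_table(
    rules: Sequence[Rule], n_groups: int, measure: str = "lift"
) -> pd.DataFrame:
    """Cluster antecedents and tabulate (group x consequent item) cells.

    Identical antecedent itemsets always share a group; if more distinct
    antecedents remain than ``n_groups``, the two groups with the highest
    Jaccard overlap of their pooled items are merged repeatedly (ties
    broken lexicographically).  Columns: ``lhs_group``, ``rhs``,
    ``n_rules``, ``max_<measure>``.
    """
    if n_groups < 1:
        raise ValueError(f"n_groups must be >= 1, got {n_groups}")
    groups: dict[frozenset, list[Rule]] = {}
    for r in rules:
        groups.setdefault(frozenset(r.lhs), []).append(r)

    # greedy merge to n_groups by pooled-item Jaccard similarity
    members: list[tuple[frozenset, list[Rule]]] = sorted(
        groups.items(), key=lambda kv: sorted(kv[0])
    )
    while len(members) > n_groups:
        best = None
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                sim = _jaccard(members[i][0], members[j][0])
                key = (-sim, sorted(members[i][0]), sorted(members[j][0]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        merged = (members[i][0] | members[j][0], members[i][1] + members[j][1])
        members = [m for k, m in enumerate(members) if k not in (i, j)]
        members.append(merged)
        members.sort(key=lambda kv: sorted(kv[0]))

    rows = []
    for items, rs in members:
        label = ",".join(sorted(items))
        cells: dict[str, list[Rule]] = {}
        for r in rs:
            for c in r.rhs:
                cells.setdefault(c, []).append(r)
        for rhs_item in sorted(cells):
            vals = [
                getattr(r.metrics, measure)
                for r in cells[rhs_item]
                if getattr(r.metrics, measure) is not None
            ]
            rows.append(
                {
                    "lhs_group": label,
                    "rhs": rhs_item,
                    "n_rules": len(cells[rhs_item]),
                    f"max_{measure}": max(vals) if vals else None,
                }
            )
    return pd.DataFrame(rows, columns=["lhs_group", "rhs", "n_rules", f"max_{measure}"])


def plot_rule_graph(g: nx.DiGraph, path) -> None:
    """Render the rule network to an image file (spring layout)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(g, seed=0)
    kinds = nx.get_node_attributes(g, "kind")
    gene_nodes = [n for n in g if kinds.get(n) == "gene"]
    rule_nodes = [n for n in g if kinds.get(n) == "rule"]
    fig, ax = plt.subplots(figsize=(8, 6))
    nx.draw_networkx_nodes(g, pos, nodelist=gene_nodes, node_color="#4c72b0", ax=ax)
    nx.draw_networkx_nodes(
        g, pos, nodelist=rule_nodes, node_color="#dd8452", node_shape="s", ax=ax
    )
    nx.draw_networkx_edges(g, pos, ax=ax, arrows=True)
    nx.draw_networkx_labels(g, pos, {n: n for n in gene_nodes}, font_size=8, ax=ax)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_grouped_table(table: pd.DataFrame, path) -> None:
    """Render the grouped incidence table as a balloon plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(dict.fromkeys(table["lhs_group"]))
    rhs = list(dict.fromkeys(table["rhs"]))
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(rhs), 1 + 0.5 * len(groups)))
    measure_col = table.columns[-1]
    for _, row in table.iterrows():
        x = rhs.index(row["rhs"])
        y = groups.index(row["lhs_group"])
        size = 80 * row["n_rules"]
        ax.scatter(x, y, s=size, c="#4c72b0", alpha=0.7)
    ax.set_xticks(range(len(rhs)), rhs, rotation=90, fontsize=8)
    ax.set_yticks(range(len(groups)), groups, fontsize=8)
    ax.set_xlabel("consequent (RHS)")
    ax.set_ylabel("antecedent group (LHS)")
    ax.set_title(measure_col)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
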