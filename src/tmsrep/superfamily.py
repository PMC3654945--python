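"""Transitive homology networks over transporter families.

The superfamily principle: homology is transitive, so if membrane protein A
is homologous to B and B to C, then A and C are homologous even when no
direct A-C similarity is detectable.  Families are nodes, demonstrated
binary comparisons are evidence edges (comparison score in S.D.), and
superfamilies are the connected components of the resulting graph.

The bundled evidence table transcribes the published family-vs-family
comparison-score matrix for the ABC uptake porter superfamily (TC 3.A.1):
33 of the families numbered 1-34 appear (family 21, which belongs with the
ABC1 exporters, appears in no cell).  Cells carry either an explicit "SD"
suffix or a bare number; both are retained and distinguished, since the
meaning of the bare-number cells is not documented.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "EvidenceEdge",
    "build_network",
    "components",
    "export_network",
    "import_network",
    "table1_fixture",
    "transitivity_paths",
]


@dataclass
class EvidenceEdge:
    """One demonstrated pairwise comparison between family labels."""

    node_a: str
    node_b: str
    z: float
    span: int | None = None
    source_pair: tuple[str, str] | None = None
    passes: bool = True
    sd_suffix: bool = True  # False when the table cell had no "SD" suffix


def build_network(edges: list[EvidenceEdge]) -> nx.Graph:
    """Undirected evidence graph; parallel evidence collapsed keeping max z.

    All evidence records are retained in the edge's ``evidence`` attribute.
    Self edges (same family on both sides) are dropped with a warning
    attribute on the graph.
    """
    g = nx.Graph()
    dropped = []
    for e in edges:
        if not e.node_a or not e.node_b:
            raise ValueError("edge labels must be non-empty")
        if e.node_a == e.node_b:
            dropped.append(e)
            continue
        g.add_node(e.node_a)
        g.add_node(e.node_b)
        if g.has_edge(e.node_a, e.node_b):
            data = g[e.node_a][e.node_b]
            data["evidence"].append(e)
            if e.z > data["z"]:
                data["z"] = e.z
                data["sd_suffix"] = e.sd_suffix
        else:
            g.add_edge(e.node_a, e.node_b, z=e.z, sd_suffix=e.sd_suffix, evidence=[e])
    g.graph["dropped_self_edges"] = len(dropped)
    return g


def components(network: nx.Graph, z_min: float = 0.0) -> list[set[str]]:
    """Connected components of the subgraph with edge z >= z_min.

    ``z_min = 0`` keeps every piece of evidence; ``z_min = 10`` restricts to
    cells meeting the homology threshold.  Nodes are always retained, so
    raising ``z_min`` can only split components, never merge them.
    """
    sub = nx.Graph()
    sub.add_nodes_from(network.nodes)
    sub.add_edges_from(
        (u, v) for u, v, d in network.edges(data=True) if d.get("z", 0.0) >= z_min
    )
    comps = [set(c) for c in nx.connected_components(sub)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))


def transitivity_paths(network: nx.Graph, z_min: float = 0.0) -> dict:
    """For every node pair in a component, an explicit evidence path.

    Returns {(a, b): [n0, n1, ...]} — the audit trail that justifies calling
    a and b homologous by transitivity.
    """
    sub = nx.Graph()
    sub.add_nodes_from(network.nodes)
    sub.add_edges_from((u, v) for u, v, d in network.edges(data=True) if d.get("z", 0.0) >= z_min)
    paths = {}
    for comp in nx.connected_components(sub):
        nodes = sorted(comp)
        for i, a in enumerate(nodes):
            sp = nx.single_source_shortest_path(sub, a)
            for b in nodes[i + 1 :]:
                paths[(a, b)] = sp[b]
    return paths


def export_network(network: nx.Graph, fmt: str = "tsv-edgelist") -> str:
    """Serialize the network as text; round-trip safe via import_network."""
    if fmt == "tsv-edgelist":
        lines = ["node_a\tnode_b\tz\tsd_suffix"]
        for u, v, d in sorted(network.edges(data=True)):
            lines.append(f"{u}\t{v}\t{d['z']}\t{int(d.get('sd_suffix', True))}")
        return "\n".join(lines) + "\n"
    if fmt == "sif":
        return "".join(
            f"{u} hom {v}\n" for u, v in sorted(network.edges)
        )
    if fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(network.nodes)
        for u, v, d in network.edges(data=True):
            g.add_edge(u, v, z=float(d["z"]), sd_suffix=bool(d.get("sd_suffix", True)))
        buf = io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()
    raise ValueError(f"unknown format {fmt!r}; choose tsv-edgelist, sif or graphml")


def import_network(text: str, fmt: str = "tsv-edgelist") -> nx.Graph:
    if fmt == "tsv-edgelist":
        g = nx.Graph()
        lines = text.strip().splitlines()
        for line in lines[1:]:
            u, v, z, sd = line.split("\t")
            g.add_edge(u, v, z=float(z), sd_suffix=bool(int(sd)))
        return g
    if fmt == "sif":
        g = nx.Graph()
        for line in text.strip().splitlines():
            u, _, v = line.split()
            g.add_edge(u, v)
        return g
    if fmt == "graphml":
        return nx.parse_graphml(text)
    raise ValueError(f"unknown format {fmt!r}")


# Family-vs-family comparison-score matrix for the ABC uptake porters
# (TC 3.A.1), transcribed cell by cell.  Row/column labels are
# subfamily+protein tags; the leading number is the family within 3.A.1.
# Values are comparison scores; "SD" marks cells whose table entry carried
# the explicit S.D. suffix.
_TABLE1 = """\
row	col	value	sd
1.6 CymF	20.1 BitE	12	0
2.5 GguB	14.16 FeuC	13	1
2.10 PnrE	3.2 GlnP	16	1
3.2 GlnP	12.3 OPBD	15	1
3.19 GtsC	1.1 MalG	16	0
4.4 UrtB	2.4 XylH	14	1
5.2 DppC	12.3 OPBD	13.5	1
6.3 CysW	20.1 BitE	14	0
6.5 WtpB	3.2 GlnP	8	0
7.1 PstA	12.3 OPBD	12	1
8.1 ModB	1.1 MalG	10	0
9.2 PhnE	12.8 OpuBB	12	0
10.3 FbpB	20.1 BitE	21	0
11.4 ChtK	1.1 MalG	8	0
13.1 BtuC	14.3 FhuB	30	0
15.4 YfeC	14.3 FhuB	18	1
16.3 CmpB	12.3 OPBD	10	0
17.2 SsuC	12.3 OPBD	9	0
18.1 CbiQ	23.2 CbiQ	15	1
19.1 ThiP	20.1 BitE	17	1
22.1 CbiQ	26.1 CbiQ	13	1
24.1 MetI	12.3 OPBD	9	0
25.1 BioY gi145224049	3.2 GlnP	11	1
25.1 BioY gi145224049	3.8 AapM	11	1
26.7 EcfT	25.1 BioN	8	0
27.2 Tgd1 gi54023080	4.1 LivM	11	1
28.1 QrtT	26.1 CbiQ	13	0
29.1 MtsU	23.2 CbiQ	6	0
30.1 YkoC	26.1 CbiQ	7	0
30.1 YkoC	28.1 QrtT	17	1
31.1 HtsTUV	26.1 CbiQ	14	1
32.1 CbrT	29.1 MtsU	18.9	1
33.1 MtaT	28.1 QrtT	6	0
33.1 MtaT	29.1 MtsU	13	0
34.1 TrpY	2.1 RbsC	12	0
"""


def _family(label: str) -> str:
    return "3.A.1." + label.split()[0].split(".")[0]


def table1_fixture(family_level: bool = True) -> list[EvidenceEdge]:
    """The transcribed evidence table as a list of edges.

    With ``family_level=True`` (default) node labels are TC family prefixes
    ("3.A.1.15"); otherwise the full row/column system tags are kept.
    """
    edges = []
    for line in _TABLE1.strip().splitlines()[1:]:
        row, col, value, sd = line.split("\t")
        z = float(value)
        a, b = (_family(row), _family(col)) if family_level else (row, col)
        edges.append(
            EvidenceEdge(a, b, z, source_pair=(row, col), passes=z >= 10, sd_suffix=bool(int(sd)))
        )
    return edges
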