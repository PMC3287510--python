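"""Single-locus-variant (SLV) graph and clonal-complex inference.

Two STs are single-locus variants when their allelic profiles differ at
exactly one locus (Hamming distance 1 on the allele tuples). Clonal
complexes are the connected components of the SLV graph with at least two
STs — the stringent eBURST grouping in which every member shares L−1 of L
alleles with at least one other member. The putative founder of a complex
is the member with the most SLV links inside the complex, with ties broken
by isolate frequency and then lowest ST id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .mlst import STProfile


def _roman(n: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass
class ClonalComplex:
    """An SLV-connected group of ≥2 STs with a putative founder."""

    complex_id: str
    member_st_ids: list[int]
    founder_st_id: int
    isolate_total: int
    founder_designated: bool = False
    founder_trace: list[str] = field(default_factory=list)


def build_slv_graph(sts: list[STProfile]) -> nx.Graph:
    """Graph over ST ids with an edge for every single-locus-variant pair."""
    if not sts:
        raise ValueError("no STs given")
    lengths = {len(st.alleles) for st in sts}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent profile lengths: {sorted(lengths)}")
    graph = nx.Graph()
    for st in sts:
        graph.add_node(st.st_id, frequency=st.frequency, alleles=st.alleles)
    for a, b in combinations(sts, 2):
        hamming = sum(x != y for x, y in zip(a.alleles, b.alleles))
        if hamming == 1:
            graph.add_edge(a.st_id, b.st_id)
    return graph


def predict_founder(
    members: list[int], graph: nx.Graph
) -> tuple[int, list[str]]:
    """Pick the founder of a complex: max within-complex SLV degree,
    ties by isolate frequency, then lowest ST id. Returns (founder, trace).
    """
    sub = graph.subgraph(members)
    ranked = sorted(
        members,
        key=lambda st: (-sub.degree(st), -graph.nodes[st]["frequency"], st),
    )
    founder = ranked[0]
    trace = [
        f"ST{st}: slv_degree={sub.degree(st)} "
        f"frequency={graph.nodes[st]['frequency']}"
        for st in ranked
    ]
    trace.append(f"founder=ST{founder} (degree, then frequency, then lowest id)")
    return founder, trace


def find_clonal_complexes(
    graph: nx.Graph,
    designated_founders: dict[frozenset[int], int] | None = None,
) -> tuple[list[ClonalComplex], list[int]]:
    """Connected components with ≥2 STs become clonal complexes.

    Complexes are labelled with Roman numerals in decreasing order of
    isolate total (ties: more STs, then lowest member ST id). Isolated
    nodes — STs sharing no L−1 profile with anyone — are returned as
    singletons. ``designated_founders`` (keyed by frozen member set) may
    pin a known founder, e.g. from a reference table; otherwise the
    founder is predicted from SLV degree and frequency.
    """
    components = [set(c) for c in nx.connected_components(graph)]
    singletons = sorted(st for comp in components for st in comp if len(comp) == 1)
    multi = [comp for comp in components if len(comp) >= 2]

    def isolate_total(comp: set[int]) -> int:
        return sum(graph.nodes[st]["frequency"] for st in comp)

    multi.sort(key=lambda c: (-isolate_total(c), -len(c), min(c)))
    complexes: list[ClonalComplex] = []
    for rank, comp in enumerate(multi, start=1):
        members = sorted(comp)
        designated = None
        if designated_founders:
            designated = designated_founders.get(frozenset(members))
        if designated is not None:
            founder, trace = designated, [f"founder=ST{designated} (designated)"]
        else:
            founder, trace = predict_founder(members, graph)
        complexes.append(
            ClonalComplex(
                complex_id=_roman(rank),
                member_st_ids=members,
                founder_st_id=founder,
                isolate_total=isolate_total(comp),
                founder_designated=designated is not None,
                founder_trace=trace,
            )
        )
    return complexes, singletons


def write_complexes_tsv(complexes: list[ClonalComplex], path) -> None:
    with open(path, "w") as fh:
        fh.write("complex_id\tfounder_st\tmember_sts\tn_sts\tisolate_total\n")
        for c in complexes:
            members = ",".join(str(m) for m in c.member_st_ids)
            fh.write(
                f"{c.complex_id}\t{c.founder_st_id}\t{members}\t"
                f"{len(c.member_st_ids)}\t{c.isolate_total}\n"
            )


def write_edge_list(graph: nx.Graph, path) -> None:
    """Edge list suitable for external graph drawing."""
    with open(path, "w") as fh:
        fh.write("st_a\tst_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")
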