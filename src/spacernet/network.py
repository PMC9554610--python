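"""Greedy covering-set selection and host--MGE interaction networks.

The MGE database is highly redundant, so building a network from every MGE
with a matching protospacer would be needlessly complex. Instead a greedy
set-cover heuristic selects a small set of MGEs that collectively explain
every matched spacer cluster: repeatedly pick the candidate covering the most
not-yet-covered clusters. The same rule selects a minimal host set. The
selected nodes define two bipartite networks -- spacer--MGE and host--MGE --
whose connected components ("modules") group co-interacting hosts, spacers
and invaders.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .records import MGERecord, SpacerCluster, SpacerHit

UNTYPED = "untyped"


@dataclass
class CoverInstance:
    """A set-cover instance: elements to explain and candidate covers."""

    universe: set[str]
    candidates: dict[str, set[str]]

    def validate(self) -> None:
        covered = set()
        for cid, elems in self.candidates.items():
            extra = elems - self.universe
            if extra:
                raise ValueError(
                    f"candidate {cid!r} covers elements outside the "
                    f"universe: {sorted(extra)[:5]}"
                )
            covered |= elems
        missing = self.universe - covered
        if missing:
            raise ValueError(
                "universe not coverable; uncovered elements: "
                + ", ".join(sorted(missing))
            )


def greedy_cover(instance: CoverInstance) -> list[str]:
    """Greedy set cover: pick the candidate covering the most uncovered
    elements, ties broken by lexicographically smallest id; repeat until the
    universe is covered. Returns candidates in selection order."""
    instance.validate()
    remaining = set(instance.universe)
    selected: list[str] = []
    while remaining:
        best_id = None
        best_gain = 0
        for cid in sorted(instance.candidates):
            gain = len(instance.candidates[cid] & remaining)
            if gain > best_gain:
                best_gain = gain
                best_id = cid
        assert best_id is not None  # validate() guarantees coverability
        selected.append(best_id)
        remaining -= instance.candidates[best_id]
    return selected


def select_mges(hits: list[SpacerHit]) -> list[str]:
    """Minimal MGE set (greedy) explaining every matched spacer cluster."""
    if not hits:
        return []
    candidates: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        candidates[h.mge_id].add(h.cluster_id)
    universe = set().union(*candidates.values())
    return greedy_cover(CoverInstance(universe, dict(candidates)))


def select_hosts(
    hits: list[SpacerHit], cluster_hosts: dict[str, set[str]]
) -> list[str]:
    """Minimal host set (greedy) contributing every matched spacer cluster.

    ``cluster_hosts`` maps each cluster id to the hosts carrying a member
    spacer (see :func:`spacernet.crispr.cluster_hosts_map`).
    """
    matched = {h.cluster_id for h in hits}
    if not matched:
        return []
    candidates: dict[str, set[str]] = defaultdict(set)
    for cid in matched:
        for host in cluster_hosts.get(cid, ()):
            candidates[host].add(cid)
    return greedy_cover(CoverInstance(matched, dict(candidates)))


def _type_label(types: set[str]) -> str:
    return ",".join(sorted(types)) if types else UNTYPED


def build_spacer_mge_network(
    hits: list[SpacerHit],
    selected_mges: list[str],
    clusters: list[SpacerCluster],
    mge_meta: dict[str, MGERecord] | None = None,
) -> nx.Graph:
    """Bipartite spacer-cluster vs MGE network.

    An edge joins a spacer cluster to a selected MGE containing >=1 matching
    protospacer; ``n_matches`` counts the passing hits (loci) for the pair.
    """
    selected = set(selected_mges)
    types = {c.cluster_id: c.crispr_types for c in clusters}
    pair_hits: Counter = Counter()
    for h in hits:
        if h.mge_id in selected:
            pair_hits[(h.cluster_id, h.mge_id)] += 1

    G = nx.Graph()
    for (cid, mid), n in sorted(pair_hits.items()):
        if cid not in G:
            G.add_node(
                cid,
                kind="spacer",
                crispr_type=_type_label(types.get(cid, set())),
            )
        if mid not in G:
            G.add_node(mid, kind="mge", **_mge_attrs(mid, mge_meta))
        G.add_edge(cid, mid, n_matches=n)
    return G


def build_host_mge_network(
    hits: list[SpacerHit],
    selected_hosts: list[str],
    selected_mges: list[str],
    cluster_hosts: dict[str, set[str]],
    mge_meta: dict[str, MGERecord] | None = None,
    host_taxa: dict[str, str] | None = None,
) -> nx.Graph:
    """Bipartite host vs MGE network.

    An edge joins a selected host to a selected MGE when some spacer cluster
    carried by the host has a passing hit to the MGE; ``n_matches`` counts
    distinct (cluster, locus) matched pairs for the host/MGE pair.
    """
    sel_h, sel_m = set(selected_hosts), set(selected_mges)
    pair_matches: dict[tuple[str, str], set] = defaultdict(set)
    for h in hits:
        if h.mge_id not in sel_m:
            continue
        locus = (h.cluster_id, h.s_start, h.s_end, h.strand)
        for host in cluster_hosts.get(h.cluster_id, ()):
            if host in sel_h:
                pair_matches[(host, h.mge_id)].add(locus)

    G = nx.Graph()
    for (host, mid), loci in sorted(pair_matches.items()):
        if host not in G:
            G.add_node(
                host, kind="host", taxon=(host_taxa or {}).get(host, "")
            )
        if mid not in G:
            G.add_node(mid, kind="mge", **_mge_attrs(mid, mge_meta))
        G.add_edge(host, mid, n_matches=len(loci))
    return G


def _mge_attrs(mge_id: str, mge_meta: dict[str, MGERecord] | None) -> dict:
    rec = (mge_meta or {}).get(mge_id)
    if rec is None:
        return {"mge_class": "phage", "source_db": ""}
    attrs = {"mge_class": rec.mge_class, "source_db": rec.source_db}
    if rec.known_host:
        attrs["known_host"] = rec.known_host
    return attrs


@dataclass
class Component:
    """One connected component (module) of an interaction network."""

    component_id: str
    nodes: list[str]
    counts_by_kind: dict[str, int] = field(default_factory=dict)
    counts_by_mge_class: dict[str, int] = field(default_factory=dict)
    counts_by_crispr_type: dict[str, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def connected_components(G: nx.Graph) -> list[Component]:
    """Components ordered by decreasing size, ties by smallest node id."""
    comps = sorted(
        (sorted(c) for c in nx.connected_components(G)),
        key=lambda nodes: (-len(nodes), nodes[0]),
    )
    out = []
    for i, nodes in enumerate(comps):
        kinds: Counter = Counter()
        classes: Counter = Counter()
        ctypes: Counter = Counter()
        for n in nodes:
            data = G.nodes[n]
            kind = data.get("kind", "")
            kinds[kind] += 1
            if kind == "mge":
                classes[data.get("mge_class", "phage")] += 1
            elif kind == "spacer":
                ctypes[data.get("crispr_type") or UNTYPED] += 1
        out.append(
            Component(
                component_id=f"C{i + 1}",
                nodes=nodes,
                counts_by_kind=dict(kinds),
                counts_by_mge_class=dict(classes),
                counts_by_crispr_type=dict(ctypes),
            )
        )
    return out


def module_type_report(component: Component, G: nx.Graph) -> dict:
    """Counts of spacers per CRISPR type, phages, plasmids and hosts within
    one module -- e.g. to compare the involvement of different CRISPR-Cas
    systems against the phages of the module."""
    report = {
        "component_id": component.component_id,
        "n_nodes": component.n_nodes,
        "spacers_by_type": dict(component.counts_by_crispr_type),
        "n_phages": component.counts_by_mge_class.get("phage", 0),
        "n_plasmids": component.counts_by_mge_class.get("plasmid", 0),
        "n_hosts": component.counts_by_kind.get("host", 0),
    }
    return report


def validate_network(G: nx.Graph) -> None:
    """Check bipartiteness (spacer/host vs mge), no self loops, degree >= 1."""
    for u, v in G.edges:
        ku, kv = G.nodes[u].get("kind"), G.nodes[v].get("kind")
        if u == v:
            raise ValueError(f"self loop at {u!r}")
        if {ku, kv} & {"mge"} != {"mge"} or ku == kv:
            raise ValueError(f"edge ({u!r},{v!r}) is not spacer/host vs mge")
    for n in G.nodes:
        if G.degree[n] < 1:
            raise ValueError(f"isolated node {n!r}")


def write_network(G: nx.Graph, path: str, format: str = "gml") -> None:
    """Write the network as GML (default) or node/edge TSV tables.

    GML round-trips losslessly through :func:`read_network`; the TSV tables
    import directly into Cytoscape.
    """
    if format == "gml":
        nx.write_gml(G, path)
    elif format == "tsv":
        write_network_tables(G, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str) -> nx.Graph:
    G = nx.read_gml(path, label="label")
    for _, _, data in G.edges(data=True):
        if "n_matches" in data:
            data["n_matches"] = int(data["n_matches"])
    return G


def write_network_tables(G: nx.Graph, prefix: str) -> None:
    """Write ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv``."""
    attr_keys = sorted({k for _, d in G.nodes(data=True) for k in d})
    with open(f"{prefix}.nodes.tsv", "w") as fh:
        fh.write("\t".join(["id"] + attr_keys) + "\n")
        for n in sorted(G.nodes):
            d = G.nodes[n]
            fh.write(
                "\t".join([str(n)] + [str(d.get(k, "")) for k in attr_keys])
                + "\n"
            )
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("source\ttarget\tn_matches\n")
        for u, v in sorted(tuple(sorted((u, v))) for u, v in G.edges):
            fh.write(f"{u}\t{v}\t{G.edges[u, v].get('n_matches', 1)}\n")


def write_components_tsv(
    components: list[Component], path: str
) -> None:
    """Per-module summary table (nodes, hosts, MGEs by class, spacer types)."""
    all_types = sorted(
        {t for c in components for t in c.counts_by_crispr_type}
    )
    header = [
        "component_id",
        "n_nodes",
        "n_hosts",
        "n_spacers",
        "n_mges",
        "n_phages",
        "n_plasmids",
    ] + [f"spacers_{t}" for t in all_types]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for c in components:
            row = [
                c.component_id,
                c.n_nodes,
                c.counts_by_kind.get("host", 0),
                c.counts_by_kind.get("spacer", 0),
                c.counts_by_kind.get("mge", 0),
                c.counts_by_mge_class.get("phage", 0),
                c.counts_by_mge_class.get("plasmid", 0),
            ] + [c.counts_by_crispr_type.get(t, 0) for t in all_types]
            fh.write("\t".join(str(x) for x in row) + "\n")
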