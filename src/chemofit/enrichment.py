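"""Gene-set enrichment on sensitive-gene sets, with pruning and maps.

Hypergeometric over-representation of each gene-set term in a screen's
sensitive genes (FD >= threshold), BH-adjusted; GO-Elite-style redundancy
reduction: within a DAG lineage only the most significant term survives,
then terms are single-linkage clustered on the Jaccard similarity of their
driver gene sets (query ∩ term) and only the most significant term of each
cluster survives.  Retained terms become an enrichment map whose node size
is -log10(FDR) and whose edges carry the overlap coefficient
|A∩B|/min(|A|,|B|) between term gene sets (edges below 0.5 are dropped).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "EnrichmentMap",
    "load_gene_sets",
    "hypergeom_pvalue",
    "bh_adjust",
    "enrich_screen",
    "prune_lineage",
    "prune_clusters",
    "build_enrichment_map",
]

logger = logging.getLogger(__name__)

FDR_FLOOR = 1e-300  # before -log10 in map export
SIZE_MIN_DEFAULT = 5
SIZE_MAX_DEFAULT = 300


@dataclass(frozen=True)
class GeneSetCollection:
    """Term -> member genes, with the annotated-gene universe."""

    sets: Mapping[str, frozenset]
    names: Mapping[str, str]
    universe: frozenset

    def filter_sizes(self, size_min: int = SIZE_MIN_DEFAULT, size_max: int = SIZE_MAX_DEFAULT) -> "GeneSetCollection":
        """Drop terms that are too specific (< size_min genes) or too general
        (> size_max genes)."""
        kept = {
            t: g for t, g in self.sets.items() if size_min <= len(g) <= size_max
        }
        return GeneSetCollection(
            sets=kept,
            names={t: self.names.get(t, t) for t in kept},
            universe=self.universe,
        )

    def __len__(self) -> int:
        return len(self.sets)

    def to_gmt(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for term in sorted(self.sets):
                genes = "\t".join(sorted(self.sets[term]))
                fh.write(f"{term}\t{self.names.get(term, term)}\t{genes}\n")
        return path


@dataclass
class EnrichmentRow:
    """One term's enrichment in one query: k of K term genes among the n
    query genes drawn from a universe of N."""

    term_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    fdr: float = 1.0
    drivers: frozenset = field(default_factory=frozenset)
    status: str = "not_significant"  # retained|pruned_lineage|pruned_cluster|not_significant
    cluster_id: int = -1


@dataclass
class EnrichmentMap:
    """Nodes (retained terms) and overlap-coefficient edges for drawing."""

    nodes: list[dict]
    edges: list[dict]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"nodes": self.nodes, "edges": self.edges}, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_graphml(self, path: str | Path) -> Path:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node["term_id"], **{k: v for k, v in node.items() if k != "term_id"})
        for edge in self.edges:
            g.add_edge(
                edge["term_a"],
                edge["term_b"],
                overlap_coefficient=edge["overlap_coefficient"],
                overlap_count=edge["overlap_count"],
            )
        nx.write_graphml(g, path)
        return Path(path)


# ---------------------------------------------------------------------------
# Loading annotations
# ---------------------------------------------------------------------------

_ASPECTS = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}


def _read_gaf(path: str | Path, aspect: str) -> dict[str, set[str]]:
    """GAF 2.x: direct gene annotations per term (NOT-qualified rows skipped)."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GAF line in {path}: {line[:60]!r}")
            symbol, qualifier, go_id, asp = cols[2], cols[3], cols[4], cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            if aspect and asp != aspect:
                continue
            direct.setdefault(go_id, set()).add(symbol)
    return direct


def _read_obo(path: str | Path) -> tuple[nx.DiGraph, dict[str, str]]:
    """OBO -> child->parent DiGraph over is_a and part_of, plus term names."""
    import obonet

    multi = obonet.read_obo(path)
    dag = nx.DiGraph()
    names: dict[str, str] = {}
    for node, data in multi.nodes(data=True):
        dag.add_node(node)
        names[node] = data.get("name", node)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent, relation=key)
    for node, data in multi.nodes(data=True):
        for rel in data.get("relationship", []):
            parts = rel.split()
            if len(parts) == 2 and parts[0] == "part_of":
                dag.add_edge(node, parts[1], relation="part_of")
    return dag, names


def _check_acyclic(dag: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")


def propagate_annotations(direct: Mapping[str, set], dag: nx.DiGraph) -> dict[str, frozenset]:
    """True-path rule: each term inherits the genes of all its descendants."""
    members: dict[str, set] = {t: set(g) for t, g in direct.items()}
    for term in dag.nodes:
        members.setdefault(term, set())
    # edges run child -> parent, so accumulate in topological order
    for term in nx.topological_sort(dag):
        for parent in dag.successors(term):
            members.setdefault(parent, set()).update(members.get(term, set()))
    return {t: frozenset(g) for t, g in members.items()}


def load_gene_sets(
    annotation_file: str | Path,
    ontology_file: str | Path | None = None,
    size_min: int = SIZE_MIN_DEFAULT,
    size_max: int = SIZE_MAX_DEFAULT,
    aspect: str = "P",
) -> tuple[GeneSetCollection, nx.DiGraph]:
    """Load gene sets from GAF + OBO, or from GMT (empty DAG).

    Membership is propagated up the DAG before size filtering; terms outside
    [size_min, size_max] are dropped from the collection, but the returned
    DAG is the full ontology so lineage pruning can still see pruned-away
    intermediate terms.
    """
    annotation_file = Path(annotation_file)
    if ontology_file is None:
        sets, names = _read_gmt(annotation_file)
        universe = frozenset().union(*sets.values()) if sets else frozenset()
        collection = GeneSetCollection(sets=sets, names=names, universe=universe)
        return collection.filter_sizes(size_min, size_max), nx.DiGraph()
    dag, names = _read_obo(ontology_file)
    _check_acyclic(dag)
    direct = _read_gaf(annotation_file, aspect=aspect)
    members = propagate_annotations(direct, dag)
    universe = frozenset().union(*members.values()) if members else frozenset()
    collection = GeneSetCollection(
        sets={t: g for t, g in members.items() if g},
        names=names,
        universe=universe,
    )
    return collection.filter_sizes(size_min, size_max), dag


def _read_gmt(path: Path) -> tuple[dict[str, frozenset], dict[str, str]]:
    sets: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[cols[0]] = frozenset(g for g in cols[2:] if g)
            names[cols[0]] = cols[1]
    return sets, names


# ---------------------------------------------------------------------------
# Test statistics
# ---------------------------------------------------------------------------

def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if (pvals <= 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Enrichment per screen
# ---------------------------------------------------------------------------

def enrich_query(
    query: Iterable[str],
    assayed: Iterable[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.1,
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of ``query`` against every term.

    The universe is the assayed genes intersected with the collection's
    annotated universe; term sizes K are taken within that universe.
    Significance is strict: fdr < fdr_threshold.
    """
    universe = frozenset(assayed) & collection.universe
    query_set = frozenset(query) & universe
    N = len(universe)
    n = len(query_set)
    rows: list[EnrichmentRow] = []
    for term in sorted(collection.sets):  # canonical order
        members = collection.sets[term] & universe
        K = len(members)
        if K == 0:
            continue
        drivers = query_set & members
        k = len(drivers)
        p = hypergeom_pvalue(k, K, n, N)
        rows.append(
            EnrichmentRow(
                term_id=term,
                name=collection.names.get(term, term),
                k=k,
                K=K,
                n=n,
                N=N,
                p=p,
                drivers=drivers,
            )
        )
    if rows:
        fdrs = bh_adjust([r.p for r in rows])
        for row, fdr in zip(rows, fdrs):
            row.fdr = float(fdr)
            row.status = "retained" if row.fdr < fdr_threshold else "not_significant"
    return rows


def enrich_screen(
    fitness,
    screen_id: str,
    collection: GeneSetCollection,
    fd_threshold: float = 1.0,
    fdr_threshold: float = 0.1,
) -> list[EnrichmentRow]:
    """Enrichment of a screen's sensitive genes (fd >= fd_threshold)."""
    sub = fitness.screen(screen_id)
    query = set(sub.loc[sub["fd"] >= fd_threshold, "gene"])
    assayed = set(sub["gene"])
    if not query:
        logger.info("screen %s: empty sensitive-gene query", screen_id)
        return []
    return enrich_query(query, assayed, collection, fdr_threshold=fdr_threshold)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def _priority(row: EnrichmentRow) -> tuple:
    # most significant first; ties -> smaller term, then lexicographic id
    return (row.p, row.K, row.term_id)


def prune_lineage(rows: Sequence[EnrichmentRow], dag: nx.DiGraph) -> list[EnrichmentRow]:
    """Keep only the most significant term of each DAG lineage.

    Among significant rows, any ancestor/descendant pair keeps the smaller-p
    member; the survivors form an antichain under the lineage relation.
    Lineage spans is_a and part_of over any number of hops, evaluated on the
    full DAG (pruned-away intermediate terms still connect lineages).
    """
    rows = [replace(r) for r in rows]
    significant = [r for r in rows if r.status == "retained"]
    reach: dict[str, set] = {}
    for r in significant:
        if dag.has_node(r.term_id):
            # successors-direction = ancestors (edges run child -> parent)
            reach[r.term_id] = nx.descendants(dag, r.term_id)
        else:
            reach[r.term_id] = set()
    kept: list[EnrichmentRow] = []
    for row in sorted(significant, key=_priority):
        related = any(
            k.term_id in reach[row.term_id] or row.term_id in reach[k.term_id]
            for k in kept
        )
        if related:
            row.status = "pruned_lineage"
        else:
            kept.append(row)
    by_id = {r.term_id: r for r in significant}
    return [by_id.get(r.term_id, r) for r in rows]


def prune_clusters(
    rows: Sequence[EnrichmentRow], jaccard_merge: float = 0.5
) -> list[EnrichmentRow]:
    """Single-linkage clustering of surviving terms on driver-set Jaccard.

    Clusters merge at J >= jaccard_merge; within each cluster only the most
    significant term stays retained, the rest become pruned_cluster.  All
    clustered rows receive a cluster_id.
    """
    rows = [replace(r) for r in rows]
    alive = [r for r in rows if r.status == "retained"]
    order = sorted(range(len(alive)), key=lambda i: _priority(alive[i]))
    parent = list(range(len(alive)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(len(alive)):
        for b in range(a + 1, len(alive)):
            da, db = alive[a].drivers, alive[b].drivers
            union = len(da | db)
            j = len(da & db) / union if union else 0.0
            if j >= jaccard_merge:
                parent[find(a)] = find(b)
    cluster_of: dict[int, int] = {}
    next_id = 0
    for i in order:  # cluster ids in significance order
        root = find(i)
        if root not in cluster_of:
            cluster_of[root] = next_id
            next_id += 1
    winners: dict[int, int] = {}
    for i in order:
        cid = cluster_of[find(i)]
        alive[i].cluster_id = cid
        if cid not in winners:
            winners[cid] = i  # most significant in the cluster
        else:
            alive[i].status = "pruned_cluster"
    by_id = {r.term_id: r for r in alive}
    return [by_id.get(r.term_id, r) for r in rows]


def prune(rows: Sequence[EnrichmentRow], dag: nx.DiGraph, jaccard_merge: float = 0.5) -> list[EnrichmentRow]:
    """Lineage pruning followed by driver-set cluster pruning."""
    return prune_clusters(prune_lineage(rows, dag), jaccard_merge=jaccard_merge)


# ---------------------------------------------------------------------------
# Enrichment map
# ---------------------------------------------------------------------------

def build_enrichment_map(
    rows: Sequence[EnrichmentRow],
    collection: GeneSetCollection,
    overlap_min: float = 0.5,
) -> EnrichmentMap:
    """Map of retained terms: node size = -log10(FDR); edges carry the
    overlap coefficient |A∩B|/min(|A|,|B|) on term gene sets, kept when
    >= overlap_min (inclusive).  n_genes additionally records the term size
    for drawings that scale nodes by gene count."""
    retained = sorted(
        (r for r in rows if r.status == "retained"), key=lambda r: r.term_id
    )
    nodes = [
        {
            "term_id": r.term_id,
            "name": r.name,
            "size_value": float(-np.log10(max(r.fdr, FDR_FLOOR))),
            "n_genes": r.K,
            "cluster_id": r.cluster_id,
        }
        for r in retained
    ]
    edges = []
    for i, a in enumerate(retained):
        set_a = collection.sets.get(a.term_id, a.drivers)
        for b in retained[i + 1 :]:
            set_b = collection.sets.get(b.term_id, b.drivers)
            inter = len(set_a & set_b)
            denom = min(len(set_a), len(set_b))
            coeff = inter / denom if denom else 0.0
            if coeff >= overlap_min:
                edges.append(
                    {
                        "term_a": a.term_id,
                        "term_b": b.term_id,
                        "overlap_coefficient": coeff,
                        "overlap_count": inter,
                    }
                )
    return EnrichmentMap(nodes=nodes, edges=edges)


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tidy export of enrichment rows (drivers semicolon-joined)."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "name": [r.name for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "p": [r.p for r in rows],
            "fdr": [r.fdr for r in rows],
            "status": [r.status for r in rows],
            "cluster_id": [r.cluster_id for r in rows],
            "drivers": [";".join(sorted(r.drivers)) for r in rows],
        }
    )
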