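"""Synthetic benchmark scenarios with planted ground truth.

Each function builds a study-shaped dataset with the synthetic module,
runs the relevant pipeline stages, and scores the result against the
planted truth: genome-scale recovery of planted fitness defects, null
calibration, planted-pathway enrichment, screen-group clustering, and the
read-counting round trip.  These are the scenarios the acceptance checks
and the validation tests both run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import counting, enrichment, fitness, similarity, synthetic

__all__ = [
    "recovery_run",
    "null_run",
    "pathway_run",
    "clustering_run",
    "replicate_adjacency_run",
    "read_roundtrip_run",
]


def _tag_matrix(counts: pd.DataFrame) -> counting.TagCountMatrix:
    qc = pd.DataFrame(
        {
            "total_reads": counts.sum(axis=0),
            "assigned": counts.sum(axis=0),
            "unmatched": 0,
            "ambiguous": 0,
        }
    )
    return counting.TagCountMatrix(counts=counts, qc=qc)


def _fd_for_truth(
    catalog: synthetic.StrainCatalog,
    design: synthetic.ScreenDesign,
    truth: synthetic.TruthTable,
    seed: int,
    dispersion: float = 0.05,
) -> fitness.FitnessTable:
    params = synthetic.NBParams(dispersion=dispersion, seed=seed)
    counts, _ = synthetic.simulate_counts(catalog, design, truth, params)
    gene_counts = fitness.collapse_tags(_tag_matrix(counts), catalog, design)
    return fitness.fd_table(gene_counts, design)


def recovery_run(
    catalog: synthetic.StrainCatalog,
    seed: int,
    n_planted: int = 100,
    true_lfc: float = -2.0,
) -> dict[str, float]:
    """One genome-scale 3v3 screen with planted depletions.

    Returns sensitivity of the FD >= 1 call on planted genes, the empirical
    FDR of the call, and the mean absolute FD error |FD - |true_lfc|| on
    planted genes.
    """
    design = synthetic.make_design([("cmpd", "1mM", "DMSO")], n_replicates=3)
    screen = design.screen_ids[0]
    rng = np.random.default_rng(seed)
    planted_genes = list(rng.choice(catalog.genes, size=n_planted, replace=False))
    truth = synthetic.make_truth(
        catalog, design, {screen: {g: true_lfc for g in planted_genes}}
    )
    table = _fd_for_truth(catalog, design, truth, seed=seed)
    sub = table.screen(screen).set_index("gene")
    called = set(sub.index[sub["call"] == "sensitive"])
    planted_set = set(planted_genes)
    tp = len(called & planted_set)
    fp = len(called - planted_set)
    sensitivity = tp / n_planted
    empirical_fdr = fp / max(len(called), 1)
    bias = float((sub.loc[planted_genes, "fd"] - abs(true_lfc)).abs().mean())
    return {"sensitivity": sensitivity, "fdr": empirical_fdr, "fd_error": bias}


def null_run(catalog: synthetic.StrainCatalog, seed: int) -> float:
    """Fraction of sensitive calls in a screen with no planted effects."""
    design = synthetic.make_design([("cmpd", "1mM", "DMSO")], n_replicates=3)
    truth = synthetic.make_truth(catalog, design)
    table = _fd_for_truth(catalog, design, truth, seed=seed)
    sub = table.screen(design.screen_ids[0])
    return float((sub["call"] == "sensitive").mean())


def pathway_run(seed: int, n_terms: int = 200, n_genes: int = 1000):
    """Plant one ontology term's members as depleted; enrich and prune.

    Picks a mid-sized term with a uniquely identifying gene set and at least
    one size-filtered ancestor, plants its members at -2.5, and returns
    (planted_term, pruned enrichment rows, dag).
    """
    import networkx as nx

    collection, dag = synthetic.make_toy_ontology(
        n_terms=n_terms, n_genes=n_genes, depth=4, seed=seed
    )
    filtered = collection.filter_sizes()
    set_counts: dict[frozenset, int] = {}
    for genes in collection.sets.values():
        set_counts[genes] = set_counts.get(genes, 0) + 1
    planted_term = None
    for term in sorted(filtered.sets):
        genes = filtered.sets[term]
        if not (10 <= len(genes) <= 40) or set_counts[genes] != 1:
            continue
        ancestors = nx.descendants(dag, term) if dag.has_node(term) else set()
        in_filter = [a for a in ancestors if a in filtered.sets]
        if in_filter:
            planted_term = term
            break
    if planted_term is None:  # pragma: no cover - generator guarantees one
        raise RuntimeError("no suitable term to plant")
    catalog = synthetic.make_catalog(n_genes, seed=seed + 1)
    design = synthetic.make_design([("cmpd", "1mM", "DMSO")], n_replicates=3)
    screen = design.screen_ids[0]
    truth = synthetic.make_truth(
        catalog,
        design,
        {screen: {g: -2.5 for g in filtered.sets[planted_term]}},
        planted_term={screen: planted_term},
    )
    table = _fd_for_truth(catalog, design, truth, seed=seed)
    rows = enrichment.enrich_screen(table, screen, filtered)
    rows = enrichment.prune(rows, dag)
    return planted_term, rows, dag


def clustering_run(
    seed: int,
    n_genes: int = 1200,
    n_groups: int = 3,
    group_size: int = 5,
    n_singletons: int = 7,
):
    """22 screens in 3 signature groups plus singletons; cluster and score.

    Returns (cluster labels at k=n_groups, true group labels) restricted to
    the grouped screens, plus the dendrogram.
    """
    catalog = synthetic.make_catalog(n_genes, seed=seed + 10)
    n_screens = n_groups * group_size + n_singletons
    compounds = [(f"cmpd{i}", "1mM", "DMSO") for i in range(n_screens)]
    design = synthetic.make_design(compounds, n_replicates=3)
    screens = design.screen_ids
    groups = {
        f"group{g}": screens[g * group_size : (g + 1) * group_size]
        for g in range(n_groups)
    }
    truth = synthetic.make_group_truth(
        catalog, design, groups, n_shared=60, n_private=20, lfc=-2.0, seed=seed
    )
    table = _fd_for_truth(catalog, design, truth, seed=seed)
    fd = fitness.fd_matrix(table)
    coin = similarity.coinhibition_matrix(fd)
    dend = similarity.ward_cluster(coin)
    cut = dend.cut(n_groups)
    grouped = [s for members in groups.values() for s in members]
    predicted = cut.loc[grouped]
    expected = pd.Series(
        {s: label for label, members in groups.items() for s in members}
    ).loc[grouped]
    return predicted, expected, dend


def replicate_adjacency_run(seed: int, n_genes: int = 800):
    """Replicate-level screens (one screen per replicate): each screen's
    nearest coinhibition neighbor should share its compound."""
    catalog = synthetic.make_catalog(n_genes, seed=seed + 20)
    dates = ["190801", "190802", "190803"]
    compounds, all_dates = [], []
    for name in ("NDMA", "NDEA"):
        for d in dates:
            compounds.append((name, "1mM", "DMSO"))
            all_dates.append(d)
    # one screen per biological replicate; duplicate samples within each so
    # dispersions remain estimable
    design = synthetic.make_design(compounds, n_replicates=2, date=all_dates)
    screens = design.screen_ids
    groups = {
        "NDMA": [s for s in screens if s.startswith("NDMA")],
        "NDEA": [s for s in screens if s.startswith("NDEA")],
    }
    truth = synthetic.make_group_truth(
        catalog, design, groups, n_shared=60, n_private=10, lfc=-2.0, seed=seed
    )
    table = _fd_for_truth(catalog, design, truth, seed=seed)
    coin = similarity.coinhibition_matrix(fitness.fd_matrix(table))
    hits = []
    for screen in screens:
        neighbor = coin.values[screen].drop(index=screen).idxmax()
        hits.append(neighbor.split("_")[0] == screen.split("_")[0])
    return hits


def read_roundtrip_run(seed: int, out_dir, n_strains: int = 960, error_rate: float = 0.01):
    """Simulate ~1e5 reads, count them back, and score assignment.

    Returns a dict with the error-free round-trip exactness, and at
    ``error_rate`` the fraction of reads assigned and the fraction of
    assigned reads assigned to the correct strain and tag.
    """
    catalog = synthetic.make_catalog(n_strains, seed=seed)
    design = synthetic.make_design([("cmpd", "1mM", "DMSO")], n_replicates=1)
    sample = design.samples[0]
    truth = synthetic.make_truth(catalog, design)
    params = synthetic.NBParams(
        baseline_log_mean=np.log(52), baseline_log_sd=0.3, seed=seed
    )
    counts, _ = synthetic.simulate_counts(catalog, design, truth, params)
    counts = counts[[sample]]
    exact_paths = synthetic.simulate_reads(counts, catalog, 0.0, seed=seed, out_dir=out_dir)
    matrix = counting.count_fastq(exact_paths, catalog)
    roundtrip_exact = bool(
        matrix.counts.loc[counts.index, counts.columns].equals(counts)
    )
    noisy_paths = synthetic.simulate_reads(
        counts, catalog, error_rate, seed=seed + 1, out_dir=out_dir
    )
    seqs = counting._read_fastq(noisy_paths[sample])
    index = counting.TagIndex(catalog, max_mm=1)
    outcomes = counting.classify_reads(seqs, index)
    tag_map = catalog.tag_to_strain()
    read_truth = np.repeat(counts.index.to_numpy(), counts[sample].to_numpy())
    assigned = correct = 0
    for outcome, true_tag in zip(outcomes, read_truth):
        if outcome is None or outcome == counting.AMBIGUOUS:
            continue
        assigned += 1
        correct += outcome == tag_map[true_tag]
    total = len(seqs)
    return {
        "roundtrip_exact": roundtrip_exact,
        "n_reads": total,
        "assigned_fraction": assigned / total,
        "assigned_accuracy": correct / max(assigned, 1),
    }
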