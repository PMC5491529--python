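"""Protein-protein interaction network statistics for associated gene sets.

The reference interactome merges several scored edge lists (confidence
score strictly above 0.7; whitelisted unscored sources kept wholesale).
The statistic of interest for a variant's associated genes is the size of
the largest connected component (LCC) of the induced subgraph, expressed
as a proportion of the induced nodes, with empirical significance from
three resampling nulls: other variants' gene sets, random variants, or
uniform random gene sets.  Enrichment of annotations inside a component is
assessed by permutation, with BH adjustment across transcription factors
for TF-target enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "merge_ppi",
    "LCCStat",
    "induced_lcc",
    "lcc_null",
    "empirical_p",
    "set_enrichment_perm",
    "tf_target_enrichment",
    "downreg_majority_test",
]


def empirical_p(null: np.ndarray, observed: float) -> float:
    """Add-one empirical P: (1 + #{null >= observed}) / (B + 1)."""
    null = np.asarray(null, dtype=float)
    return float((1 + (null >= observed).sum()) / (len(null) + 1))


def merge_ppi(
    edge_lists: list[pd.DataFrame],
    score_min: float = 0.7,
    always_include_sources: set[str] = frozenset({"HPRD"}),
) -> nx.Graph:
    """Merge scored edge lists into one reference interactome.

    Edges require confidence score strictly above ``score_min``; edges
    from whitelisted sources (databases publishing no score) are always
    kept.  Self-loops are dropped and duplicate edges collapsed with their
    source tags concatenated.
    """
    g = nx.Graph()
    for edges in edge_lists:
        for row in edges.itertuples(index=False):
            a, b = row.nodeA, row.nodeB
            if a == b:
                continue
            source = getattr(row, "source", "unknown")
            score = getattr(row, "score", np.nan)
            whitelisted = source in always_include_sources
            if not whitelisted and not (pd.notna(score) and score > score_min):
                continue
            if g.has_edge(a, b):
                sources = set(g.edges[a, b]["source"].split(";"))
                sources.add(str(source))
                g.edges[a, b]["source"] = ";".join(sorted(sources))
                if pd.notna(score):
                    prev = g.edges[a, b]["score"]
                    g.edges[a, b]["score"] = (
                        score if pd.isna(prev) else max(prev, score)
                    )
            else:
                g.add_edge(a, b, score=score, source=str(source))
    return g


@dataclass
class LCCStat:
    induced_nodes: int
    lcc_nodes: int
    lcc_edges: int
    proportion: float
    lcc_members: frozenset = frozenset()


def induced_lcc(network: nx.Graph, gene_set: set[str]) -> LCCStat:
    """Largest connected component of the subgraph induced by a gene set.

    The proportion denominator is the number of gene-set members present
    in the reference network.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    present = set(gene_set) & set(network.nodes)
    if not present:
        log.warning("induced_lcc: gene set disjoint from network")
        return LCCStat(0, 0, 0, float("nan"))
    sub = network.subgraph(present)
    comp = max(nx.connected_components(sub), key=len)
    lcc = sub.subgraph(comp)
    return LCCStat(
        induced_nodes=len(present),
        lcc_nodes=lcc.number_of_nodes(),
        lcc_edges=lcc.number_of_edges(),
        proportion=lcc.number_of_nodes() / len(present),
        lcc_members=frozenset(comp),
    )


def lcc_null(
    network: nx.Graph,
    observed: LCCStat,
    strategy: str,
    B: int = 10_000,
    set_size: int | None = None,
    mapping: dict[str, set[str]] | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Empirical P of an observed LCC proportion under a resampling null.

    Strategies:
      * ``variant_sets``   - the null is the LCC proportion of every
        variant's associated-gene set in ``mapping`` (a reference
        distribution over real variant sets);
      * ``random_variants`` - B draws of a random variant from ``mapping``
        and its gene set;
      * ``random_gene_sets`` - B uniform draws of ``set_size`` nodes from
        the reference network.
    """
    if B < 1:
        raise ValueError("B must be positive")
    rng = np.random.default_rng(seed)
    props = []
    if strategy in ("variant_sets", "random_variants"):
        if not mapping:
            raise ValueError(f"strategy {strategy!r} requires a variant->genes map")
        keys = sorted(mapping)
        if strategy == "variant_sets":
            chosen = keys
        else:
            chosen = [keys[i] for i in rng.integers(0, len(keys), size=B)]
        for key in chosen:
            genes = mapping[key]
            if not genes:
                continue
            stat = induced_lcc(network, genes)
            if np.isfinite(stat.proportion):
                props.append(stat.proportion)
    elif strategy == "random_gene_sets":
        if set_size is None:
            set_size = observed.induced_nodes
        nodes = np.array(sorted(network.nodes))
        for _ in range(B):
            pick = rng.choice(nodes, size=set_size, replace=False)
            props.append(induced_lcc(network, set(pick)).proportion)
    else:
        raise ValueError(f"unknown null strategy {strategy!r}")
    null = np.asarray(props)
    return empirical_p(null, observed.proportion), null


def set_enrichment_perm(
    component_genes: set[str],
    annotation_set: set[str],
    universe: set[str],
    B: int = 10_000,
    seed: int = 0,
) -> tuple[float, int]:
    """Permutation enrichment of an annotation within a component.

    The statistic is the overlap size; the null draws ``B`` uniform gene
    sets of the component's size from the universe.  Returns (empirical P,
    observed overlap).
    """
    component = set(component_genes)
    if not component <= set(universe):
        raise ValueError("component must be a subset of the universe")
    annot = set(annotation_set) & set(universe)
    if not annot:
        raise ValueError("annotation set disjoint from the universe")
    observed = len(component & annot)
    rng = np.random.default_rng(seed)
    uni = np.array(sorted(universe))
    is_annot = np.isin(uni, sorted(annot))
    k = len(component)
    null = np.empty(B)
    for i in range(B):
        idx = rng.choice(len(uni), size=k, replace=False)
        null[i] = is_annot[idx].sum()
    return empirical_p(null, observed), observed


def tf_target_enrichment(
    component_genes: set[str],
    tf_targets: dict[str, set[str]],
    universe: set[str],
    B: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-TF permutation enrichment with BH adjustment across TFs."""
    if not tf_targets:
        raise ValueError("need at least one TF target set")
    rows = []
    for i, (tf, targets) in enumerate(sorted(tf_targets.items())):
        usable = set(targets) & set(universe)
        if not usable:
            log.info("tf_target_enrichment: %s has no targets in universe", tf)
            continue
        p, obs = set_enrichment_perm(
            component_genes, usable, universe, B=B, seed=seed + i
        )
        rows.append({"tf": tf, "overlap": obs, "p_value": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.set_index("tf") if not out.empty else out


def downreg_majority_test(
    n_down: int, n_total: int, reference_proportion: float = 0.5
) -> float:
    """Two-sided one-sample proportion z-test with continuity correction.

    Tests whether the downregulated fraction differs from
    ``reference_proportion`` (default: an even split).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    p0 = reference_proportion
    se = np.sqrt(p0 * (1 - p0) / n_total)
    cc = 0.5 / n_total
    z = max(abs(n_down / n_total - p0) - cc, 0.0) / se
    return float(min(2 * stats.norm.sf(z), 1.0))
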