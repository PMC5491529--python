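"""Hi-C link definition and deregulation-concordance testing.

A "link" of an anchor locus is a genomic bin whose normalized chromatin
contact signal exceeds the 90th percentile of the anchor's full
intra-chromosomal signal distribution.  Concordance asks whether
transcripts inside link bins are more deregulated in the comparison of
interest (locus-edited vs control cells) than in same-class comparisons
(edited vs edited, control vs control), via two-sided Mann-Whitney tests,
plus an empirical null over random same-size gene sets on the chromosome.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .network import empirical_p

log = logging.getLogger(__name__)

__all__ = ["define_links", "assign_genes_to_bins", "concordance_test", "random_gene_null"]


def define_links(signal: pd.DataFrame, percentile: float = 90.0) -> list[str]:
    """Bins with contact signal strictly above the given percentile.

    ``signal`` needs columns ``bin`` and ``signal``; the threshold is the
    linearly interpolated empirical percentile of all bins.  A constant
    signal yields no links.
    """
    if len(signal) < 10:
        raise ValueError("need at least 10 bins to define links")
    values = signal["signal"].to_numpy(dtype=float)
    threshold = float(np.percentile(values, percentile))
    links = signal.loc[values > threshold, "bin"]
    if links.empty:
        log.warning("define_links: constant or degenerate signal, no links")
    return list(links)


def assign_genes_to_bins(genes: pd.DataFrame, bins: pd.DataFrame) -> pd.Series:
    """Map genes to bins by transcription-start-site containment.

    ``genes`` needs columns ``gene`` and ``tss``; ``bins`` needs ``bin``,
    ``start``, ``end`` (half-open).  Genes whose TSS falls in no bin map
    to NA.
    """
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    names = bins["bin"].to_numpy()[order]
    tss = genes["tss"].to_numpy()
    idx = np.searchsorted(starts, tss, side="right") - 1
    ok = (idx >= 0) & (tss < ends[np.clip(idx, 0, None)])
    mapped = np.where(ok, names[np.clip(idx, 0, None)], None)
    return pd.Series(mapped, index=genes["gene"], name="bin")


def concordance_test(
    deg_tables: dict[str, pd.DataFrame],
    links: list[str],
    gene_to_bin: pd.Series,
    focal_class: str = "edited_vs_control",
    min_genes: int = 3,
) -> pd.DataFrame:
    """Mann-Whitney comparison of link-gene deregulation across classes.

    ``deg_tables`` maps comparison class to a table indexed by gene with a
    ``log2_ratio`` column.  Genes are restricted to link bins; the focal
    class's |log2 ratio| distribution is compared two-sided against every
    other class.
    """
    if focal_class not in deg_tables:
        raise ValueError(f"missing focal class {focal_class!r}")
    link_set = set(links)
    link_genes = set(gene_to_bin.index[gene_to_bin.isin(link_set)])

    def link_values(df: pd.DataFrame) -> np.ndarray:
        genes = df.index.intersection(link_genes)
        return df.loc[genes, "log2_ratio"].abs().to_numpy(dtype=float)

    focal = link_values(deg_tables[focal_class])
    if len(focal) < min_genes:
        raise ValueError(
            f"only {len(focal)} genes in link bins; need >= {min_genes}"
        )
    rows = []
    for cls, df in deg_tables.items():
        if cls == focal_class:
            continue
        other = link_values(df)
        p = float(stats.mannwhitneyu(focal, other, alternative="two-sided").pvalue)
        rows.append(
            {
                "contrast": cls,
                "n_focal": len(focal),
                "n_contrast": len(other),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def random_gene_null(
    deg_table: pd.DataFrame,
    universe: list[str],
    links: list[str],
    gene_to_bin: pd.Series,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Empirical P of observed link-gene deregulation vs random gene sets.

    The statistic is the mean |log2 ratio| of link-bin genes; the null
    draws ``B`` random gene sets of the same size from the chromosome's
    gene universe.  Add-one empirical P.
    """
    link_set = set(links)
    link_genes = [
        g for g in deg_table.index
        if g in gene_to_bin.index and gene_to_bin[g] in link_set
    ]
    observed = float(deg_table.loc[link_genes, "log2_ratio"].abs().mean())
    pool = [g for g in universe if g in deg_table.index]
    if len(pool) < len(link_genes):
        raise ValueError("gene universe smaller than the observed set")
    rng = np.random.default_rng(seed)
    abs_ratio = deg_table["log2_ratio"].abs()
    null = np.empty(B)
    for i in range(B):
        pick = rng.choice(pool, size=len(link_genes), replace=False)
        null[i] = abs_ratio.loc[pick].mean()
    return empirical_p(null, observed), null
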