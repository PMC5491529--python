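"""Functional-region consensus, variant selection by mark logic, and LD.

A putative active enhancer is defined by histone-mark consensus: the
presence of H3K4me1 and H3K27ac signal and the absence of H3K4me3 signal,
where each mark's consensus is built across cell lines.  Variants inside
such enhancers are the candidate "functional variants"; completely dependent
variants (pairwise D' = 1 and r^2 = 1) are pruned to one representative.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "build_consensus",
    "select_functional_variants",
    "prune_dependent",
    "haplotype_em",
    "ld_pair",
    "ld_report",
]


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping or book-ended intervals per chromosome."""
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    out = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is None or row.chrom != cur[0] or row.start > cur[2]:
            if cur is not None:
                out.append(cur)
            cur = [row.chrom, row.start, row.end]
        else:
            cur[2] = max(cur[2], row.end)
    out.append(cur)
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _overlap_with_union(
    iv: tuple[str, int, int], merged: pd.DataFrame
) -> int:
    """Bases of ``iv`` covered by the merged interval set (no double count)."""
    chrom, start, end = iv
    sub = merged[merged["chrom"] == chrom]
    if sub.empty:
        return 0
    s = np.maximum(sub["start"].to_numpy(), start)
    e = np.minimum(sub["end"].to_numpy(), end)
    return int(np.clip(e - s, 0, None).sum())


def build_consensus(
    tracks: dict[str, pd.DataFrame],
    min_signal: float = 5.0,
    min_cell_lines: int = 2,
    min_overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Cross-cell-line consensus regions for one histone mark.

    Intervals with enrichment signal strictly above ``min_signal`` are kept;
    an interval survives if the union of same-mark intervals from *other*
    cell lines covers at least ``min_overlap_fraction`` of its length.
    Survivors are concatenated, sorted and merged into disjoint regions.

    Parameters
    ----------
    tracks
        Mapping cell line -> interval table (chrom, start, end, signal).
    """
    if len(tracks) < min_cell_lines:
        raise ValueError(
            f"need intervals from at least {min_cell_lines} cell lines, "
            f"got {len(tracks)}"
        )
    filtered = {
        line: df[df["signal"] > min_signal].reset_index(drop=True)
        for line, df in tracks.items()
    }
    merged_by_line = {line: _merge_intervals(df) for line, df in filtered.items()}
    retained = []
    for line, df in filtered.items():
        others = pd.concat(
            [m for other, m in merged_by_line.items() if other != line],
            ignore_index=True,
        )
        others = _merge_intervals(others)
        for row in df.itertuples(index=False):
            length = row.end - row.start
            ov = _overlap_with_union((row.chrom, row.start, row.end), others)
            if ov >= min_overlap_fraction * length:
                retained.append((row.chrom, row.start, row.end))
    return _merge_intervals(pd.DataFrame(retained, columns=["chrom", "start", "end"]))


def _in_intervals(
    chrom: np.ndarray, pos0: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """Membership of 0-based positions in a disjoint sorted interval set."""
    hit = np.zeros(len(chrom), dtype=bool)
    for c, sub in intervals.groupby("chrom"):
        mask = chrom == c
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        p = pos0[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
        hit[np.flatnonzero(mask)] = ok
    return hit


def select_functional_variants(
    variants: pd.DataFrame,
    consensus_h3k4me1: pd.DataFrame,
    consensus_h3k27ac: pd.DataFrame,
    consensus_h3k4me3: pd.DataFrame,
) -> pd.DataFrame:
    """Variants in H3K4me1 AND H3K27ac consensus but NOT in H3K4me3.

    ``variants`` needs columns id, chrom, pos (1-based); positions are
    converted to 0-based for half-open interval membership.
    """
    chrom = variants["chrom"].to_numpy()
    pos0 = variants["pos"].to_numpy() - 1
    keep = (
        _in_intervals(chrom, pos0, consensus_h3k4me1)
        & _in_intervals(chrom, pos0, consensus_h3k27ac)
        & ~_in_intervals(chrom, pos0, consensus_h3k4me3)
    )
    return variants[keep].reset_index(drop=True)


def prune_dependent(
    variant_ids: list[str], ld_pairs: pd.DataFrame, tol: float = 0.0
) -> list[str]:
    """Keep one representative per completely dependent variant group.

    Two variants are completely dependent when both D' and r^2 equal 1
    (within ``tol``).  Connected components of the dependence graph are
    collapsed to their lexicographically smallest id.
    """
    g = nx.Graph()
    g.add_nodes_from(variant_ids)
    if not ld_pairs.empty:
        dep = ld_pairs[
            (ld_pairs["d_prime"] >= 1.0 - tol) & (ld_pairs["r2"] >= 1.0 - tol)
        ]
        for row in dep.itertuples(index=False):
            if row.variant_a in g and row.variant_b in g:
                g.add_edge(row.variant_a, row.variant_b)
    keep = sorted(min(comp) for comp in nx.connected_components(g))
    return keep


def haplotype_em(
    g1: np.ndarray,
    g2: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> np.ndarray:
    """EM estimate of two-locus haplotype frequencies from unphased dosages.

    Dosages are minor-allele counts in {0,1,2}; samples with a missing call
    at either locus must be removed beforehand.  Returns frequencies of the
    haplotypes (00, 01, 10, 11) where 1 denotes the minor allele.  Only the
    double heterozygote is phase-ambiguous; the EM iterates its split.
    """
    g1 = np.asarray(g1, dtype=int)
    g2 = np.asarray(g2, dtype=int)
    n = len(g1)
    if n == 0:
        raise ValueError("no samples")
    # counts of the nine genotype combinations
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1
    # unambiguous haplotype counts (each person carries two haplotypes)
    base = np.zeros(4)  # 00, 01, 10, 11

    def hap_idx(a1: int, a2: int) -> int:
        return 2 * a1 + a2

    for a in range(3):
        for b in range(3):
            c = counts[a, b]
            if c == 0 or (a == 1 and b == 1):
                continue
            # alleles at locus1: a copies of minor; resolve per haplotype
            h1 = (min(a, 1), min(b, 1))
            h2 = (a - h1[0], b - h1[1])
            base[hap_idx(*h1)] += c
            base[hap_idx(*h2)] += c
    n_dh = counts[1, 1]  # double heterozygotes: 00/11 or 01/10
    freqs = np.full(4, 0.25)
    prev_ll = -np.inf
    for _ in range(max_iter):
        if n_dh > 0:
            p_cis = freqs[0] * freqs[3]
            p_trans = freqs[1] * freqs[2]
            denom = p_cis + p_trans
            w = 0.5 if denom == 0 else p_cis / denom
        else:
            w = 0.0
        h = base.copy()
        h[0] += n_dh * w
        h[3] += n_dh * w
        h[1] += n_dh * (1 - w)
        h[2] += n_dh * (1 - w)
        freqs = h / h.sum()
        with np.errstate(divide="ignore"):
            ll = float(
                np.sum(base * np.log(np.where(freqs > 0, freqs, 1)))
                + (
                    n_dh
                    * np.log(freqs[0] * freqs[3] + freqs[1] * freqs[2])
                    if n_dh > 0
                    else 0.0
                )
            )
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return freqs


def ld_pair(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """D' and r^2 between two biallelic loci from unphased dosages."""
    f = haplotype_em(g1, g2)
    p1 = f[2] + f[3]  # minor-allele freq locus 1
    p2 = f[1] + f[3]
    d = f[3] - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom <= 0:
        raise ValueError("monomorphic locus")
    r2 = d * d / denom
    if d >= 0:
        dmax = min(p1 * (1 - p2), (1 - p1) * p2)
    else:
        dmax = min(p1 * p2, (1 - p1) * (1 - p2))
    d_prime = 0.0 if dmax == 0 else abs(d) / dmax
    return float(min(d_prime, 1.0)), float(min(r2, 1.0))


def ld_report(
    genotypes: pd.DataFrame,
    focal: str,
    positions: pd.Series | None = None,
    window_bp: int | None = None,
    r2_min: float = 0.10,
) -> pd.DataFrame:
    """Pairwise LD of every variant against a focal variant.

    Returns pairs with r^2 strictly above ``r2_min`` sorted by descending
    r^2.  ``positions`` (variant -> bp) with ``window_bp`` restricts partners
    to a window around the focal variant; monomorphic partners are skipped.
    """
    from .synthdata import MISSING

    if focal not in genotypes.columns:
        raise ValueError(f"focal variant {focal!r} not genotyped")
    gf = genotypes[focal].to_numpy(dtype=int)
    rows = []
    for var in genotypes.columns:
        if var == focal:
            continue
        if positions is not None and window_bp is not None:
            if abs(positions[var] - positions[focal]) > window_bp:
                continue
        gp = genotypes[var].to_numpy(dtype=int)
        ok = (gf != MISSING) & (gp != MISSING)
        a, b = gf[ok], gp[ok]
        if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
            log.info("ld_report: skipping monomorphic partner %s", var)
            continue
        d_prime, r2 = ld_pair(a, b)
        if r2 > r2_min:
            rows.append(
                {"variant_a": focal, "variant_b": var, "d_prime": d_prime, "r2": r2}
            )
    out = pd.DataFrame(rows, columns=["variant_a", "variant_b", "d_prime", "r2"])
    return out.sort_values("r2", ascending=False).reset_index(drop=True)
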