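"""Expression normalization, hormone-regulated gene lists, and DEG calls.

Raw abundances arrive as RPKM; the analysis operates on log2(RPKM+1) after
quantile normalization, so every sample shares one reference distribution.
Hormone-regulated genes are derived from treated/control replicate pairs
(genes detected in both members, then |log2 fold change| >= 1, union across
replicates).  Two-sample deregulation calls floor sub-1 RPKM values to 1
and flag |log2 ratio| >= 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "log2_rpkm",
    "quantile_normalize",
    "normalize",
    "derive_hormone_genes",
    "deg_call",
]


def log2_rpkm(raw: pd.DataFrame) -> pd.DataFrame:
    """log2(RPKM + 1); raw values must be non-negative."""
    if (raw.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return np.log2(raw + 1.0)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Rank-wise quantile normalization across samples (columns).

    Each sample's values are replaced by the cross-sample means of the
    order statistics at their ranks; tied values within a sample receive
    the mean of the reference values of their tied rank block.  After the
    transform every column has an identical sorted value vector.
    """
    x = values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        order = np.argsort(x[:, j], kind="mergesort")
        col = np.empty(n_genes)
        col[order] = ref
        # ties: every member of a tied block gets the block's mean ref value
        vals, inv = np.unique(x[:, j], return_inverse=True)
        sums = np.bincount(inv, weights=col)
        cnts = np.bincount(inv)
        out[:, j] = (sums / cnts)[inv]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Full normalization: log2(RPKM+1) then quantile normalization."""
    return quantile_normalize(log2_rpkm(raw))


def derive_hormone_genes(
    replicates: list[tuple[pd.DataFrame, pd.DataFrame]],
    detection_alpha: float = 0.05,
    min_abs_log2: float = 1.0,
) -> list[str]:
    """Hormone-regulated gene list from treated/control replicate pairs.

    Each replicate is a pair of single-sample tables with columns ``value``
    (raw intensity/abundance) and ``detection_p``.  Per replicate: keep
    genes detected (P < ``detection_alpha``) in both members, quantile-
    normalize the two log2(value+1) vectors jointly, and select genes with
    |log2(treated) - log2(control)| >= ``min_abs_log2``.  The final list is
    the union across replicates (a gene differentially expressed in at
    least one replicate qualifies).
    """
    if not replicates:
        raise ValueError("at least one treated/control replicate required")
    selected: set[str] = set()
    for treated, control in replicates:
        detected = (treated["detection_p"] < detection_alpha) & (
            control["detection_p"] < detection_alpha
        )
        genes = treated.index[detected]
        if len(genes) == 0:
            log.warning("derive_hormone_genes: no genes detected in a replicate")
            continue
        pair = pd.DataFrame(
            {
                "treated": np.log2(treated.loc[genes, "value"] + 1.0),
                "control": np.log2(control.loc[genes, "value"] + 1.0),
            }
        )
        norm = quantile_normalize(pair)
        change = (norm["treated"] - norm["control"]).abs()
        selected.update(genes[change >= min_abs_log2])
    if not selected:
        log.warning("derive_hormone_genes: empty final gene list")
    return sorted(selected)


def deg_call(
    sample_a: pd.Series, sample_b: pd.Series, min_rpkm: float = 1.0
) -> pd.DataFrame:
    """Deregulated transcripts between two raw RPKM vectors.

    Transcripts with RPKM <= ``min_rpkm`` in both samples are excluded;
    remaining values below the floor are set to it.  ``log2_ratio`` is
    log2(a/b); a transcript is deregulated when |log2_ratio| >= 1, with
    direction "up" when sample_a exceeds sample_b.
    """
    common = sample_a.index.intersection(sample_b.index)
    if len(common) != len(sample_a) or len(common) != len(sample_b):
        raise ValueError("samples must share one gene universe")
    a = sample_a.loc[common].to_numpy(dtype=float)
    b = sample_b.loc[common].to_numpy(dtype=float)
    tested = (a > min_rpkm) | (b > min_rpkm)
    af = np.maximum(a[tested], min_rpkm)
    bf = np.maximum(b[tested], min_rpkm)
    ratio = np.log2(af / bf)
    out = pd.DataFrame(
        {
            "gene": np.asarray(common)[tested],
            "log2_ratio": ratio,
            "deregulated": np.abs(ratio) >= 1.0,
        }
    )
    out["direction"] = np.where(out["log2_ratio"] > 0, "up", "down")
    out.loc[out["log2_ratio"] == 0, "direction"] = "none"
    return out.set_index("gene")
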