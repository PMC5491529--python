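"""Trigger-score assessment: eQTL-style regression and variant ranking.

For each candidate functional variant, expression of a predefined panel of
DNA-repair and hormone-regulated transcripts is regressed on the coded
genotype under up to three models (dosage = minor-allele count, dominant =
carrier indicator, recessive = minor-homozygote indicator).  Within each
(variant, model) family the transcript P-values receive a Benjamini-
Hochberg adjustment; the model with the highest percentage of associated
transcripts defines the variant's DnaRep and HormReg counts, combined into

    trigger score = ln(DnaRep x HormReg + 1)

Variants are ranked by score and the top tertile of the positive-score
distribution is retained.  Tissue specificity is assessed by recomputing
scores on repeated subsamples of an alternative (non-prostate) panel: a
variant whose score is never positive there is flagged non-global.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata import MISSING

log = logging.getLogger(__name__)

__all__ = [
    "MODELS",
    "code_genotype",
    "eligible_transcripts",
    "eqtl_scan",
    "trigger_score",
    "score_variants",
    "rank_top_tertile",
    "direction_summary",
    "two_proportion_test",
    "specificity_flags",
    "spop_de_test",
]

MODELS = ("dosage", "dominant", "recessive")
_MODEL_PRIORITY = {m: i for i, m in enumerate(MODELS)}
P_FLOOR = 1e-300


def code_genotype(dosage: np.ndarray, model: str) -> np.ndarray:
    """Code minor-allele dosages under a genotype model."""
    if model == "dosage":
        return dosage.astype(float)
    if model == "dominant":
        return (dosage >= 1).astype(float)
    if model == "recessive":
        return (dosage == 2).astype(float)
    raise ValueError(f"unknown model {model!r}")


def model_applicable(
    dosage: np.ndarray, model: str, min_class_fraction: float = 0.03
) -> bool:
    """Genotype-class requirements for applying a model.

    The dosage test needs all three genotype classes present; dominant and
    recessive need at least ``min_class_fraction`` of samples in each coded
    class.
    """
    if model == "dosage":
        return len(np.unique(dosage)) == 3
    x = code_genotype(dosage, model)
    n = len(x)
    k = x.sum()
    return min(k, n - k) >= min_class_fraction * n


def eligible_transcripts(
    expr: pd.DataFrame, gene_sets: dict[str, set[str]] | None = None,
    min_value: float = 1.0,
) -> list[str]:
    """Transcripts with normalized value >= ``min_value`` in >=1 sample.

    When ``gene_sets`` is given, the universe is first restricted to the
    union of the supplied panels.
    """
    genes = expr.index
    if gene_sets is not None:
        universe = set().union(*gene_sets.values())
        genes = genes[genes.isin(universe)]
    sub = expr.loc[genes]
    keep = sub.max(axis=1) >= min_value
    return list(sub.index[keep])


def _ols_scan(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row OLS slope and two-sided P of expression on coded genotype.

    ``y`` is transcripts x samples, ``x`` the coded genotype.  Constant
    transcripts get slope 0 and P = 1.
    """
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = y - y.mean(axis=1, keepdims=True)
    sxy = yc @ xc
    beta = sxy / sxx
    syy = np.einsum("ij,ij->i", yc, yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t2 = np.where(r2 < 1.0, r2 * df / (1.0 - r2), np.inf)
    p = stats.t.sf(np.sqrt(t2), df) * 2.0
    p = np.where(syy > 0, p, 1.0)
    beta = np.where(syy > 0, beta, 0.0)
    return beta, np.clip(p, P_FLOOR, 1.0)


def eqtl_scan(
    expr: pd.DataFrame,
    genotypes: pd.DataFrame,
    transcripts: list[str] | None = None,
    models: tuple[str, ...] = MODELS,
    min_class_fraction: float = 0.03,
    fdr_threshold: float = 0.05,
    variants: list[str] | None = None,
) -> pd.DataFrame:
    """Per-(variant, model, transcript) regression with BH adjustment.

    ``expr`` is a normalized genes x samples matrix and ``genotypes`` a
    samples x variants dosage matrix over the same samples.  Missing
    genotypes are dropped per variant.  BH families are formed by all
    transcripts tested for one (variant, model); ``significant`` marks
    fdr <= ``fdr_threshold``.  Models whose genotype-class requirements
    fail are skipped and logged.
    """
    samples = expr.columns.intersection(genotypes.index)
    if len(samples) == 0:
        raise ValueError("no shared samples between expression and genotypes")
    expr = expr[samples]
    genotypes = genotypes.loc[samples]
    if transcripts is None:
        transcripts = list(expr.index)
    y_all = expr.loc[transcripts].to_numpy(dtype=float)
    var_list = list(genotypes.columns) if variants is None else list(variants)

    frames = []
    for var in var_list:
        g = genotypes[var].to_numpy(dtype=int)
        ok = g != MISSING
        if ok.sum() < 3:
            log.info("eqtl_scan: %s has <3 called samples, skipped", var)
            continue
        dose = g[ok]
        if len(np.unique(dose)) < 2:
            continue  # monomorphic
        y = y_all[:, ok]
        for model in models:
            if not model_applicable(dose, model, min_class_fraction):
                log.debug("eqtl_scan: %s model %s skipped (classes)", var, model)
                continue
            x = code_genotype(dose, model)
            if np.ptp(x) == 0:
                continue
            beta, p = _ols_scan(y, x)
            fdr = multipletests(p, method="fdr_bh")[1]
            frames.append(
                pd.DataFrame(
                    {
                        "variant": var,
                        "transcript": transcripts,
                        "model": model,
                        "beta": beta,
                        "p_value": p,
                        "fdr": fdr,
                        "significant": fdr <= fdr_threshold,
                    }
                )
            )
    cols = ["variant", "transcript", "model", "beta", "p_value", "fdr", "significant"]
    if not frames:
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    out["direction"] = np.where(
        out["beta"] < 0, "down", np.where(out["beta"] > 0, "up", "none")
    )
    return out


def trigger_score(dnarep_count: int, hormreg_count: int) -> float:
    """Natural-log composite score ln(DnaRep x HormReg + 1)."""
    if dnarep_count < 0 or hormreg_count < 0:
        raise ValueError("counts must be non-negative")
    return float(np.log(dnarep_count * hormreg_count + 1))


def score_variants(
    eqtl: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Trigger records from an eQTL scan.

    Per variant the model with the highest percentage of associated
    transcripts (among all transcripts tested in that family) is selected,
    ties broken dosage > dominant > recessive; the DnaRep/HormReg counts of
    that model feed the score.
    """
    dnarep = gene_sets["dnarep"]
    hormreg = gene_sets["hormreg"]
    rows = []
    for variant, var_df in eqtl.groupby("variant", sort=True):
        best = None
        for model, mdf in var_df.groupby("model"):
            n_tested = len(mdf)
            sig = mdf[mdf["fdr"] <= fdr_threshold]
            pct = len(sig) / n_tested if n_tested else 0.0
            cand = (pct, -_MODEL_PRIORITY[model], model, sig)
            if best is None or cand[:2] > best[:2]:
                best = cand
        if best is None:
            log.info("score_variants: %s has no eligible model, omitted", variant)
            continue
        _, _, model, sig = best
        dn = int(sig["transcript"].isin(dnarep).sum())
        hr = int(sig["transcript"].isin(hormreg).sum())
        score = trigger_score(dn, hr)
        rows.append(
            {
                "variant": variant,
                "dnarep_count": dn,
                "hormreg_count": hr,
                "model_used": model,
                "score": score,
                "positive": score > 0,
            }
        )
    return (
        pd.DataFrame(
            rows,
            columns=[
                "variant",
                "dnarep_count",
                "hormreg_count",
                "model_used",
                "score",
                "positive",
            ],
        )
        .sort_values(["score", "variant"], ascending=[False, True])
        .reset_index(drop=True)
    )


def rank_top_tertile(records: pd.DataFrame) -> list[str]:
    """Variants in the highest tertile of the positive-score distribution."""
    pos = records[records["score"] > 0]
    if pos.empty:
        log.warning("rank_top_tertile: no positive trigger scores")
        return []
    threshold = float(np.quantile(pos["score"], 2 / 3))
    return list(pos.loc[pos["score"] >= threshold, "variant"])


def direction_summary(
    eqtl_variant: pd.DataFrame, fdr_threshold: float = 0.05
) -> tuple[int, int, float]:
    """(n_down, n_up, fraction_down) among significant transcripts.

    Betas are minor-allele coded, so beta < 0 means the minor allele lowers
    expression.  Zero betas count as neither direction.
    """
    sig = eqtl_variant[eqtl_variant["fdr"] <= fdr_threshold]
    n_down = int((sig["beta"] < 0).sum())
    n_up = int((sig["beta"] > 0).sum())
    n_zero = len(sig) - n_down - n_up
    if n_zero:
        log.info("direction_summary: %d zero-beta transcripts uncounted", n_zero)
    total = n_down + n_up
    frac = n_down / total if total else float("nan")
    return n_down, n_up, frac


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-sample proportion z-test with Yates correction.

    Pooled-variance z statistic with continuity correction
    0.5*(1/n1 + 1/n2); equivalent to the Yates-corrected chi-square on the
    2x2 table.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se2 = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if se2 == 0:
        return 1.0
    cc = 0.5 * (1 / n1 + 1 / n2)
    z = max(abs(p1 - p2) - cc, 0.0) / np.sqrt(se2)
    return float(min(2 * stats.norm.sf(z), 1.0))


def specificity_flags(
    records: pd.DataFrame,
    alt_expr: pd.DataFrame,
    alt_genotypes: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    n_resample: int = 100,
    subsample_size: int = 63,
    seed: int = 0,
    models: tuple[str, ...] = MODELS,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Annotate records global / non-global from an alternative panel.

    The trigger score of each record's variant is recomputed on
    ``n_resample`` random subsamples (size ``subsample_size``) of the
    alternative expression panel; a variant is non-global iff no subsample
    yields a positive score.
    """
    samples = alt_expr.columns.intersection(alt_genotypes.index)
    if len(samples) < subsample_size:
        raise ValueError(
            f"alternative panel has {len(samples)} samples, "
            f"fewer than subsample_size={subsample_size}"
        )
    rng = np.random.default_rng(seed)
    variants = list(records["variant"])
    transcripts = eligible_transcripts(alt_expr[samples], gene_sets)
    any_positive = {v: False for v in variants}
    for _ in range(n_resample):
        sub = rng.choice(samples, size=subsample_size, replace=False)
        scan = eqtl_scan(
            alt_expr[sub],
            alt_genotypes.loc[sub],
            transcripts=transcripts,
            models=models,
            fdr_threshold=fdr_threshold,
            variants=variants,
        )
        if scan.empty:
            continue
        scored = score_variants(scan, gene_sets, fdr_threshold)
        for v in scored.loc[scored["score"] > 0, "variant"]:
            any_positive[v] = True
        if all(any_positive.values()):
            break
    out = records.copy()
    out["specificity"] = [
        "global" if any_positive[v] else "non_global" for v in out["variant"]
    ]
    return out


def spop_de_test(
    expr_tumors: pd.DataFrame,
    group_labels: pd.Series,
    genes: list[str],
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Per-gene Mann-Whitney test, mutant vs wild-type tumors.

    ``group_labels`` maps sample -> {"mutant", "wildtype"}; constant genes
    get P = 1.
    """
    mut = group_labels.index[group_labels == "mutant"]
    wt = group_labels.index[group_labels == "wildtype"]
    if len(mut) == 0 or len(wt) == 0:
        raise ValueError("both groups must be nonempty")
    rows = []
    for gene in genes:
        a = expr_tumors.loc[gene, mut].to_numpy(dtype=float)
        b = expr_tumors.loc[gene, wt].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"gene": gene, "p_value": p, "significant": p <= p_cutoff})
    return pd.DataFrame(rows).set_index("gene")
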