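"""Genotype/phenotype association and cohort-level analyses.

Association of candidate variants with binary somatic-lesion phenotypes
uses covariate-adjusted logistic regression under allelic (dosage),
dominant and recessive codings.  The discovery/validation scheme splits
the cohort into two incidence-preserving halves many times; an
association counts only when it passes a BH FDR gate in the discovery
half and a P-value gate (with concordant effect direction) in the
validation half.  Somatic-burden comparisons use Mann-Whitney tests and
ancestry is assigned by convex hulls in PC1-PC2 of standardized dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon
from statsmodels.stats.multitest import multipletests

from .synthdata import MISSING
from .trigger import code_genotype

log = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "fit_logistic_irls",
    "qc_call_rate",
    "logistic_assoc",
    "partition_cv",
    "PartitionTally",
    "genomic_burden",
    "burden_test",
    "infer_ancestry",
]

ASSOC_MODELS = ("allelic", "dominant", "recessive")
_CODING = {"allelic": "dosage", "dominant": "dominant", "recessive": "recessive"}


@dataclass
class LogisticFit:
    """Result of one IRLS logistic fit (genotype coefficient of interest)."""

    coef: np.ndarray
    se: np.ndarray
    converged: bool
    separated: bool
    n_iter: int

    @property
    def estimable(self) -> bool:
        return self.converged and not self.separated


def fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    beta_cap: float = 20.0,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` includes the intercept column.  Convergence is declared when the
    maximum coefficient change falls below ``tol``; coefficients exceeding
    ``beta_cap`` in absolute value flag (quasi-)separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        xtw = X.T * w
        try:
            new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            return LogisticFit(beta, np.full(p, np.nan), False, True, it)
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > beta_cap * 5:
            break
    separated = bool(np.max(np.abs(beta)) > beta_cap)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        separated = True
    return LogisticFit(beta, se, converged, separated, it)


def qc_call_rate(genotypes: pd.DataFrame, min_call_rate: float = 0.85) -> list[str]:
    """Variants whose non-missing genotype fraction is >= ``min_call_rate``."""
    called = (genotypes != MISSING).mean(axis=0)
    return list(called.index[called >= min_call_rate])


def logistic_assoc(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    model: str = "dominant",
    variant: str | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted logistic association for one or all variants.

    ``phenotype`` is binary (1 = lesion present) indexed by sample;
    ``covariates`` (e.g. age, PSA) are aligned on the same index.  Returns
    one row per variant with odds_ratio = exp(genotype coefficient), Wald
    two-sided P, and an ``estimable`` flag (False on separation or
    non-convergence, and for constant codings).
    """
    if model not in ASSOC_MODELS:
        raise ValueError(f"unknown association model {model!r}")
    samples = genotypes.index.intersection(phenotype.index)
    y_all = phenotype.loc[samples].to_numpy(dtype=float)
    if y_all.sum() == 0 or y_all.sum() == len(y_all):
        raise ValueError("phenotype needs at least one case and one control")
    if covariates is not None:
        cov_all = covariates.loc[samples].to_numpy(dtype=float)
    else:
        cov_all = np.empty((len(samples), 0))
    variants = [variant] if variant is not None else list(genotypes.columns)
    rows = []
    for var in variants:
        g = genotypes.loc[samples, var].to_numpy(dtype=int)
        ok = g != MISSING
        y = y_all[ok]
        x = code_genotype(g[ok].astype(float), _CODING[model])
        row = {
            "variant": var,
            "model": model,
            "n_cases": int(y.sum()),
            "n_controls": int(len(y) - y.sum()),
        }
        if np.ptp(x) == 0 or y.sum() == 0 or y.sum() == len(y):
            rows.append(
                {**row, "odds_ratio": np.nan, "p_value": np.nan, "estimable": False}
            )
            continue
        X = np.column_stack([np.ones(len(y)), x, cov_all[ok]])
        fit = fit_logistic_irls(X, y)
        if not fit.estimable:
            rows.append(
                {**row, "odds_ratio": np.nan, "p_value": np.nan, "estimable": False}
            )
            continue
        b, se = fit.coef[1], fit.se[1]
        z = b / se
        rows.append(
            {
                **row,
                "odds_ratio": float(np.exp(b)),
                "p_value": float(2 * stats.norm.sf(abs(z))),
                "estimable": True,
            }
        )
    return pd.DataFrame(rows)


def _stratified_split(
    status: np.ndarray, rng: np.random.Generator, frac: float = 0.5
) -> np.ndarray:
    """Boolean mask for subset 1 of an incidence-preserving split."""
    mask = np.zeros(len(status), dtype=bool)
    for value in (0, 1):
        idx = np.flatnonzero(status == value)
        rng.shuffle(idx)
        take = int(round(frac * len(idx)))
        mask[idx[:take]] = True
    return mask


@dataclass
class PartitionTally:
    """Outcome of the repeated discovery/validation partition scheme."""

    n_partitions: int
    n_with_signal: int
    pass_counts: dict[str, int] = field(default_factory=dict)
    leading_variant: str | None = None
    leading_variant_share: float = float("nan")
    partition_hits: list[list[str]] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_partitions": self.n_partitions,
            "n_with_signal": self.n_with_signal,
            "leading_variant": self.leading_variant,
            "leading_variant_share": self.leading_variant_share,
            "pass_counts": dict(self.pass_counts),
        }


def partition_cv(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    variants: list[str] | None = None,
    status_column: str = "status",
    covariate_columns: tuple[str, ...] = ("age", "psa"),
    models: tuple[str, ...] = ASSOC_MODELS,
    n_partitions: int = 200,
    discovery_fdr: float = 0.20,
    validation_p: float = 0.05,
    split_fraction: float = 0.5,
    seed: int = 0,
    max_redraws: int = 20,
) -> PartitionTally:
    """Repeated incidence-preserving discovery/validation association.

    Each partition stratifies samples by lesion status into two halves.
    All (variant, model) pairs with non-constant coding are tested in the
    discovery half; a BH adjustment across those tests gates survivors at
    FDR <= ``discovery_fdr``.  Survivors are re-tested in the validation
    half and must reach P <= ``validation_p`` under the same model with a
    concordant effect direction.  A partition "has signal" when at least
    one variant passes both gates.
    """
    samples = genotypes.index.intersection(phenotypes.index)
    pheno = phenotypes.loc[samples]
    geno = genotypes.loc[samples]
    status = pheno[status_column].to_numpy(dtype=int)
    if status.sum() == 0:
        raise ValueError("phenotype incidence is zero")
    cov = pheno[list(covariate_columns)] if covariate_columns else None
    if variants is None:
        variants = list(geno.columns)
    rng = np.random.default_rng(seed)

    pass_counts: dict[str, int] = {v: 0 for v in variants}
    partition_hits: list[list[str]] = []
    n_signal = 0
    for _ in range(n_partitions):
        for _redraw in range(max_redraws):
            mask = _stratified_split(status, rng, split_fraction)
            if 0 < status[mask].sum() and 0 < status[~mask].sum():
                break
            log.info("partition_cv: redrawing a caseless partition")
        else:
            raise RuntimeError("could not draw a partition with cases in both halves")
        disc_idx = samples[mask]
        val_idx = samples[~mask]
        disc_rows = []
        for model in models:
            res = _assoc_subset(geno, pheno, disc_idx, variants, status_column,
                                cov, model)
            disc_rows.append(res)
        disc = pd.concat(disc_rows, ignore_index=True)
        tested = disc[disc["estimable"]].reset_index(drop=True)
        hits: list[str] = []
        if not tested.empty:
            fdr = multipletests(tested["p_value"], method="fdr_bh")[1]
            surv = tested[fdr <= discovery_fdr]
            for row in surv.itertuples(index=False):
                val = _assoc_subset(
                    geno, pheno, val_idx, [row.variant], status_column, cov, row.model
                )
                v = val.iloc[0]
                if not v["estimable"] or v["p_value"] > validation_p:
                    continue
                same_dir = (np.log(v["odds_ratio"]) > 0) == (
                    np.log(row.odds_ratio) > 0
                )
                if same_dir:
                    hits.append(row.variant)
        hits = sorted(set(hits))
        partition_hits.append(hits)
        if hits:
            n_signal += 1
            for v in hits:
                pass_counts[v] += 1
    leading = None
    share = float("nan")
    if n_signal > 0:
        leading = max(pass_counts, key=lambda v: (pass_counts[v], v))
        share = pass_counts[leading] / n_signal
    return PartitionTally(
        n_partitions=n_partitions,
        n_with_signal=n_signal,
        pass_counts=pass_counts,
        leading_variant=leading,
        leading_variant_share=share,
        partition_hits=partition_hits,
    )


def _assoc_subset(geno, pheno, idx, variants, status_column, cov, model):
    sub_geno = geno.loc[idx, variants]
    sub_status = pheno.loc[idx, status_column]
    sub_cov = cov.loc[idx] if cov is not None else None
    try:
        return logistic_assoc(sub_geno, sub_status, sub_cov, model=model)
    except ValueError:
        return pd.DataFrame(
            {
                "variant": variants,
                "model": model,
                "n_cases": 0,
                "n_controls": 0,
                "odds_ratio": np.nan,
                "p_value": np.nan,
                "estimable": False,
            }
        )


def genomic_burden(seg_table: pd.DataFrame, threshold: float = 0.15) -> pd.Series:
    """Per-sample fraction of the genome with |log2 tumor/normal| > threshold.

    ``seg_table`` columns: sample, length, log2_ratio (lengths in bases).
    The fraction is length-weighted; the threshold is strict.
    """
    if seg_table.empty:
        raise ValueError("empty segment table")
    if (seg_table["length"] <= 0).any():
        raise ValueError("segment lengths must be positive")
    df = seg_table.copy()
    df["hit"] = (df["log2_ratio"].abs() > threshold) * df["length"]
    grouped = df.groupby("sample")
    return grouped["hit"].sum() / grouped["length"].sum()


def burden_test(values: pd.Series, carrier: pd.Series) -> float:
    """Two-sided Mann-Whitney comparing burden between carriers and others."""
    idx = values.index.intersection(carrier.index)
    a = values.loc[idx][carrier.loc[idx].astype(bool)].to_numpy(dtype=float)
    b = values.loc[idx][~carrier.loc[idx].astype(bool)].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both genotype groups must be nonempty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _standardized_dosages(genotypes: pd.DataFrame) -> np.ndarray:
    """Variant-standardized dosage matrix ((x - 2f) / sqrt(2f(1-f)))."""
    g = genotypes.to_numpy(dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    f = np.nanmean(g, axis=0) / 2.0
    sd = np.sqrt(2.0 * f * (1.0 - f))
    keep = sd > 0
    z = (g[:, keep] - 2.0 * f[keep]) / sd[keep]
    return np.nan_to_num(z, nan=0.0)


def infer_ancestry(
    ref_genotypes: pd.DataFrame,
    ref_labels: pd.Series,
    target_genotypes: pd.DataFrame,
) -> pd.Series:
    """Assign ancestry labels by convex hulls in PC1-PC2 space.

    Reference and target genotypes (shared variant columns) are combined,
    variant-standardized and decomposed by PCA.  Each labeled reference
    group defines a convex hull in the first two components; a target
    inside exactly one hull takes that label, one inside several takes the
    label of the nearest group centroid, and one outside all hulls takes
    the label of the group with the nearest hull boundary (nearest
    reference point for degenerate groups).
    """
    shared = ref_genotypes.columns.intersection(target_genotypes.columns)
    if len(shared) < 2:
        raise ValueError("reference and targets share too few variants")
    counts = ref_labels.value_counts()
    if (counts < 3).any():
        raise ValueError("each reference group needs at least 3 samples")
    combined = pd.concat(
        [ref_genotypes[shared], target_genotypes[shared]], axis=0
    )
    z = _standardized_dosages(combined)
    z = z - z.mean(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    if (s > 1e-10).sum() < 2:
        raise ValueError("degenerate genotype matrix: PCA rank < 2")
    pcs = u[:, :2] * s[:2]
    n_ref = len(ref_genotypes)
    ref_pc = pcs[:n_ref]
    tgt_pc = pcs[n_ref:]

    hulls: dict[str, Polygon | None] = {}
    centroids: dict[str, np.ndarray] = {}
    points: dict[str, np.ndarray] = {}
    for grp in counts.index:
        pts = ref_pc[(ref_labels == grp).to_numpy()]
        points[grp] = pts
        centroids[grp] = pts.mean(axis=0)
        try:
            hull = ConvexHull(pts)
            hulls[grp] = Polygon(pts[hull.vertices])
        except QhullError:
            hulls[grp] = None  # collinear group: fall back to point distance

    labels = []
    for xy in tgt_pc:
        pt = Point(xy)
        inside = [g for g, poly in hulls.items() if poly is not None and poly.covers(pt)]
        if len(inside) == 1:
            labels.append(inside[0])
        elif len(inside) > 1:
            labels.append(
                min(inside, key=lambda g: float(np.linalg.norm(xy - centroids[g])))
            )
        else:
            def boundary_dist(g: str) -> float:
                poly = hulls[g]
                if poly is None:
                    return float(np.min(np.linalg.norm(points[g] - xy, axis=1)))
                return float(poly.exterior.distance(pt))

            labels.append(min(hulls, key=boundary_dist))
    return pd.Series(labels, index=target_genotypes.index, name="ancestry")
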