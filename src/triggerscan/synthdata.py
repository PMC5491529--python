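"""Synthetic fixtures with the statistical structure the pipeline assumes.

Every generator emulates one input of the trigger-variant analysis: a
genotyped cohort, a benign-tissue expression panel with planted per-genotype
additive effects, a case/control cohort with a planted dominant-model odds
ratio, a scored protein--protein interaction network with a planted connected
module, sequence windows with planted motif instances, and a binned Hi-C
signal vector with a planted high-contact link set.

All generators are deterministic functions of an explicit seed.  Per-entity
substreams are derived with :class:`numpy.random.SeedSequence` spawning, so
enlarging a simulation (more variants, more genes) never perturbs the draws
of earlier entities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "MISSING",
    "SimSpec",
    "gen_genotypes",
    "gen_expression",
    "gen_phenotypes",
    "gen_ppi",
    "gen_motif_background",
    "gen_hic_fixture",
]

#: sentinel for a missing genotype call, distinct from the dosages {0, 1, 2}
MISSING: int = -1

#: identifier of the planted trigger variant (first column of the matrix)
PLANTED_VARIANT = "var0000"


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for entity ``key`` under the root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic study.

    Defaults mirror the real study's scale: a 63-sample benign prostate
    expression panel, 300 candidate functional variants, a 539-patient tumor
    cohort with 12.1 % SPOP-mutant incidence and a dominant-model odds ratio
    of 4.83 at the planted variant, and a trigger gene complement of 14 DNA
    repair plus 15 hormone-regulated transcripts.
    """

    n_samples: int = 63
    n_variants: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_dnarep_genes: int = 180
    n_hormreg_genes: int = 330
    n_background_genes: int = 200
    n_planted_dnarep: int = 14
    n_planted_hormreg: int = 15
    eqtl_effect: float = -1.0
    baseline_expr: float = 5.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    planted_or: float = 4.83
    incidence: float = 0.121
    beta_age: float = 0.02
    beta_psa: float = 0.01
    covariate_spec: dict = field(
        default_factory=lambda: {
            "age_mean": 62.0,
            "age_sd": 8.0,
            "psa_mean": 8.0,
            "psa_sd": 4.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_samples",
            "n_variants",
            "n_dnarep_genes",
            "n_hormreg_genes",
            "n_background_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 < self.incidence < 1.0:
            raise ValueError("incidence must lie in (0, 1)")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def with_(self, **kwargs) -> "SimSpec":
        return replace(self, **kwargs)


def gen_genotypes(spec: SimSpec, n_samples: int | None = None) -> pd.DataFrame:
    """Draw a samples x variants minor-allele dosage matrix.

    Each variant's minor-allele frequency is uniform over ``spec.maf_range``
    and genotypes are Binomial(2, MAF), i.e. Hardy--Weinberg in expectation.
    Missing calls (rate ``spec.missing_rate``) are encoded as :data:`MISSING`.
    """
    n = spec.n_samples if n_samples is None else n_samples
    if n <= 0:
        raise ValueError("number of samples must be positive")
    lo, hi = spec.maf_range
    out = np.empty((n, spec.n_variants), dtype=np.int8)
    for j in range(spec.n_variants):
        rng = _substream(spec.seed, 0, j)
        maf = rng.uniform(lo, hi)
        g = rng.binomial(2, maf, size=n).astype(np.int8)
        if spec.missing_rate > 0:
            miss = rng.random(n) < spec.missing_rate
            g[miss] = MISSING
        out[:, j] = g
    samples = [f"s{i:04d}" for i in range(n)]
    variants = [f"var{j:04d}" for j in range(spec.n_variants)]
    return pd.DataFrame(out, index=samples, columns=variants)


def gen_expression(
    genotypes: pd.DataFrame, spec: SimSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples log2-scale expression panel.

    Planted genes (the first ``n_planted_dnarep`` DNA-repair and
    ``n_planted_hormreg`` hormone-regulated genes) follow

        expression = baseline + eqtl_effect * dosage(planted variant) + noise

    while all other genes are genotype-independent.  Returns the matrix and a
    gene table with columns ``gene``, ``gene_set`` (dnarep / hormreg /
    background), ``planted`` and ``true_effect``.
    """
    if genotypes.empty:
        raise ValueError("genotype matrix is empty")
    if PLANTED_VARIANT not in genotypes.columns:
        raise ValueError(f"planted variant {PLANTED_VARIANT!r} not in genotypes")
    dosage = genotypes[PLANTED_VARIANT].to_numpy(dtype=float)
    dosage = np.where(dosage == MISSING, np.nan, dosage)
    # missing planted-variant calls contribute baseline expression only
    dose_term = np.nan_to_num(dosage, nan=0.0)
    n = len(genotypes)

    names, sets, planted = [], [], []
    for i in range(spec.n_dnarep_genes):
        names.append(f"DNR{i:04d}")
        sets.append("dnarep")
        planted.append(i < spec.n_planted_dnarep)
    for i in range(spec.n_hormreg_genes):
        names.append(f"HRG{i:04d}")
        sets.append("hormreg")
        planted.append(i < spec.n_planted_hormreg)
    for i in range(spec.n_background_genes):
        names.append(f"BKG{i:04d}")
        sets.append("background")
        planted.append(False)

    values = np.empty((len(names), n))
    effects = np.zeros(len(names))
    for gi, is_planted in enumerate(planted):
        rng = _substream(spec.seed, 1, gi)
        noise = rng.normal(0.0, spec.noise_sd, size=n)
        mu = spec.baseline_expr
        if is_planted:
            effects[gi] = spec.eqtl_effect
            values[gi] = mu + spec.eqtl_effect * dose_term + noise
        else:
            values[gi] = mu + noise
    values = np.clip(values, 0.0, None)

    expr = pd.DataFrame(values, index=names, columns=genotypes.index)
    genes = pd.DataFrame(
        {
            "gene": names,
            "gene_set": sets,
            "planted": planted,
            "true_effect": effects,
        }
    ).set_index("gene")
    return expr, genes


def _calibrate_intercept(
    linpred_wo_intercept: np.ndarray, incidence: float
) -> float:
    """Intercept making the mean logistic probability equal ``incidence``."""

    def mean_prob(b0: float) -> float:
        return float(expit(b0 + linpred_wo_intercept).mean()) - incidence

    return brentq(mean_prob, -50.0, 50.0)


def gen_phenotypes(genotypes: pd.DataFrame, spec: SimSpec) -> pd.DataFrame:
    """Draw lesion status and covariates from a dominant-model logistic law.

    ``logit P(status=1) = b0 + log(planted_or) * carrier + b_age*age +
    b_psa*psa`` with the intercept calibrated so the mean prevalence equals
    ``spec.incidence``.  Carrier status refers to the planted variant's minor
    allele.  Returns a table with columns sample, age, psa, status.
    """
    if PLANTED_VARIANT not in genotypes.columns:
        raise ValueError(f"planted variant {PLANTED_VARIANT!r} not in genotypes")
    rng = _substream(spec.seed, 2)
    n = len(genotypes)
    cov = spec.covariate_spec
    age = np.clip(rng.normal(cov["age_mean"], cov["age_sd"], n), 30.0, None)
    psa = np.clip(rng.normal(cov["psa_mean"], cov["psa_sd"], n), 0.1, None)
    g = genotypes[PLANTED_VARIANT].to_numpy(dtype=float)
    carrier = (g >= 1).astype(float)  # missing (-1) treated as non-carrier
    lin = (
        np.log(spec.planted_or) * carrier
        + spec.beta_age * (age - cov["age_mean"])
        + spec.beta_psa * (psa - cov["psa_mean"])
    )
    b0 = _calibrate_intercept(lin, spec.incidence)
    status = (rng.random(n) < expit(b0 + lin)).astype(int)
    return pd.DataFrame(
        {"sample": genotypes.index, "age": age, "psa": psa, "status": status}
    ).set_index("sample")


def gen_ppi(
    n_nodes: int,
    planted_module_size: int,
    edge_prob: float = 0.01,
    module_density: float = 0.8,
    score_range: tuple[float, float] = (0.71, 1.0),
    seed: int = 0,
) -> tuple[nx.Graph, list[str]]:
    """Random scored PPI graph with one dense planted connected module.

    Background edges are Erdos--Renyi with probability ``edge_prob``; within
    the planted module each pair is additionally connected with probability
    ``module_density``.  Edge confidence scores are uniform on ``score_range``
    (above the conventional 0.7 retention cutoff).  Returns the graph and the
    planted-module node names.
    """
    if planted_module_size > n_nodes:
        raise ValueError("planted_module_size cannot exceed n_nodes")
    rng = _substream(seed, 3)
    names = [f"G{i:05d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    iu, ju = np.triu_indices(n_nodes, k=1)
    take = rng.random(iu.size) < edge_prob
    for a, b in zip(iu[take], ju[take]):
        g.add_edge(names[a], names[b])
    module = names[:planted_module_size]
    for x in range(planted_module_size):
        for y in range(x + 1, planted_module_size):
            if rng.random() < module_density:
                g.add_edge(module[x], module[y])
    lo, hi = score_range
    for a, b in g.edges:
        g.edges[a, b]["score"] = float(rng.uniform(lo, hi))
        g.edges[a, b]["source"] = "synthetic"
    return g, module


def gen_motif_background(
    pwm_probs: np.ndarray,
    n: int,
    planted_fraction: float,
    length: int = 61,
    seed: int = 0,
) -> pd.DataFrame:
    """Random sequences, a fraction carrying the PWM consensus.

    ``pwm_probs`` is a (motif length, 4) probability matrix over A,C,G,T.
    Returns a table with columns ``name``, ``seq``, ``plant_pos`` (-1 when no
    motif was planted).
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must lie in [0, 1]")
    motif_len = pwm_probs.shape[0]
    if length < motif_len:
        raise ValueError("sequence length shorter than the motif")
    rng = _substream(seed, 4)
    bases = np.array(list("ACGT"))
    consensus = "".join(bases[pwm_probs.argmax(axis=1)])
    rows = []
    for i in range(n):
        seq = rng.choice(bases, size=length)
        pos = -1
        if rng.random() < planted_fraction:
            pos = int(rng.integers(0, length - motif_len + 1))
            seq[pos : pos + motif_len] = list(consensus)
        rows.append({"name": f"seq{i:05d}", "seq": "".join(seq), "plant_pos": pos})
    return pd.DataFrame(rows)


def gen_hic_fixture(
    n_bins: int,
    link_fraction: float,
    concordant_effect: float,
    bin_size: int = 40_000,
    chrom: str = "chr7",
    noise_scale: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binned Hi-C contact vector plus a paired expression fold-change table.

    The contact signal is exponential (heavy right tail).  The top
    ``link_fraction`` of bins are designated planted links; one gene per bin
    receives |log2 fold change| inflated by ``concordant_effect`` when its
    bin is a planted link.  Returns (signal table, fold-change table).
    """
    if not 0.0 < link_fraction < 1.0:
        raise ValueError("link_fraction must lie in (0, 1)")
    rng = _substream(seed, 5)
    signal = rng.exponential(1.0, size=n_bins)
    order = np.argsort(signal)
    n_links = max(1, int(round(link_fraction * n_bins)))
    link_idx = order[-n_links:]
    is_link = np.zeros(n_bins, dtype=bool)
    is_link[link_idx] = True

    starts = np.arange(n_bins) * bin_size
    bins = pd.DataFrame(
        {
            "bin": [f"bin{i:04d}" for i in range(n_bins)],
            "chrom": chrom,
            "start": starts,
            "end": starts + bin_size,
            "signal": signal,
            "planted_link": is_link,
        }
    )
    base = np.abs(rng.normal(0.0, noise_scale, size=n_bins))
    lfc = base + np.where(is_link, concordant_effect, 0.0)
    sign = rng.choice([-1.0, 1.0], size=n_bins)
    genes = pd.DataFrame(
        {
            "gene": [f"CH7G{i:04d}" for i in range(n_bins)],
            "bin": bins["bin"],
            "tss": starts + bin_size // 2,
            "log2_ratio": sign * lfc,
        }
    )
    return bins, genes
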