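import numpy as np
import pytest

from triggerscan import synthdata as sd
from triggerscan import trigger


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale study: strong planted eQTL effect confined to var0000."""
    return sd.SimSpec(
        n_variants=20,
        n_dnarep_genes=30,
        n_hormreg_genes=40,
        n_background_genes=20,
        n_planted_dnarep=14,
        n_planted_hormreg=15,
        eqtl_effect=-2.0,
        noise_sd=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_spec):
    geno = sd.gen_genotypes(small_spec)
    expr, genes = sd.gen_expression(geno, small_spec)
    gene_sets = {
        "dnarep": set(genes.index[genes["gene_set"] == "dnarep"]),
        "hormreg": set(genes.index[genes["gene_set"] == "hormreg"]),
    }
    return geno, expr, genes, gene_sets


@pytest.fixture(scope="session")
def small_scan(small_panel):
    geno, expr, genes, gene_sets = small_panel
    transcripts = trigger.eligible_transcripts(expr, gene_sets)
    return trigger.eqtl_scan(expr, geno, transcripts=transcripts)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
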