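import numpy as np
import pandas as pd
import pytest

from lethaldyn import AssayDesign, SyntheticScreenConfig
from lethaldyn.screen import NONTARGETING, CountMatrix


@pytest.fixture(scope="session")
def design():
    return AssayDesign()


@pytest.fixture(scope="session")
def small_screen_config():
    """A screen small enough for fast unit tests but above the pseudo-gene
    and non-targeting preconditions."""
    return SyntheticScreenConfig(n_genes=120, n_nontargeting=240, seed=7)


def toy_count_matrix(n_genes=10, guides_per_gene=3, n_nt=60, base=100,
                     conditions=("T0", "untreated", "treated"), n_rep=2):
    """Deterministic toy matrix: every count equal to ``base``."""
    genes = [f"G{i}" for i in range(n_genes)]
    ids = [f"sg_{g}_{k}" for g in genes for k in range(guides_per_gene)]
    ids += [f"sg_NT_{i}" for i in range(n_nt)]
    gene_col = [g for g in genes for _ in range(guides_per_gene)] + [NONTARGETING] * n_nt
    samples = [f"{c}_r{r}" for c in conditions for r in range(1, n_rep + 1)]
    counts = pd.DataFrame(base, index=pd.Index(ids, name="sgRNA"), columns=samples)
    guides = pd.DataFrame({
        "gene": gene_col,
        "is_nontargeting": [g == NONTARGETING for g in gene_col],
        "is_mirna": False,
    }, index=counts.index)
    sheet = pd.DataFrame({
        "sample_id": samples,
        "condition": [s.rsplit("_r", 1)[0] for s in samples],
        "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
    }).set_index("sample_id")
    return CountMatrix(counts=counts, guides=guides, samples=sheet)


@pytest.fixture
def toy_cm():
    return toy_count_matrix()
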