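import numpy as np
import pandas as pd
import pytest

from rankmeta import ExpressionStudy, SimConfig, simulate_multistudy


def make_study(values, groups, study_id="toy", genes=None):
    """Build an ExpressionStudy from a nested list (genes x samples)."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"s{i + 1}" for i in range(n_samples)]
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    grp = pd.Series(list(groups), index=samples, name="group")
    return ExpressionStudy(study_id=study_id, matrix=matrix, groups=grp)


@pytest.fixture(scope="session")
def planted_studies():
    """Four small studies with a strong planted signal, plus ground truth."""
    cfg = SimConfig(n_genes=400, n_studies=4, frac_de=0.05, effect_lfc=2.0,
                    attenuation=0.9, noise_sd=0.5, platform_coverage=0.9, seed=11)
    return simulate_multistudy(cfg)


@pytest.fixture(scope="session")
def null_studies():
    """Four small studies with no signal at all."""
    cfg = SimConfig(n_genes=400, n_studies=4, frac_de=0.0, noise_sd=0.5,
                    platform_coverage=0.9, seed=12)
    studies, _ = simulate_multistudy(cfg)
    return studies
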