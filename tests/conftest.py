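import numpy as np
import pytest

from hist2rna.stain import StainMatrix
from hist2rna.synthetic import hne_like_concentrations, make_cohort, make_stain_image


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(n_patients=20, patches_per_patient=6, n_features=16,
                       n_genes=8, noise_sd=0.1, seed=3)


@pytest.fixture(scope="session")
def stain_basis():
    return StainMatrix.from_columns((0.6, 0.7, 0.3), (0.1, 0.95, 0.2))


@pytest.fixture(scope="session")
def hne_image(stain_basis):
    rng = np.random.default_rng(0)
    conc = hne_like_concentrations((64, 64), rng)
    return make_stain_image(stain_basis, conc, background=245), conc
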