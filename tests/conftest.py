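import numpy as np
import pytest

import redifine as rd

# Reference condensate: a fully disordered protein forming ~1.2 um droplets
# holding three quarters of the protein, with a slow (~1 /s) interphase
# exchange -- the regime the method was designed for.
FUS_LIKE = dict(
    D_dil=8.0e-11, D_cond=8.9e-13, nu_cond=0.753, R_drop=1.21e-6, p=0.405e-6
)

# Reference soluble complex: a high-affinity protein-RNA pair in intermediate
# exchange, where decay curves are exchange-averaged.
COMPLEX_LIKE = dict(D_free=1.0e-10, D_complex=4.0e-11, nu_complex=0.945, k_off=1.41)


@pytest.fixture(scope="session")
def condensate_params() -> rd.CondensateParams:
    return rd.CondensateParams(**FUS_LIKE)


@pytest.fixture(scope="session")
def binding_params() -> rd.BindingParams:
    return rd.BindingParams(**COMPLEX_LIKE)


@pytest.fixture(scope="session")
def protein_scheme() -> rd.AcquisitionScheme:
    return rd.default_scheme("protein")


@pytest.fixture(scope="session")
def binding_scheme() -> rd.AcquisitionScheme:
    # folded-domain acquisition: shorter gradients, Delta capped at 700 ms
    return rd.AcquisitionScheme(
        gradient_fractions=tuple(np.linspace(0.02, 0.95, 16)),
        diffusion_times=(0.05, 0.1, 0.2, 0.35, 0.5, 0.7),
        gradient_duration=9e-3,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(condensate_params, protein_scheme) -> rd.DecayDataset:
    return rd.generate_dataset(condensate_params, protein_scheme)


@pytest.fixture(scope="session")
def noiseless_binding_dataset(binding_params, binding_scheme) -> rd.DecayDataset:
    return rd.generate_dataset(binding_params, binding_scheme)
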