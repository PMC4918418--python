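import numpy as np
import pytest

from mutselhet.genetic_code import build_genetic_code, codon_averaged_k80


@pytest.fixture(scope="session")
def code():
    return build_genetic_code("standard")


@pytest.fixture(scope="session")
def mutation():
    """K80 (kappa=2) codon-averaged mutation model with uniform codon usage."""
    return codon_averaged_k80(2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_profiles(rng, n, alpha=0.5):
    """Strictly positive random profiles, Dirichlet(alpha) per site."""
    P = rng.dirichlet(np.full(20, alpha), size=n)
    P = P + 1e-8
    return P / P.sum(axis=1, keepdims=True)
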