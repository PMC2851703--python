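import numpy as np
import pytest
from scipy.stats import norm


@pytest.fixture(scope="session")
def grid_oracle():
    """Brute-force maximizer of the least-favorable marginal densities.

    Dense grid search (step 1e-4 over [0, 20]) standing in for the 1-D
    optimizer inside the Berger-Sellke bounds.
    """

    grid = np.arange(1e-4, 20.0, 1e-4)

    def oracle(z: float, family: str) -> float:
        if family == "symmetric":
            marginal = 0.5 * (norm.pdf(z - grid) + norm.pdf(z + grid))
        elif family == "unimodal":
            marginal = (norm.cdf(grid - z) - norm.cdf(-grid - z)) / (2.0 * grid)
        else:
            raise ValueError(family)
        return float(norm.pdf(z) / max(marginal.max(), norm.pdf(z)))

    return oracle
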