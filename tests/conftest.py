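import numpy as np
import pytest

from mnapport.simulate import GeneratorConfig, fixture_tiny, generate_survey


@pytest.fixture(scope="session")
def tiny():
    """Hand-written miniature survey (deterministic, no RNG)."""
    return fixture_tiny()


@pytest.fixture(scope="session")
def survey():
    """One default-condition synthetic survey, shared across tests."""
    return generate_survey(GeneratorConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def lmg_shares_by_enumeration(X, y):
    """Independent LMG oracle: explicit average of sequential R^2 gains
    over all p! predictor orderings, with R^2 from a direct OLS fit per
    subset (no shared code with the production path beyond numpy)."""
    from itertools import permutations

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape

    def r2(cols):
        if not cols:
            return 0.0
        A = np.column_stack([np.ones(n), X[:, list(cols)]])
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        tss = float(((y - y.mean()) ** 2).sum())
        return 1.0 - float((resid ** 2).sum()) / tss

    shares = np.zeros(p)
    orders = list(permutations(range(p)))
    for order in orders:
        prev = 0.0
        used = []
        for k in order:
            used.append(k)
            cur = r2(used)
            shares[k] += cur - prev
            prev = cur
    return shares / len(orders)
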