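import numpy as np
import pytest

from evoscape.competition_fitness import CompetitionTimeSeries, SelectionEstimate


def make_estimate(s, se=0.0, normalized=True, **kw):
    """SelectionEstimate with a symmetric 1.96*se CI around s."""
    return SelectionEstimate(
        s=s, se=se, ci95=(s - 1.96 * se, s + 1.96 * se), normalized=normalized, **kw
    )


def linear_series(s, n=12, intercept=0.0, noise_sd=0.0, rng=None, replicate="rep1"):
    """Series whose log ratio is intercept + s*g (+ optional gaussian noise)."""
    g = np.arange(n, dtype=float)
    y = intercept + s * g
    if noise_sd:
        y = y + (rng or np.random.default_rng(0)).normal(0.0, noise_sd, n)
    ref = np.full(n, 10_000.0)
    return CompetitionTimeSeries(replicate, g, ref * np.exp(y), ref)


@pytest.fixture
def rse_table():
    """The paradigm reciprocal-sign-epistasis two-locus table."""
    return [("00", 1.0), ("10", 1.2), ("01", 1.3), ("11", 0.8)]
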