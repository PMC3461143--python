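"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pytest
from scipy.special import gammaln


def zippin_grid_oracle(catches, n_max=5000):
    """Exhaustive integer-abundance maximisation of the removal likelihood.

    For every candidate abundance N the capture probability is set to its
    conditional maximiser p(N) = T/(T + X + k(N - T)) (stationarity of the
    log-likelihood in p), and the profile is scanned over the full integer
    range. Returns (N, p, interior) where ``interior`` is False when the
    maximum sits on the upper grid bound (no finite ML within range).
    """
    c = np.asarray(catches, dtype=np.int64)
    k = c.size
    total = int(c.sum())
    x = int(np.arange(k) @ c)
    ns = np.arange(total, n_max + 1)
    p = total / (total + x + k * (ns - total))
    q = 1.0 - p
    tail = x + k * (ns - total)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = (
            gammaln(ns + 1.0) - gammaln(ns - total + 1.0) - gammaln(c + 1.0).sum()
            + total * np.log(p)
            + np.where(tail > 0, tail * np.log(np.where(q > 0, q, 1.0)), 0.0)
        )
    i = int(np.argmax(loglik))
    return int(ns[i]), float(p[i]), i < ns.size - 1


def flat_poisson_loglik(catches):
    """N -> infinity limit of the removal profile likelihood: iid Poisson
    catches with equal per-pass rate T/k."""
    c = np.asarray(catches, dtype=float)
    total = c.sum()
    k = c.size
    return float(total * np.log(total / k) - total - gammaln(c + 1.0).sum())


@pytest.fixture(scope="session")
def zippin_oracle():
    return zippin_grid_oracle


@pytest.fixture(scope="session")
def default_life_history():
    """Maturation curve, survival schedule and fecundity model matching the
    package defaults (seasonal moments calibrated to the three-season
    averages: males k=3.5, V=74.5; females k=2.0, V=14.1)."""
    import ebreeders as eb

    curve = eb.maturation_from_proportions(
        np.arange(3, 9), [0.10, 0.30, 0.60, 0.85, 0.95, 1.0])
    survival = eb.SurvivalSchedule.flat(0.5)
    fecundity = eb.SeasonalFecundityModel.seasonal_default()
    return curve, survival, fecundity
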