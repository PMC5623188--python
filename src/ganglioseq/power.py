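"""Power and sample size for two-group RNA-seq differential expression.

The closed form follows the coverage/CV convention of RNA-seq power
calculators: for sequencing depth mu (expected counts per gene), biological
coefficient of variation cv, fold change Delta and n replicates per group,
the per-gene log-ratio statistic has approximate variance
``2 * (1/mu + cv**2) / n``, giving

    power = Phi( sqrt( n * ln(Delta)**2 / (2 * (1/mu + cv**2)) ) - z_{1-alpha/2} )

for a two-sided normal test of size alpha (no multiple-testing adjustment).
:func:`monte_carlo_power` provides an independent simulation-based estimate
of the same quantity for verification.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .errors import ValidationError


def _check_common(depth: float, cv: float, effect: float, alpha: float) -> None:
    if depth <= 0:
        raise ValidationError("depth must be positive")
    if cv < 0:
        raise ValidationError("cv must be non-negative")
    if effect <= 0:
        raise ValidationError("effect (fold change) must be positive")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")


def de_power(depth: float, cv: float, effect: float, n: int, alpha: float = 0.05) -> float:
    """Power to detect a fold change of ``effect`` with ``n`` replicates per
    group at two-sided size ``alpha``.

    In the null limit ``effect -> 1`` the value tends to ``alpha / 2`` (the
    one-sided rejection mass of a two-sided test approximated on the favored
    side).
    """
    _check_common(depth, cv, effect, alpha)
    if n < 1:
        raise ValidationError("n must be a positive integer")
    z_crit = stats.norm.ppf(1 - alpha / 2)
    ncp = math.sqrt(n * math.log(effect) ** 2 / (2 * (1 / depth + cv**2)))
    return float(stats.norm.cdf(ncp - z_crit))


def de_sample_size(
    depth: float, cv: float, effect: float, alpha: float = 0.05, power: float = 0.8
) -> int:
    """Smallest replicates-per-group n with ``de_power(...) >= power``."""
    _check_common(depth, cv, effect, alpha)
    if not (alpha < power < 1):
        raise ValidationError("target power must lie in (alpha, 1)")
    if effect == 1:
        raise ValidationError("power cannot exceed alpha/2 at effect = 1")
    z_crit = stats.norm.ppf(1 - alpha / 2)
    z_pow = stats.norm.ppf(power)
    n = max(
        1,
        math.ceil(2 * (z_crit + z_pow) ** 2 * (1 / depth + cv**2) / math.log(effect) ** 2),
    )
    # The ceiling already satisfies the bound; walk down to the smallest n.
    while n > 1 and de_power(depth, cv, effect, n - 1, alpha) >= power:
        n -= 1
    return int(n)


def monte_carlo_power(
    depth: float,
    cv: float,
    effect: float,
    n: int,
    alpha: float = 0.05,
    n_genes: int = 5000,
    seed: int = 0,
) -> float:
    """Simulation estimate of :func:`de_power` under the same model.

    Draws ``n_genes`` independent genes with NB counts and dispersion
    ``cv**2``, the fold change split symmetrically around the nominal depth
    (group means ``depth / sqrt(effect)`` and ``depth * sqrt(effect)``, so
    ``depth`` is the geometric-mean expression of the two groups — the same
    convention the count simulator uses for its DE classes). Forms the Wald
    statistic ``ln(mB/mA) / sqrt((1/mA + cv^2)/n + (1/mB + cv^2)/n)`` from
    the sample means and returns the two-sided rejection fraction.
    """
    _check_common(depth, cv, effect, alpha)
    rng = np.random.default_rng(seed)
    disp = cv**2

    def draw(mean: float) -> np.ndarray:
        if disp == 0:
            return rng.poisson(mean, size=(n_genes, n))
        r = 1.0 / disp
        return rng.negative_binomial(r, r / (r + mean), size=(n_genes, n))

    half = math.sqrt(effect)
    m_a = draw(depth / half).mean(axis=1)
    m_b = draw(depth * half).mean(axis=1)
    ok = (m_a > 0) & (m_b > 0)
    se = np.sqrt((1 / m_a[ok] + disp) / n + (1 / m_b[ok] + disp) / n)
    z = np.log(m_b[ok] / m_a[ok]) / se
    z_crit = stats.norm.ppf(1 - alpha / 2)
    return float(np.mean(np.abs(z) > z_crit))
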