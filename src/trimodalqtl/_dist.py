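"""Count-distribution log densities used inside the samplers.

Written in gammaln form for speed in tight MCMC loops; unit tests pin them
against scipy.stats.nbinom / scipy.stats.betabinom.

Parameterisations (shared with the synthetic generators):
  negative binomial: mean mu, variance mu + mu^2/phi  (phi = size/dispersion)
  beta-binomial:     mean fraction pi, concentration theta; a = pi*theta,
                     b = (1-pi)*theta
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def nb_logpmf(c, mu, phi):
    """log NB(c | mean mu, overdispersion phi), variance mu + mu^2/phi."""
    c = np.asarray(c, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return (
        gammaln(c + phi)
        - gammaln(phi)
        - gammaln(c + 1.0)
        + phi * np.log(phi / (phi + mu))
        + c * np.log(mu / (phi + mu))
    )


def betabinom_logpmf(k, n, pi, theta):
    """log BetaBinomial(k | n, a=pi*theta, b=(1-pi)*theta)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    a = pi * theta
    b = (1.0 - pi) * theta
    return (
        gammaln(n + 1.0)
        - gammaln(k + 1.0)
        - gammaln(n - k + 1.0)
        + gammaln(k + a)
        + gammaln(n - k + b)
        - gammaln(n + a + b)
        + gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
    )
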