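"""Small stable numeric primitives shared across modules."""

from __future__ import annotations

import numpy as np

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, float)))


def softplus(x):
    x = np.asarray(x, float)
    return np.logaddexp(0.0, x)


def bernoulli_loglik(y, logit):
    """Generalized Bernoulli log-mass; fractional targets in [0, 1] allowed."""
    return y * logit - softplus(logit)


def normal_logpdf(x, loc=0.0, scale=1.0):
    z = (np.asarray(x, float) - loc) / scale
    return -0.5 * z * z - np.log(scale) - _LOG_SQRT_2PI


def halfnormal_logpdf(x, scale=1.0):
    x = np.asarray(x, float)
    out = np.where(
        x < 0,
        -np.inf,
        np.log(2.0) - 0.5 * (x / scale) ** 2 - np.log(scale) - _LOG_SQRT_2PI,
    )
    return out


def gauss_hermite(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilists' Gauss-Hermite rule: nodes z and weights summing to 1,
    exact for polynomials against the standard normal density."""
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / w.sum()
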