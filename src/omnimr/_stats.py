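"""Log-space normal tail utilities.

GWAS p-values routinely reach magnitudes like 1e-32, and two-sided tail
areas computed naively as ``2 * (1 - cdf(z))`` lose all precision long
before that.  Every p-value <-> z-score conversion in the package goes
through the log-space functions here (`scipy.special.log_ndtr` /
`ndtri_exp`), which stay accurate far beyond the double-underflow limit.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtri_exp

_LOG2 = np.log(2.0)

#: 97.5% standard-normal quantile used for 95% Wald intervals.
Z_975: float = float(-ndtri_exp(np.log(0.025)))


def log_p_from_z(z):
    """Natural log of the two-sided normal p-value for z-score(s) ``z``."""
    z = np.asarray(z, dtype=float)
    return _LOG2 + log_ndtr(-np.abs(z))


def p_from_z(z):
    """Two-sided normal p-value; underflows to 0.0 only below ~1e-308."""
    return np.exp(log_p_from_z(z))


def z_from_p(p=None, *, log_p=None):
    """|z| whose two-sided normal tail area equals ``p``.

    Accepts either ``p`` or its natural log; the log path is exact for
    arbitrarily small tail areas.
    """
    if log_p is None:
        if p is None:
            raise ValueError("provide p or log_p")
        log_p = np.log(np.asarray(p, dtype=float))
    return -ndtri_exp(np.asarray(log_p, dtype=float) - _LOG2)
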