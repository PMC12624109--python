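"""Methylation scale transforms.

Array methylation is reported as a beta value (the methylated fraction of a
CpG, in (0,1)) or as an M-value, its base-2 logit.  Beta values are bounded
and heteroscedastic near 0 and 1; M-values are unbounded and closer to
homoscedastic, so statistical testing is done on M-values while effect
directions and summaries are reported on the beta scale.  The two are linked
by a strictly monotone bijection, so directions agree between scales.
"""

from __future__ import annotations

import numpy as np

__all__ = ["m_to_beta", "beta_to_m"]


def m_to_beta(m):
    """Map M-values to beta values: beta = 2^m / (2^m + 1).

    Accepts scalars or arrays; inputs must be finite.
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("M-values must be finite")
    # expit(m * ln 2) == 2^m / (2^m + 1), numerically stable for large |m|
    from scipy.special import expit

    out = expit(m * np.log(2.0))
    return out if out.ndim else float(out)


def beta_to_m(beta):
    """Map beta values to M-values: m = log2(beta / (1 - beta)).

    Beta values must lie strictly inside (0, 1).
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all((beta > 0.0) & (beta < 1.0)):
        raise ValueError("beta values must lie strictly inside (0, 1)")
    out = np.log2(beta / (1.0 - beta))
    return out if out.ndim else float(out)
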