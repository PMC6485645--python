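"""Statistical helpers for phenotype endpoints.

Currently the maximum-likelihood polyserial correlation: the association
between a continuous trait (e.g. a patient's LAI) and an ordinal trait
(e.g. a binned metastasis count) under a latent bivariate-normal model in
which the ordinal variable arises by thresholding a latent normal.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = ["polyserial_correlation"]


def polyserial_correlation(continuous, ordinal) -> float:
    """Maximum-likelihood polyserial correlation coefficient.

    ``continuous`` is a numeric sample; ``ordinal`` gives ordered category
    labels (any sortable values).  The continuous margin is normal with
    moments estimated by ML; the thresholds of the latent normal behind the
    ordinal margin are estimated from the category frequencies; the
    correlation ``rho`` of the latent bivariate normal is then found by
    maximizing the conditional likelihood of the observed categories given
    the continuous values.  Returns a value in (-1, 1), or NaN (with a
    warning) when the ordinal variable is degenerate.
    """
    x = np.asarray(continuous, dtype=float)
    o = np.asarray(ordinal)
    if x.shape != o.shape or x.ndim != 1:
        raise ValueError("continuous and ordinal must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    levels, codes = np.unique(o, return_inverse=True)
    if levels.size < 2:
        warnings.warn("ordinal variable has a single occupied level; polyserial undefined")
        return float("nan")

    props = np.bincount(codes) / codes.size
    tau = norm.ppf(np.cumsum(props)[:-1])
    upper = np.concatenate([tau, [np.inf]])[codes]
    lower = np.concatenate([[-np.inf], tau])[codes]
    z = (x - x.mean()) / max(x.std(), 1e-12)

    def negll(rho: float) -> float:
        s = np.sqrt(1.0 - rho * rho)
        p = norm.cdf((upper - rho * z) / s) - norm.cdf((lower - rho * z) / s)
        return -float(np.sum(np.log(np.maximum(p, 1e-300))))

    res = minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)
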