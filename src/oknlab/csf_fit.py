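"""Log-parabola contrast-sensitivity-function fitting.

Contrast sensitivity as a function of spatial frequency is modelled as a
downward parabola in double-log coordinates,

    log10 CS(SF) = log10(gamma_max)
                   - log10(2) * ((log10 SF - log10 SF_max) / (beta / 2))^2,

with peak sensitivity ``gamma_max``, peak spatial frequency ``SF_max`` (cpd)
and bandwidth ``beta`` in log10-cpd units: at one half-bandwidth from the
peak the linear sensitivity is halved.  Fitting and the coefficient of
determination are computed in log10-sensitivity space, which is also where
the measurement noise of threshold estimates is approximately homogeneous.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError

__all__ = ["CSFParams", "logparabola", "fit_csf"]

LOG10_2 = math.log10(2.0)


@dataclass
class CSFParams:
    """Log-parabola CSF parameters with goodness of fit."""

    gamma_max: float   # peak sensitivity (linear units)
    sf_max: float      # peak spatial frequency, cpd
    beta: float        # bandwidth, log10-cpd units
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.gamma_max <= 0 or self.sf_max <= 0 or self.beta <= 0:
            raise ValueError("CSF parameters must be positive")

    def sensitivity(self, sf: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Linear contrast sensitivity at ``sf``."""
        out = 10.0 ** logparabola(sf, self)
        return out

    def curve(self, sf: np.ndarray) -> np.ndarray:
        return np.asarray(self.sensitivity(np.asarray(sf, dtype=float)))


def logparabola(
    sf: Union[float, np.ndarray], params: CSFParams
) -> Union[float, np.ndarray]:
    """log10 sensitivity of the log-parabola model at spatial frequency ``sf``.

    Maximum ``log10(gamma_max)`` at ``sf = sf_max``; symmetric in log10 sf
    about the peak; the value drops by ``log10(2)`` at
    ``|log10 sf - log10 sf_max| = beta / 2``.
    """
    sfa = np.asarray(sf, dtype=float)
    if np.any(sfa <= 0) or np.any(~np.isfinite(sfa)):
        raise ValueError("spatial frequency must be positive and finite")
    val = math.log10(params.gamma_max) - LOG10_2 * (
        (np.log10(sfa) - math.log10(params.sf_max)) / (params.beta / 2.0)
    ) ** 2
    return float(val) if np.isscalar(sf) else val


def fit_csf(
    sf: Sequence[float],
    cs: Sequence[float],
    sf_max_bounds: Optional[Tuple[float, float]] = None,
) -> CSFParams:
    """Least-squares log-parabola fit in log10-sensitivity space.

    Requires at least four points.  Initialization is the empirical peak;
    ``sf_max`` is bounded to ``[min sf / 2, max sf * 2]`` by default.  The
    returned ``r2`` is ``1 - SS_res / SS_tot`` in log10 space; degenerate
    identical-CS input yields ``r2 = 0`` (by the SS_tot = 0 convention)
    with a warning.
    """
    sf = np.asarray(sf, dtype=float)
    cs = np.asarray(cs, dtype=float)
    if sf.size != cs.size:
        raise ValueError("sf and cs must have equal length")
    if sf.size < 4:
        raise InsufficientDataError(
            f"log-parabola fit needs >=4 points, got {sf.size}"
        )
    if np.any(sf <= 0) or np.any(cs <= 0):
        raise ValueError("sf and cs must be positive")

    logsf = np.log10(sf)
    logcs = np.log10(cs)
    if sf_max_bounds is None:
        sf_max_bounds = (float(sf.min()) / 2.0, float(sf.max()) * 2.0)

    i_peak = int(np.argmax(logcs))
    x0 = np.array(
        [
            logcs[i_peak],                      # log10 gamma_max
            np.clip(
                logsf[i_peak],
                math.log10(sf_max_bounds[0]),
                math.log10(sf_max_bounds[1]),
            ),                                  # log10 sf_max
            2.0,                                # beta
        ]
    )

    def residuals(theta):
        lg, lsf, beta = theta
        return (
            lg - LOG10_2 * ((logsf - lsf) / (beta / 2.0)) ** 2 - logcs
        )

    res = least_squares(
        residuals,
        x0,
        bounds=(
            [-3.0, math.log10(sf_max_bounds[0]), 1e-3],
            [7.0, math.log10(sf_max_bounds[1]), 50.0],
        ),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    lg, lsf, beta = res.x
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((logcs - logcs.mean()) ** 2))
    if ss_tot <= 1e-30:
        warnings.warn(
            "flat sensitivity data: r2 reported as 0 (SS_tot = 0 convention)",
            stacklevel=2,
        )
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return CSFParams(
        gamma_max=10.0 ** float(lg),
        sf_max=10.0 ** float(lsf),
        beta=float(beta),
        r2=r2,
    )
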