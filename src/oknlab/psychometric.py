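"""Cumulative-Weibull psychometric model: evaluation, maximum-likelihood
fitting, and threshold/sensitivity conversions.

The parametrization places the threshold ``m`` and the width ``w`` in the
natural-log space of the stimulus level ``x`` (a Michelson contrast
fraction):

    Psi(x; m, w, gamma, lambda) =
        gamma + (1 - lambda - gamma) * (1 - exp(log(0.5) * exp(c*(log x - m)/w)))

with the constant ``c = log(-log 0.05) - log(-log 0.95)``.  Under this
parametrization ``Psi(e^m) = 0.5`` when the guess rate ``gamma`` and lapse
rate ``lambda`` are zero, ``w`` is exactly the log-contrast span between the
0.05 and 0.95 points, and the slope is ``s = c / w``.  The contrast
threshold is ``CT = e^m`` and contrast sensitivity ``CS = 1 / CT``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import InsufficientDataError

__all__ = [
    "C_WEIBULL",
    "PsychometricParams",
    "OutcomeTable",
    "weibull_psi",
    "fit_psychometric",
    "PsychometricFit",
    "threshold_to_cs",
    "width_to_slope",
    "slope_to_width",
]

#: c = log(-log 0.05) - log(-log 0.95), the width normalization constant
C_WEIBULL: float = math.log(-math.log(0.05)) - math.log(-math.log(0.95))

LOG_HALF = math.log(0.5)


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters (m, w, guess, lapse) of the cumulative Weibull."""

    m: float                    # log contrast threshold (natural log)
    w: float                    # width, log-contrast units (0.05..0.95 span)
    gamma_guess: float = 0.0
    lambda_lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("width w must be positive")
        if not (0 <= self.gamma_guess and 0 <= self.lambda_lapse
                and self.gamma_guess + self.lambda_lapse < 1):
            raise ValueError("invalid asymptote parameters")

    @property
    def slope(self) -> float:
        """Weibull slope s = c / w."""
        return C_WEIBULL / self.w

    @property
    def ct(self) -> float:
        """Contrast threshold CT = e^m (50% point for zero asymptotes)."""
        return math.exp(self.m)

    @property
    def cs(self) -> float:
        """Contrast sensitivity CS = 1 / CT."""
        return 1.0 / self.ct

    def quantile(self, p: float) -> float:
        """Log-contrast at which Psi = p (zero-asymptote inverse)."""
        if not 0 < p < 1:
            raise ValueError("p must be in (0, 1)")
        return self.m + (self.w / C_WEIBULL) * math.log(
            math.log(1.0 - p) / LOG_HALF
        )


def weibull_psi(
    x: Union[float, np.ndarray],
    params: Optional[PsychometricParams] = None,
    *,
    m: Optional[float] = None,
    w: Optional[float] = None,
    gamma_guess: float = 0.0,
    lambda_lapse: float = 0.0,
) -> Union[float, np.ndarray]:
    """Probability of a positive (OKN "seen") response at contrast ``x``.

    Accepts either a :class:`PsychometricParams` or keyword ``m``/``w``.
    ``x`` must be positive (contrast fraction); raises ``ValueError``
    otherwise.
    """
    if params is not None:
        m, w = params.m, params.w
        gamma_guess, lambda_lapse = params.gamma_guess, params.lambda_lapse
    if m is None or w is None:
        raise TypeError("provide params or both m and w")
    xa = np.asarray(x, dtype=float)
    if np.any(xa <= 0) or np.any(~np.isfinite(xa)):
        raise ValueError("contrast x must be positive and finite")
    z = np.exp(C_WEIBULL * (np.log(xa) - m) / w)
    psi = gamma_guess + (1.0 - lambda_lapse - gamma_guess) * (
        1.0 - np.exp(LOG_HALF * z)
    )
    return float(psi) if np.isscalar(x) else psi


@dataclass
class OutcomeTable:
    """Aggregated trial outcomes: per contrast level, presented vs seen."""

    contrast: np.ndarray
    n_presented: np.ndarray
    n_seen: np.ndarray

    def __post_init__(self) -> None:
        self.contrast = np.asarray(self.contrast, dtype=float)
        self.n_presented = np.asarray(self.n_presented, dtype=int)
        self.n_seen = np.asarray(self.n_seen, dtype=int)
        if np.any(self.contrast <= 0):
            raise ValueError("contrast levels must be positive")
        if np.any(self.n_seen < 0) or np.any(self.n_seen > self.n_presented):
            raise ValueError("need 0 <= n_seen <= n_presented")

    @classmethod
    def from_trials(cls, trials: Iterable[Tuple[float, bool]]) -> "OutcomeTable":
        """Aggregate (contrast, seen) pairs."""
        agg: dict = {}
        for c, seen in trials:
            n, k = agg.get(c, (0, 0))
            agg[c] = (n + 1, k + bool(seen))
        levels = sorted(agg)
        return cls(
            contrast=np.array(levels),
            n_presented=np.array([agg[c][0] for c in levels]),
            n_seen=np.array([agg[c][1] for c in levels]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contrast": self.contrast,
                "n_presented": self.n_presented,
                "n_seen": self.n_seen,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OutcomeTable":
        df = pd.read_csv(path)
        return cls(
            contrast=df["contrast"].to_numpy(),
            n_presented=df["n_presented"].to_numpy(),
            n_seen=df["n_seen"].to_numpy(),
        )


@dataclass
class PsychometricFit:
    """Maximum-likelihood fit result."""

    params: PsychometricParams
    log_likelihood: float
    converged: bool
    message: str = ""


def _neg_log_likelihood(
    m: float, w: float, table: OutcomeTable,
    gamma_guess: float, lambda_lapse: float,
) -> float:
    psi = weibull_psi(
        table.contrast, m=m, w=w,
        gamma_guess=gamma_guess, lambda_lapse=lambda_lapse,
    )
    psi = np.clip(psi, 1e-12, 1.0 - 1e-12)
    ll = table.n_seen * np.log(psi) + (
        table.n_presented - table.n_seen
    ) * np.log(1.0 - psi)
    return -float(np.sum(ll))


def fit_psychometric(
    table: OutcomeTable,
    gamma_guess: float = 0.0,
    lambda_lapse: float = 0.0,
    m_bounds: Optional[Tuple[float, float]] = None,
    w_bounds: Tuple[float, float] = (0.05, 20.0),
) -> PsychometricFit:
    """Fit (m, w) by maximizing the product-binomial likelihood.

    The guess and lapse rates are fixed (zero in the reference protocol).
    ``m`` is bounded to the tested log-contrast range extended by one median
    level spacing unless explicit bounds are given.  A table in which every
    presentation was seen (or none was) pins the threshold to a boundary and
    is returned with ``converged=False`` plus a warning, never as a silent
    interior estimate.

    The optimizer is a coarse grid search refined by Nelder-Mead on
    ``(m, log w)``; the tests cross-check it against an independent dense
    grid evaluation of the same likelihood.
    """
    if np.unique(table.contrast).size < 1:
        raise InsufficientDataError("empty outcome table")
    logc = np.log(table.contrast)
    if m_bounds is None:
        step = float(np.median(np.diff(np.sort(logc)))) if logc.size > 1 else 1.0
        m_bounds = (float(logc.min()) - step, float(logc.max()) + step)

    total_seen = int(table.n_seen.sum())
    total = int(table.n_presented.sum())
    degenerate = total_seen == 0 or total_seen == total
    if degenerate or np.unique(table.contrast).size < 2:
        m_est = m_bounds[1] if total_seen == 0 else m_bounds[0]
        w_est = math.sqrt(w_bounds[0] * w_bounds[1])
        params = PsychometricParams(m_est, w_est, gamma_guess, lambda_lapse)
        msg = ("degenerate outcome table (all seen or none seen, or a single "
               "level): boundary estimate returned")
        warnings.warn(msg, stacklevel=2)
        return PsychometricFit(
            params=params,
            log_likelihood=-_neg_log_likelihood(
                m_est, w_est, table, gamma_guess, lambda_lapse
            ),
            converged=False,
            message=msg,
        )

    # coarse grid
    m_grid = np.linspace(m_bounds[0], m_bounds[1], 61)
    w_grid = np.geomspace(w_bounds[0], w_bounds[1], 31)
    best = (math.inf, m_grid[0], w_grid[0])
    for mg in m_grid:
        for wg in w_grid:
            nll = _neg_log_likelihood(mg, wg, table, gamma_guess, lambda_lapse)
            if nll < best[0]:
                best = (nll, mg, wg)

    def objective(theta):
        m, logw = theta
        m = min(max(m, m_bounds[0]), m_bounds[1])
        w = min(max(math.exp(logw), w_bounds[0]), w_bounds[1])
        return _neg_log_likelihood(m, w, table, gamma_guess, lambda_lapse)

    res = minimize(
        objective,
        x0=[best[1], math.log(best[2])],
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
    )
    m_est = min(max(float(res.x[0]), m_bounds[0]), m_bounds[1])
    w_est = min(max(math.exp(float(res.x[1])), w_bounds[0]), w_bounds[1])
    params = PsychometricParams(m_est, w_est, gamma_guess, lambda_lapse)
    return PsychometricFit(
        params=params,
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
    )


def threshold_to_cs(params: PsychometricParams) -> Tuple[float, float]:
    """(CT, CS) = (e^m, 1/e^m)."""
    return params.ct, params.cs


def width_to_slope(w: float) -> float:
    """Slope s = c / w."""
    if w <= 0:
        raise ValueError("width must be positive")
    return C_WEIBULL / w


def slope_to_width(s: float) -> float:
    """Width w = c / s (inverse of :func:`width_to_slope`)."""
    if s <= 0:
        raise ValueError("slope must be positive")
    return C_WEIBULL / s
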