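"""QUEST+ adaptive contrast selection over a Weibull psychometric model.

The procedure maintains a posterior probability mass over a grid of
candidate psychometric parameters — here the 39 displayable contrast levels
as candidate thresholds crossed with 11 candidate slopes (0.5 to 5.5 in
steps of 0.5) — and selects the next stimulus contrast as the ladder level
minimizing the expected posterior entropy over the two possible trial
outcomes.  Guess and lapse rates are fixed at zero.  The object itself is
fully deterministic; randomness only ever lives in the simulated observers
that consume it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .psychometric import C_WEIBULL, weibull_psi

__all__ = ["QuestPlus", "QuestEstimate", "outcome_likelihood", "DEFAULT_SLOPE_GRID"]

DEFAULT_SLOPE_GRID: np.ndarray = np.arange(0.5, 5.5 + 1e-9, 0.5)


def outcome_likelihood(
    contrast: float, threshold_candidate: float, slope_candidate: float
) -> float:
    """P(seen | contrast, candidate threshold, candidate slope).

    The candidate threshold is a contrast fraction; the Weibull is evaluated
    with ``m = log(threshold)`` and ``w = c / slope`` and zero asymptotes,
    so a stimulus at the candidate threshold is seen with probability 0.5.
    """
    if slope_candidate <= 0:
        raise ValueError("slope candidate must be positive")
    return float(
        weibull_psi(
            contrast,
            m=math.log(threshold_candidate),
            w=C_WEIBULL / slope_candidate,
        )
    )


@dataclass
class QuestEstimate:
    """Posterior summary of (threshold, slope)."""

    mode_threshold: float
    mode_slope: float
    mean_log_threshold: float
    mean_slope: float
    ci_log_threshold: Tuple[float, float]
    ci_slope: Tuple[float, float]


class QuestPlus:
    """Bayesian adaptive staircase over (threshold x slope).

    Parameters
    ----------
    ladder:
        Strictly increasing admissible contrast levels in (0, 1]; also the
        candidate-threshold grid (thresholds and displayable contrasts are
        unified).
    slope_grid:
        Candidate Weibull slopes.
    prior:
        Optional prior mass of shape ``(len(ladder), len(slope_grid))``;
        uniform when omitted.  Any non-negative mass is renormalized.
    """

    def __init__(
        self,
        ladder: Sequence[float],
        slope_grid: Sequence[float] = DEFAULT_SLOPE_GRID,
        prior: Optional[np.ndarray] = None,
    ) -> None:
        ladder = np.asarray(ladder, dtype=float)
        if ladder.ndim != 1 or ladder.size < 2:
            raise ConfigError("ladder must be a 1-D array of >=2 levels")
        if np.any(np.diff(ladder) <= 0):
            raise ConfigError("contrast ladder must be strictly increasing")
        if np.any(ladder <= 0) or np.any(ladder > 1):
            raise ConfigError("ladder levels must lie in (0, 1]")
        slope_grid = np.asarray(slope_grid, dtype=float)
        if np.any(slope_grid <= 0):
            raise ConfigError("slopes must be positive")

        self.ladder = ladder
        self.slope_grid = slope_grid
        self.history: List[Tuple[float, bool]] = []

        if prior is None:
            post = np.full((ladder.size, slope_grid.size), 1.0)
        else:
            post = np.asarray(prior, dtype=float).copy()
            if post.shape != (ladder.size, slope_grid.size):
                raise ConfigError(
                    f"prior shape {post.shape} != "
                    f"{(ladder.size, slope_grid.size)}"
                )
            if np.any(post < 0) or post.sum() <= 0:
                raise ConfigError("prior must be non-negative with positive mass")
        self._posterior = post / post.sum()

        # P(seen | stimulus i, threshold j, slope k) -> (n_stim, n_cells)
        logx = np.log(ladder)
        m = np.log(ladder)
        w = C_WEIBULL / slope_grid
        z = np.exp(
            C_WEIBULL
            * (logx[:, None, None] - m[None, :, None])
            / w[None, None, :]
        )
        psi = 1.0 - np.exp(math.log(0.5) * z)
        self._psi = psi.reshape(ladder.size, -1)

    # -- state ----------------------------------------------------------
    @property
    def posterior(self) -> np.ndarray:
        """Posterior mass, shape (n_thresholds, n_slopes); sums to 1."""
        return self._posterior.copy()

    def _flat(self) -> np.ndarray:
        return self._posterior.reshape(-1)

    # -- Bayes update ---------------------------------------------------
    def _stim_index(self, contrast: float) -> int:
        idx = int(np.argmin(np.abs(self.ladder - contrast)))
        if not math.isclose(self.ladder[idx], contrast, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(f"contrast {contrast!r} is not on the ladder")
        return idx

    def update(self, contrast: float, seen: bool) -> None:
        """Multiply the posterior by the outcome likelihood and renormalize."""
        i = self._stim_index(contrast)
        like = self._psi[i] if seen else 1.0 - self._psi[i]
        post = self._flat() * like
        total = post.sum()
        if total <= 0:
            raise ValueError("posterior collapsed to zero mass")
        self._posterior = (post / total).reshape(self._posterior.shape)
        self.history.append((float(self.ladder[i]), bool(seen)))

    # -- stimulus selection ---------------------------------------------
    @staticmethod
    def _entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))

    def expected_entropies(self) -> np.ndarray:
        """E[posterior entropy] after one trial, for every ladder level."""
        post = self._flat()
        out = np.empty(self.ladder.size)
        for i in range(self.ladder.size):
            like = self._psi[i]
            seen = post * like
            p_seen = seen.sum()
            not_seen = post - seen
            h = 0.0
            if p_seen > 0:
                h += p_seen * self._entropy(seen / p_seen)
            if p_seen < 1:
                h += (1.0 - p_seen) * self._entropy(not_seen / (1.0 - p_seen))
            out[i] = h
        return out

    def next_contrast(self) -> float:
        """Ladder level minimizing expected posterior entropy.

        Ties break toward the lower contrast (argmin returns the first
        minimum on the ascending ladder), preferring the harder stimulus.
        """
        eh = self.expected_entropies()
        return float(self.ladder[int(np.argmin(eh))])

    # -- summaries -------------------------------------------------------
    def estimate(self) -> QuestEstimate:
        """Posterior mode/mean with central 95% marginal intervals."""
        post = self._posterior
        j, k = np.unravel_index(int(np.argmax(post)), post.shape)
        marg_t = post.sum(axis=1)
        marg_s = post.sum(axis=0)
        logt = np.log(self.ladder)

        def ci(grid: np.ndarray, mass: np.ndarray) -> Tuple[float, float]:
            cdf = np.cumsum(mass)
            lo = grid[int(np.searchsorted(cdf, 0.025))]
            hi = grid[min(int(np.searchsorted(cdf, 0.975)), grid.size - 1)]
            return float(lo), float(hi)

        return QuestEstimate(
            mode_threshold=float(self.ladder[j]),
            mode_slope=float(self.slope_grid[k]),
            mean_log_threshold=float(np.dot(marg_t, logt)),
            mean_slope=float(np.dot(marg_s, self.slope_grid)),
            ci_log_threshold=ci(logt, marg_t),
            ci_slope=ci(self.slope_grid, marg_s),
        )

    def to_log(self) -> dict:
        """Human-readable serializable snapshot for audit logs."""
        est = self.estimate() if self.history else None
        return {
            "n_trials": len(self.history),
            "history": [
                {"contrast": c, "seen": s} for c, s in self.history
            ],
            "estimate": None if est is None else est.__dict__,
        }
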