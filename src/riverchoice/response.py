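"""Relative-selection-ratio response functions.

For one covariate of a fitted model, the linear predictor is evaluated on a
grid spanning the 10th-90th percentile of use locations with every other
covariate held at its mean over all rows.  Ratios are ``exp`` of the linear
predictor scaled so the maximum equals 1 (by default scaled to the maximum
point prediction; optionally to the maximum of the upper confidence bound).
Confidence intervals come from the delta method on the linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from riverchoice.choice_sets import ChoiceSet
from riverchoice.dcgam import DCGAMFit
from riverchoice.errors import DomainError

DEFAULT_CONF_LEVEL = 0.90


@dataclass
class ResponseFunction:
    """Scaled relative selection ratio over a covariate grid."""

    covariate: str
    grid: np.ndarray
    ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    conf_level: float
    rug_used: np.ndarray
    rug_available: np.ndarray

    @property
    def peak_value(self) -> float:
        return float(self.grid[int(np.argmax(self.ratio))])

    @property
    def plateau_low(self) -> float:
        return peak_and_plateau(self)[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "covariate": self.covariate,
                "grid": self.grid,
                "ratio": self.ratio,
                "lo": self.ci_low,
                "hi": self.ci_high,
            }
        )

    def summary(self) -> dict:
        peak, plateau = peak_and_plateau(self)
        return {
            "covariate": self.covariate,
            "peak_value": peak,
            "plateau_low": plateau,
            "conf_level": self.conf_level,
        }


def _covariate_values(sets: Iterable[ChoiceSet], covariate: str, used_only: bool):
    return np.array(
        [
            a.covariate(covariate)
            for cs in sets
            for a in cs.alternatives
            if (a.used or not used_only)
        ]
    )


def response_function(
    fit: DCGAMFit,
    covariate: str,
    data: Sequence[ChoiceSet],
    n_grid: int = 100,
    conf_level: float = DEFAULT_CONF_LEVEL,
    scale_by_upper_ci: bool = False,
    percentiles: tuple[float, float] = (10.0, 90.0),
    percentile_basis: str = "use",
) -> ResponseFunction:
    """Response function of ``covariate`` with the other model covariates
    held constant at their means over all rows of ``data``.

    The grid spans the stated percentiles of the covariate at *use*
    locations (``percentile_basis="all"`` uses every row instead, showing
    the rise below the range of used values).  ``scale_by_upper_ci=True``
    scales ratios by the maximum of the upper confidence bound instead of
    the maximum point prediction.
    """
    if covariate not in fit.model.covariates:
        raise DomainError(f"covariate {covariate!r} is not in model {fit.name}")
    if percentile_basis not in ("use", "all"):
        raise DomainError("percentile_basis must be 'use' or 'all'")
    used_vals = _covariate_values(data, covariate, used_only=True)
    all_vals = _covariate_values(data, covariate, used_only=False)
    basis_vals = used_vals if percentile_basis == "use" else all_vals
    g_lo, g_hi = np.percentile(basis_vals, list(percentiles))
    if g_hi <= g_lo:
        raise DomainError(f"degenerate use-percentile range for {covariate!r}")
    grid = np.linspace(g_lo, g_hi, n_grid)

    values = {covariate: grid}
    for other in fit.model.covariates:
        if other != covariate:
            values[other] = np.full(n_grid, _covariate_values(data, other, False).mean())
    rows = fit.design.design_row(values, clamp=True)
    eta = rows @ fit.beta if fit.design.n_params else np.zeros(n_grid)

    # the displayed quantity is the ratio against the curve's maximum, so the
    # interval is on the linear-predictor contrast with that reference point
    i_ref = int(np.argmax(eta))
    d_rows = rows - rows[i_ref]
    if fit.design.n_params:
        se = np.sqrt(
            np.maximum(np.einsum("ij,jk,ik->i", d_rows, fit.coef_covariance, d_rows), 0.0)
        )
    else:
        se = np.zeros(n_grid)
    z = norm.ppf(0.5 + conf_level / 2.0)
    d_eta = eta - eta[i_ref]
    lo = np.exp(d_eta - z * se)
    hi = np.exp(d_eta + z * se)
    ratio = np.exp(d_eta)
    if scale_by_upper_ci:
        ref = float(np.max(hi))
        ratio, lo, hi = ratio / ref, lo / ref, hi / ref
    return ResponseFunction(
        covariate=covariate,
        grid=grid,
        ratio=ratio,
        ci_low=lo,
        ci_high=hi,
        conf_level=conf_level,
        rug_used=used_vals,
        rug_available=np.array(
            [a.covariate(covariate) for cs in data for a in cs.alternatives if not a.used]
        ),
    )


def peak_and_plateau(rf: ResponseFunction) -> tuple[float, float]:
    """Peak covariate value and the plateau onset.

    The peak is the grid value maximizing the ratio; the plateau onset is
    the smallest grid value whose confidence interval overlaps the peak's
    (overlapping intervals are treated as statistically similar).
    """
    i_peak = int(np.argmax(rf.ratio))
    peak = float(rf.grid[i_peak])
    similar = rf.ci_high >= rf.ci_low[i_peak]
    plateau_low = float(rf.grid[int(np.flatnonzero(similar)[0])])
    return peak, plateau_low


def saturation_onset(rf: ResponseFunction, frac: float = 0.95) -> float:
    """Smallest grid value whose ratio reaches ``frac`` of the maximum.

    For saturating (ramp/plateau) responses this estimates the covariate
    value beyond which selection no longer appreciably increases.
    """
    idx = int(np.flatnonzero(rf.ratio >= frac * rf.ratio.max())[0])
    return float(rf.grid[idx])


def plot_response(rf: ResponseFunction, path=None, ax=None):
    """Optional thin plotting layer (ratio curve, CI band, rug marks)."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    ax.plot(rf.grid, rf.ratio, "k-", lw=1.5)
    ax.plot(rf.grid, rf.ci_low, "k--", lw=0.8)
    ax.plot(rf.grid, rf.ci_high, "k--", lw=0.8)
    ax.plot(rf.rug_used, np.ones_like(rf.rug_used), "|", color="0.3", ms=8)
    ax.plot(rf.rug_available, np.zeros_like(rf.rug_available), "|", color="0.6", ms=8)
    ax.set_xlabel(rf.covariate.upper())
    ax.set_ylabel("relative selection ratio")
    ax.set_ylim(-0.05, 1.1)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return ax
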