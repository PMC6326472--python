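"""Binned calibration-slope validation with a Good/Adequate/Poor verdict.

Each repetition randomly splits the choice sets 2/3 train : 1/3 test, fits
the model on the training sets, scales the predicted weights of the test
*available* locations so they sum to the number of test use locations, bins
them into percentile categories, and regresses the observed number of use
locations per bin on the expected number.  A well-calibrated model has
slope near 1.  The verdict is taken from the position of the 95% CI of the
replicate slopes relative to 0 and 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from riverchoice._rng import rng_for
from riverchoice.choice_sets import CandidateModel, ChoiceSet, split_train_test
from riverchoice.dcgam import fit_dcgam
from riverchoice.errors import FitError

log = logging.getLogger(__name__)

VERDICT_GOOD = "Good"
VERDICT_ADEQUATE = "Adequate"
VERDICT_POOR = "Poor"


@dataclass
class ValidationResult:
    slopes: np.ndarray
    mean_slope: float
    ci95: tuple[float, float]
    verdict: str
    n_reps: int
    n_bins: int
    seed: int
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_slope": self.mean_slope,
            "ci95": list(self.ci95),
            "verdict": self.verdict,
            "n_reps": self.n_reps,
            "n_bins": self.n_bins,
            "n_skipped": self.n_skipped,
            "seed": self.seed,
            "slopes": self.slopes.tolist(),
        }


def classify_fit(ci95: tuple[float, float]) -> str:
    """Good: CI contains 1 and not 0.  Poor: CI contains 0 (the spanning-zero
    rule takes precedence when the CI contains both).  Adequate: neither."""
    lo, hi = ci95
    if lo > hi:
        raise ValueError("interval low bound exceeds high bound")
    contains_zero = lo <= 0.0 <= hi
    contains_one = lo <= 1.0 <= hi
    if contains_zero:
        return VERDICT_POOR
    if contains_one:
        return VERDICT_GOOD
    return VERDICT_ADEQUATE


def _calibration_slope(
    avail_pred: np.ndarray,
    use_pred: np.ndarray,
    n_bins: int,
    rng: np.random.Generator,
) -> float | None:
    """Slope of observed on expected use counts across percentile bins.

    Bin breakpoints are percentiles of the scaled available predictions;
    use locations are placed by their own scaled prediction (outer bins are
    open-ended so every location lands in a bin).  Returns None when the
    bins are degenerate.
    """
    n_use = use_pred.size
    total = avail_pred.sum()
    if not np.isfinite(total) or total <= 0:
        return None
    scale = n_use / total
    avail_scaled = avail_pred * scale
    use_scaled = use_pred * scale
    if np.ptp(avail_scaled) <= 1e-12 * max(1.0, abs(float(avail_scaled.mean()))):
        return None  # all predictions tied: no percentile bins exist
    # tie-break heavy duplication before quantiling
    if np.unique(avail_scaled).size < avail_scaled.size:
        log.debug("jittering tied predictions before quantile binning")
        jitter = 1e-12 * np.abs(avail_scaled).mean()
        avail_scaled = avail_scaled + rng.uniform(-jitter, jitter, avail_scaled.size)
    edges = np.quantile(avail_scaled, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        return None
    inner = edges[1:-1]
    # right-closed intervals; outer bins open-ended
    expected = np.zeros(edges.size - 1)
    observed = np.zeros(edges.size - 1)
    idx_a = np.searchsorted(inner, avail_scaled, side="left")
    np.add.at(expected, idx_a, avail_scaled)
    idx_u = np.searchsorted(inner, use_scaled, side="left")
    np.add.at(observed, idx_u, 1.0)
    if np.std(expected) == 0:
        return None
    slope = np.polyfit(expected, observed, 1)[0]
    return float(slope)


def calibration_rep(
    sets: Sequence[ChoiceSet],
    model: CandidateModel,
    train_frac: float = 2.0 / 3.0,
    n_bins: int = 20,
    seed: int = 0,
    basis_dim: int = 4,
    lambdas: dict[str, float] | None = None,
    lambda_grid=None,
    scramble: bool = False,
) -> float | None:
    """One train/test calibration repetition; returns the slope (or None
    when the repetition is degenerate and must be skipped).

    ``scramble`` permutes predictions among all test locations — a
    broken-model control whose slopes concentrate near zero.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    train, test = split_train_test(sets, train_frac, seed=seed)
    fit = fit_dcgam(
        train, model, lambda_grid=lambda_grid, basis_dim=basis_dim, lambdas=lambdas
    )
    w = fit.predict_weights(test, clamp=True)
    used_mask = np.array([a.used for cs in test for a in cs.alternatives])
    rng = rng_for(seed, "calibration")
    if scramble:
        w = rng.permutation(w)
    return _calibration_slope(w[~used_mask], w[used_mask], n_bins, rng)


def validate(
    sets: Sequence[ChoiceSet],
    model: CandidateModel,
    n_reps: int = 1000,
    train_frac: float = 2.0 / 3.0,
    n_bins: int = 20,
    seed: int = 0,
    basis_dim: int = 4,
    lambdas: dict[str, float] | None = None,
    lambda_grid=None,
    scramble: bool = False,
) -> ValidationResult:
    """Repeat the calibration procedure ``n_reps`` times and classify the
    model from the mean slope's 95 percentile interval.

    Pass ``lambdas`` (e.g. from a full-data fit) to skip the per-repetition
    smoothing-parameter search; the paper-style default re-tunes each time.
    """
    slopes = []
    n_skipped = 0
    for r in range(n_reps):
        s = calibration_rep(
            sets,
            model,
            train_frac=train_frac,
            n_bins=n_bins,
            seed=int(rng_for(seed, "rep", r).integers(2**31 - 1)),
            basis_dim=basis_dim,
            lambdas=lambdas,
            lambda_grid=lambda_grid,
            scramble=scramble,
        )
        if s is None:
            n_skipped += 1
            log.info("calibration rep %d skipped (degenerate bins)", r)
        else:
            slopes.append(s)
    if n_skipped > 0.2 * n_reps:
        raise FitError(
            f"{n_skipped}/{n_reps} calibration repetitions degenerate; "
            "predictions are nearly constant"
        )
    slopes_arr = np.asarray(slopes)
    if slopes_arr.size == 1:
        ci = (float(slopes_arr[0]), float(slopes_arr[0]))
    else:
        ci = tuple(np.percentile(slopes_arr, [2.5, 97.5]).tolist())
    return ValidationResult(
        slopes=slopes_arr,
        mean_slope=float(slopes_arr.mean()),
        ci95=(float(ci[0]), float(ci[1])),
        verdict=classify_fit((float(ci[0]), float(ci[1]))),
        n_reps=n_reps,
        n_bins=n_bins,
        seed=seed,
        n_skipped=n_skipped,
    )
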