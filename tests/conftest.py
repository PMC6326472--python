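"""Shared fixtures: hand-built rectangular landscapes, a small generated
landscape, and direct (landscape-free) synthetic choice data for the
numeric core."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon, box

from riverchoice._rng import rng_for
from riverchoice.choice_sets import Alternative, ChoiceSet
from riverchoice.synthetic_river import (
    LandscapeConfig,
    PlateauEffect,
    RiverLandscape,
    TrueSelectionSpec,
    generate_landscape,
    simulate_stopovers,
)

# landscape parameters used by the heavier replicate tests: short reach,
# coarse centerline, denser riparian forest (keeps NF informative)
FAST_LANDSCAPE = dict(
    extent_km=36.0,
    centerline_step_m=100.0,
    base_halfwidth_m=65.0,
    width_sigma=1.0,
    width_log_clip=1.65,
    constriction_log_amp=0.4,
    veg_per_km=3.0,
    forest_len_mean_m=2500.0,
    forest_gap_mean_m=800.0,
    forest_setback_max_m=300.0,
)
# generating truth used by recovery tests: plateau onsets 200 m / 160 m with
# a gentle post-plateau decline (the peaked-plateau shape of fitted curves)
TRUE_UOCW = PlateauEffect(4.0, 200.0, decline=0.5)
TRUE_NF = PlateauEffect(4.0, 160.0, decline=0.5)


def make_rect_landscape(
    length_m: float = 40_000.0,
    halfwidth_m: float = 100.0,
    veg: list[Polygon] | None = None,
    forest: list[Polygon] | None = None,
) -> RiverLandscape:
    """Straight rectangular channel along the x axis."""
    centerline = LineString([(0.0, 0.0), (length_m, 0.0)])
    channel = box(0.0, -halfwidth_m, length_m, halfwidth_m)
    return RiverLandscape(
        centerline=centerline,
        channel_polygon=channel,
        dense_veg_patches=veg or [],
        forest_patches=forest or [],
        discharge={"2001-04-01": 10.0},
        wetted_fraction={"2001-04-01": 0.5},
        extent_km=length_m / 1000.0,
    )


def make_synthetic_sets(
    n_sets: int,
    n_alts: int = 8,
    beta: dict[str, float] | None = None,
    seed: int = 0,
    covariates: tuple[str, ...] = ("uocw", "nf"),
    covariate_draw=None,
) -> list[ChoiceSet]:
    """Landscape-free choice sets with iid covariates and a known linear
    truth ``eta = sum_c beta[c] * x_c`` (zero when ``beta`` is None)."""
    rng = rng_for(seed, "synth-sets")
    beta = beta or {}
    sets = []
    for i in range(n_sets):
        vals = {
            c: (
                covariate_draw(rng, n_alts)
                if covariate_draw is not None
                else rng.normal(0.0, 1.0, n_alts)
            )
            for c in covariates
        }
        eta = sum(beta.get(c, 0.0) * vals[c] for c in covariates)
        eta = np.asarray(eta, dtype=float) if np.ndim(eta) else np.zeros(n_alts)
        p = np.exp(eta - eta.max())
        p /= p.sum()
        used = int(rng.choice(n_alts, p=p))
        alts = [
            Alternative(
                alt_id=j,
                used=(j == used),
                x_m=float(j),
                uocw=float(vals.get("uocw", np.zeros(n_alts))[j]),
                tcw=float(vals.get("tcw", np.zeros(n_alts))[j]),
                ufcw=float(vals.get("ufcw", np.zeros(n_alts))[j]),
                nf=float(vals.get("nf", np.zeros(n_alts))[j]),
                ud=float(vals.get("ud", np.zeros(n_alts))[j]),
                dis=float(vals.get("dis", np.zeros(n_alts))[j]),
            )
            for j in range(n_alts)
        ]
        sets.append(
            ChoiceSet(set_id=i, alternatives=alts, anchor_m=0.0, window_m=1e9,
                      date="2001-04-01", season="spring")
        )
    return sets


@pytest.fixture(scope="session")
def rect_landscape() -> RiverLandscape:
    return make_rect_landscape()


@pytest.fixture(scope="session")
def small_landscape() -> RiverLandscape:
    """36-km generated landscape shared by sampling-heavy tests."""
    return generate_landscape(LandscapeConfig(seed=11, **FAST_LANDSCAPE))


@pytest.fixture(scope="session")
def sets_85(small_landscape) -> list:
    """85 simulated stopovers with 20 available points each."""
    spec = TrueSelectionSpec(
        uocw_effect=TRUE_UOCW, nf_effect=TRUE_NF, n_use=85, n_avail=20, seed=7
    )
    return simulate_stopovers(small_landscape, spec)


@pytest.fixture(scope="session")
def sets_235(small_landscape) -> list:
    """235 simulated stopovers with 20 available points each."""
    spec = TrueSelectionSpec(
        uocw_effect=TRUE_UOCW, nf_effect=TRUE_NF, n_use=235, n_avail=20, seed=8
    )
    return simulate_stopovers(small_landscape, spec)
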