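"""Use/availability choice-set assembly, candidate-model screening and
train/test splitting.

A choice set is one used location plus ``n_avail`` available locations
sampled uniformly within a +/-16 km along-channel window centred on the use
location (window distance measured in river-kilometres along the
centerline, clipped at the landscape ends).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from riverchoice._rng import rng_for
from riverchoice.errors import ChoiceDataError, DomainError
from riverchoice.synthetic_river import DEFAULT_WINDOW_M, RiverLandscape, season_of

log = logging.getLogger(__name__)

COVARIATES = ("uocw", "tcw", "ufcw", "nf", "ud", "dis")

# CSV column dialect shared across the pipeline
CSV_COLUMNS = [
    "set_id",
    "alt_id",
    "used",
    "x_m",
    "uocw_m",
    "nf_m",
    "tcw_m",
    "ufcw_m",
    "ud_cms_per_m",
    "dis_cms_per_m",
    "season",
    "date",
]
_CSV_NAME = {
    "uocw": "uocw_m",
    "nf": "nf_m",
    "tcw": "tcw_m",
    "ufcw": "ufcw_m",
    "ud": "ud_cms_per_m",
    "dis": "dis_cms_per_m",
}


@dataclass
class Alternative:
    """One candidate location within a choice set."""

    alt_id: int
    used: bool
    x_m: float
    uocw: float
    tcw: float
    ufcw: float
    nf: float
    ud: float
    dis: float
    px: float = math.nan
    py: float = math.nan

    def covariate(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass
class ChoiceSet:
    """One use alternative plus its sampled available alternatives."""

    set_id: int
    alternatives: list[Alternative]
    anchor_m: float
    window_m: float = DEFAULT_WINDOW_M
    date: str = ""
    season: str = ""

    @property
    def window(self) -> tuple[float, float, float]:
        return (self.anchor_m, -self.window_m, +self.window_m)

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)

    def used_alternative(self) -> Alternative:
        used = [a for a in self.alternatives if a.used]
        if len(used) != 1:
            raise ChoiceDataError(
                f"choice set {self.set_id} has {len(used)} used alternatives; expected 1"
            )
        return used[0]

    def validate(self) -> None:
        self.used_alternative()
        lo = self.anchor_m - self.window_m - 1e-6
        hi = self.anchor_m + self.window_m + 1e-6
        for a in self.alternatives:
            if not (lo <= a.x_m <= hi):
                raise ChoiceDataError(
                    f"alternative {a.alt_id} of set {self.set_id} lies outside "
                    f"the availability window ({a.x_m:.0f} m vs anchor {self.anchor_m:.0f} m)"
                )


@dataclass(frozen=True)
class CandidateModel:
    """A named combination of covariates, each smooth or linear."""

    name: str
    covariates: tuple[str, ...]
    smooth: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not self.smooth:
            object.__setattr__(self, "smooth", tuple(True for _ in self.covariates))
        if len(self.smooth) != len(self.covariates):
            raise ChoiceDataError(f"model {self.name}: smooth flags mismatch covariates")

    @property
    def terms(self) -> list[tuple[str, bool]]:
        return list(zip(self.covariates, self.smooth))

    @property
    def is_null(self) -> bool:
        return len(self.covariates) == 0

    def with_linear(self, covariate: str) -> "CandidateModel":
        smooth = tuple(
            s and (c != covariate) for c, s in zip(self.covariates, self.smooth)
        )
        return CandidateModel(self.name, self.covariates, smooth)


def _model(name: str) -> CandidateModel:
    if name.upper() == "NULL":
        return CandidateModel("NULL", ())
    covs = tuple(c.strip().lower() for c in name.split("+"))
    return CandidateModel("+".join(c.upper() for c in covs), covs)


def riverine_model_list() -> list[CandidateModel]:
    """The in-channel a-priori candidate list (null + single metrics +
    screened combinations), UFCW standing in for the unforested-width term."""
    names = [
        "NULL",
        "UOCW",
        "TCW",
        "NF",
        "UFCW",
        "UD",
        "DIS",
        "UOCW+NF",
        "UOCW+UD",
        "UOCW+DIS",
        "TCW+UOCW",
        "TCW+NF+UOCW",
        "UOCW+NF+UD",
        "UOCW+NF+DIS",
    ]
    return [_model(n) for n in names]


def plains_model_list() -> list[CandidateModel]:
    """Reduced candidate list used for the corridor-wide analysis."""
    return [_model(n) for n in ["NULL", "UOCW", "NF", "UOCW+NF"]]


# ---------------------------------------------------------------------------
# choice-set construction


def build_choice_sets(
    points: Sequence[Point | tuple[float, float]],
    landscape: RiverLandscape,
    n_avail: int = 20,
    seed: int = 0,
    dates: Sequence[str] | None = None,
    window_m: float = DEFAULT_WINDOW_M,
) -> list[ChoiceSet]:
    """Assemble one choice set per use point.

    Each use point becomes alternative 0 (used); ``n_avail`` available
    points are sampled uniformly by area in the wetted channel within
    ``+/- window_m`` along the centerline of the use location.  Windows
    running past a landscape end are clipped (and logged).  Deterministic
    given ``seed``.
    """
    from riverchoice.habitat_metrics import measure_point

    if n_avail < 1:
        raise DomainError("n_avail must be >= 1")
    sets: list[ChoiceSet] = []
    for i, raw in enumerate(points):
        p = raw if isinstance(raw, Point) else Point(raw[0], raw[1])
        if not landscape.contains(p):
            raise DomainError(f"use point {i} is not inside the channel")
        rng = rng_for(seed, "choiceset", i)
        date = dates[i] if dates is not None else landscape.sample_date(rng)
        anchor = landscape.arc_coord(p)
        if anchor < window_m or anchor > landscape.length_m - window_m:
            log.info(
                "choice set %d: window clipped to landscape (anchor %.0f m)", i, anchor
            )
        q = landscape.discharge[date]
        wf = landscape.wetted_fraction[date]

        def make_alt(alt_id: int, pt: Point, used: bool) -> Alternative:
            m = measure_point(landscape, pt, q, wf)
            return Alternative(
                alt_id=alt_id,
                used=used,
                x_m=landscape.arc_coord(pt),
                uocw=m.uocw,
                tcw=m.tcw,
                ufcw=m.ufcw,
                nf=m.nf,
                ud=m.ud,
                dis=m.dis,
                px=pt.x,
                py=pt.y,
            )

        alts = [make_alt(0, p, True)]
        for j, ap in enumerate(landscape.sample_points(anchor, n_avail, rng, window_m)):
            alts.append(make_alt(j + 1, ap, False))
        cs = ChoiceSet(
            set_id=i,
            alternatives=alts,
            anchor_m=anchor,
            window_m=window_m,
            date=date,
            season=season_of(date),
        )
        cs.validate()
        sets.append(cs)
    return sets


# ---------------------------------------------------------------------------
# data-frame conversion (CSV dialect)


def sets_to_frame(sets: Iterable[ChoiceSet]) -> pd.DataFrame:
    """Flatten choice sets into the shared CSV dialect (one row per
    alternative)."""
    rows = []
    for cs in sets:
        cs.used_alternative()
        for a in cs.alternatives:
            rows.append(
                {
                    "set_id": cs.set_id,
                    "alt_id": a.alt_id,
                    "used": int(a.used),
                    "x_m": a.x_m,
                    "uocw_m": a.uocw,
                    "nf_m": a.nf,
                    "tcw_m": a.tcw,
                    "ufcw_m": a.ufcw,
                    "ud_cms_per_m": a.ud,
                    "dis_cms_per_m": a.dis,
                    "season": cs.season,
                    "date": cs.date,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_sets(df: pd.DataFrame) -> list[ChoiceSet]:
    """Rebuild choice sets from the shared CSV dialect, enforcing the
    one-used-per-set structure."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ChoiceDataError(f"choice data missing columns: {missing}")
    dup = df.duplicated(subset=["set_id", "alt_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ChoiceDataError(f"duplicate (set_id, alt_id) at row {row}")
    sets = []
    for set_id, grp in df.groupby("set_id", sort=True):
        n_used = int(grp["used"].sum())
        if n_used != 1:
            raise ChoiceDataError(
                f"choice set {set_id} has {n_used} used rows; expected exactly 1"
            )
        alts = [
            Alternative(
                alt_id=int(r.alt_id),
                used=bool(r.used),
                x_m=float(r.x_m),
                uocw=float(r.uocw_m),
                tcw=float(r.tcw_m),
                ufcw=float(r.ufcw_m),
                nf=float(r.nf_m),
                ud=float(r.ud_cms_per_m),
                dis=float(r.dis_cms_per_m),
            )
            for r in grp.itertuples()
        ]
        used = next(a for a in alts if a.used)
        cs = ChoiceSet(
            set_id=int(set_id),
            alternatives=alts,
            anchor_m=used.x_m,
            date=str(grp["date"].iloc[0]),
            season=str(grp["season"].iloc[0]),
        )
        sets.append(cs)
    return sets


def covariate_matrix(sets: Iterable[ChoiceSet], names: Sequence[str] = COVARIATES) -> pd.DataFrame:
    """Pooled covariate values (used + available rows) as a DataFrame."""
    data = {
        n: np.array([a.covariate(n) for cs in sets for a in cs.alternatives])
        for n in names
    }
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# screening and splitting


@dataclass
class ScreenResult:
    admissible: list[CandidateModel]
    rejected: dict[str, str]
    correlation: pd.DataFrame
    flagged_constant: list[str] = field(default_factory=list)


def screen_collinearity(
    data: pd.DataFrame | Iterable[ChoiceSet],
    models: Sequence[CandidateModel],
    threshold: float = 0.6,
) -> ScreenResult:
    """Reject candidate models containing a covariate pair with
    ``|Pearson r| > threshold`` (computed over all pooled rows).

    Constant covariates have undefined correlations; models containing them
    are rejected with an explanatory reason.
    """
    if not isinstance(data, pd.DataFrame):
        data = covariate_matrix(data)
    else:
        ren = {v: k for k, v in _CSV_NAME.items()}
        data = data.rename(columns=ren)
    used_covs = sorted({c for m in models for c in m.covariates})
    for c in used_covs:
        if c not in data.columns:
            raise ChoiceDataError(f"covariate {c!r} not present in data")
    cols = [c for c in COVARIATES if c in data.columns]
    if len(data) < 3:
        raise ChoiceDataError("need at least 3 rows to screen collinearity")
    constant = [c for c in cols if float(np.std(data[c].to_numpy())) == 0.0]
    corr = data[cols].corr(method="pearson")

    admissible: list[CandidateModel] = []
    rejected: dict[str, str] = {}
    for m in models:
        bad_const = [c for c in m.covariates if c in constant]
        if bad_const:
            rejected[m.name] = f"constant covariate(s) {bad_const}: correlation undefined"
            continue
        reason = None
        for i, a in enumerate(m.covariates):
            for b in m.covariates[i + 1 :]:
                r = float(corr.loc[a, b])
                if abs(r) > threshold:
                    reason = f"|r({a},{b})| = {abs(r):.3f} > {threshold}"
                    break
            if reason:
                break
        if reason:
            rejected[m.name] = reason
        else:
            admissible.append(m)
    return ScreenResult(admissible, rejected, corr, constant)


def split_train_test(
    sets: Sequence[ChoiceSet], train_frac: float = 2.0 / 3.0, seed: int = 0
) -> tuple[list[ChoiceSet], list[ChoiceSet]]:
    """Random split by whole choice set; training count is ``n * train_frac``
    rounded to the nearest integer (235 sets -> 157 train / 78 test)."""
    n = len(sets)
    if n < 3:
        raise ChoiceDataError("need at least 3 choice sets to split")
    n_train = int(math.floor(n * train_frac + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = rng_for(seed, "split")
    order = rng.permutation(n)
    train_idx = set(order[:n_train].tolist())
    train = [cs for i, cs in enumerate(sets) if i in train_idx]
    test = [cs for i, cs in enumerate(sets) if i not in train_idx]
    return train, test
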