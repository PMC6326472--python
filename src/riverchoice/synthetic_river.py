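"""Seeded synthetic braided-river landscapes and stopover simulation.

The landscape is a width profile around a gently meandering centerline:
half-widths on each side are correlated lognormal fields, dense-vegetation
islands are elliptical patches clipped to the channel, and riparian forest
is a sequence of bank-hugging bands with random setbacks and gaps.  Geometry
is kept exact (vector) so transect measurements need no rasterization.

Stopover events are simulated by drawing candidate points uniformly by area
within the wetted channel inside a +/- window of an anchor, then selecting
the used alternative with probability proportional to
``exp(f_uocw(UOCW) + f_nf(NF))`` where each effect is a saturating ramp
``strength * min(x, plateau) / plateau``.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import LineString, MultiPolygon, Point, Polygon, shape
from shapely.strtree import STRtree

from riverchoice._rng import rng_for
from riverchoice.errors import ConfigurationError, DomainError

MIN_EXTENT_KM = 32.0  # one full availability window (16 km each side)
DEFAULT_WINDOW_M = 16_000.0
NF_CAP_M = 400.0


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic river generator.

    Defaults are tuned so that the pointwise UOCW distribution over the
    wetted channel has its 10th-90th percentile range bracketing
    [50, 450] m, and nearest-forest distances span [0, 400] m (truncated).
    """

    extent_km: float = 80.0
    centerline_step_m: float = 50.0
    meander_amp_m: float = 300.0
    meander_wavelength_km: float = 20.0
    # width field: total half-width = base * exp(g), g smooth Gaussian
    base_halfwidth_m: float = 65.0
    width_sigma: float = 1.6
    width_corr_km: float = 1.5
    width_log_clip: float = 2.6
    constriction_log_amp: float = 0.5
    constriction_wavelength_km: float = 3.0
    min_halfwidth_m: float = 15.0
    # dense vegetation islands
    veg_per_km: float = 5.0
    veg_len_range_m: tuple[float, float] = (100.0, 500.0)
    veg_rel_width_range: tuple[float, float] = (0.08, 0.25)
    veg_weight_cap_quantile: float = 0.6
    # riparian forest bands
    forest_len_mean_m: float = 1500.0
    forest_gap_mean_m: float = 1500.0
    forest_depth_range_m: tuple[float, float] = (60.0, 250.0)
    forest_setback_max_m: float = 450.0
    # flow
    n_years: int = 17
    start_year: int = 2001
    discharge_mean_cms: float = 40.0
    discharge_log_sd: float = 0.45
    wetted_fraction_range: tuple[float, float] = (0.45, 0.85)
    seed: int = 0

    def validate(self) -> None:
        if self.extent_km < MIN_EXTENT_KM:
            raise ConfigurationError(
                f"extent_km={self.extent_km} is too short: the landscape must "
                f"be at least {MIN_EXTENT_KM:.0f} km so one full 32-km "
                "availability window (16 km each side) fits."
            )
        if self.base_halfwidth_m <= 0 or self.min_halfwidth_m <= 0:
            raise ConfigurationError("width parameters must be positive")
        if self.forest_depth_range_m[0] <= 0:
            raise ConfigurationError("forest depth must be positive")


@dataclass(frozen=True)
class PlateauEffect:
    """Saturating-ramp selection effect: ``strength * min(x, plateau)/plateau``.

    ``decline`` adds a gentle linear decrease beyond the plateau onset (in
    units of the rise per plateau-length), giving the response the
    peaked-plateau shape seen in fitted selection curves; the default of 0
    keeps the effect monotone.
    """

    strength: float
    plateau_m: float
    decline: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.plateau_m < math.inf):
            raise ConfigurationError("plateau onset must be positive and finite")
        if self.decline < 0:
            raise ConfigurationError("decline must be non-negative")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        r = np.minimum(x, self.plateau_m) / self.plateau_m
        if self.decline > 0:
            r = np.where(
                x > self.plateau_m,
                1.0 - self.decline * (x - self.plateau_m) / self.plateau_m,
                r,
            )
        return self.strength * r


@dataclass(frozen=True)
class TrueSelectionSpec:
    """Generating truth for stopover simulation.

    Only UOCW and NF enter selection; all other covariates are nuisance by
    construction.  A ``strength`` of zero gives the null (uniform) model.
    """

    uocw_effect: PlateauEffect = PlateauEffect(3.0, 200.0)
    nf_effect: PlateauEffect = PlateauEffect(2.0, 160.0)
    n_use: int = 85
    n_avail: int = 20
    window_m: float = DEFAULT_WINDOW_M
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_use < 1:
            raise ConfigurationError("n_use must be >= 1")
        if self.n_avail < 1:
            raise ConfigurationError("n_avail must be >= 1")


# ---------------------------------------------------------------------------
# landscape


@dataclass
class RiverLandscape:
    """Vector model of channel, vegetation and forest geometry.

    The along-channel coordinate of a point is its arc-length projection
    onto ``centerline`` (metres from the upstream end).
    """

    centerline: LineString
    channel_polygon: Polygon
    dense_veg_patches: list[Polygon]
    forest_patches: list[Polygon]
    discharge: dict[str, float]
    wetted_fraction: dict[str, float]
    extent_km: float
    config: LandscapeConfig | None = None

    _open_water: Polygon = field(init=False, repr=False)
    _veg_tree: STRtree | None = field(init=False, repr=False)
    _forest_tree: STRtree | None = field(init=False, repr=False)
    _max_halfwidth: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        veg = shapely.union_all(self.dense_veg_patches) if self.dense_veg_patches else None
        self._open_water = (
            self.channel_polygon.difference(veg) if veg is not None else self.channel_polygon
        )
        self._veg_tree = STRtree(self.dense_veg_patches) if self.dense_veg_patches else None
        self._forest_tree = STRtree(self.forest_patches) if self.forest_patches else None
        # generous transect half-length: distance from centerline to the
        # farthest channel-boundary vertex
        bx, by = self.channel_polygon.exterior.coords.xy
        pts = shapely.points(np.asarray(bx), np.asarray(by))
        self._max_halfwidth = float(np.max(shapely.distance(self.centerline, pts)))
        shapely.prepare(self.channel_polygon)
        shapely.prepare(self._open_water)
        # vertex tables for the fast arc-length projector
        cx, cy = self.centerline.coords.xy
        self._cl_x = np.asarray(cx)
        self._cl_y = np.asarray(cy)
        seg = np.hypot(np.diff(self._cl_x), np.diff(self._cl_y))
        self._cl_cum = np.concatenate([[0.0], np.cumsum(seg)])
        self._cl_x_monotone = bool(np.all(np.diff(self._cl_x) > 0))

    # -- coordinate helpers -------------------------------------------------

    @property
    def length_m(self) -> float:
        return float(self.centerline.length)

    def arc_coord(self, point: Point) -> float:
        """Arc-length coordinate (m) of ``point`` projected on the centerline."""
        return float(self._project_xy(np.array([point.x]), np.array([point.y]))[0])

    def arc_coords(self, points: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`arc_coord` for an array of shapely points."""
        return self._project_xy(shapely.get_x(points), shapely.get_y(points))

    def _project_xy(self, px: np.ndarray, py: np.ndarray, window: int = 60) -> np.ndarray:
        """Arc-length projection onto the centerline.

        The generated centerline advances monotonically in x, so only
        segments within ``window`` vertices of the point's x position can be
        nearest; this restricted search matches shapely's
        ``line_locate_point`` but is vectorized over points.  Centerlines
        that do not advance monotonically in x fall back to shapely.
        """
        if not self._cl_x_monotone:
            return shapely.line_locate_point(self.centerline, shapely.points(px, py))
        vx, vy, cum = self._cl_x, self._cl_y, self._cl_cum
        n_seg = vx.size - 1
        i0 = np.clip(np.searchsorted(vx, px) - 1, 0, n_seg - 1)
        offs = np.arange(-window, window + 1)
        k = np.clip(i0[:, None] + offs[None, :], 0, n_seg - 1)  # (n, 2w+1)
        ax, ay = vx[k], vy[k]
        dx, dy = vx[k + 1] - ax, vy[k + 1] - ay
        seg2 = dx * dx + dy * dy
        t = np.clip(((px[:, None] - ax) * dx + (py[:, None] - ay) * dy) / seg2, 0.0, 1.0)
        qx = ax + t * dx - px[:, None]
        qy = ay + t * dy - py[:, None]
        d2 = qx * qx + qy * qy
        best = np.argmin(d2, axis=1)
        rows = np.arange(px.size)
        kb = k[rows, best]
        return cum[kb] + t[rows, best] * np.sqrt(seg2[rows, best])

    def contains(self, point: Point) -> bool:
        """True if the point is strictly inside the channel polygon."""
        return bool(self.channel_polygon.contains(point))

    def in_open_water(self, point: Point) -> bool:
        """True if inside the channel and not on a dense-vegetation island."""
        return bool(self._open_water.contains(point))

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent of the centerline at arc-length ``s``."""
        eps = 1.0
        a = self.centerline.interpolate(max(s - eps, 0.0))
        b = self.centerline.interpolate(min(s + eps, self.length_m))
        v = np.array([b.x - a.x, b.y - a.y])
        n = np.hypot(*v)
        if n == 0:  # pragma: no cover - degenerate centerline
            return np.array([1.0, 0.0])
        return v / n

    def transect_reach(self) -> float:
        # a point near one bank can face a far bank ~2 half-widths away
        return 2.0 * self._max_halfwidth + 200.0

    # -- sampling -----------------------------------------------------------

    def sample_points(
        self,
        anchor_m: float,
        n: int,
        rng: np.random.Generator,
        window_m: float = DEFAULT_WINDOW_M,
    ) -> list[Point]:
        """Draw ``n`` points uniformly by area in the wetted (open-water)
        channel with arc coordinate within ``anchor_m +/- window_m``.

        Uses rejection sampling from the bounding box of the windowed reach.
        """
        lo = max(anchor_m - window_m, 0.0)
        hi = min(anchor_m + window_m, self.length_m)
        if hi <= lo:
            raise DomainError(f"empty availability window around anchor {anchor_m} m")
        minx, miny, maxx, maxy = self._open_water.bounds
        # along-channel coordinate tracks x closely; pad for meander slack
        bx_lo, bx_hi = max(lo - 500.0, minx), min(hi + 500.0, maxx)
        out: list[Point] = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 200:  # pragma: no cover - pathological geometry
                raise DomainError(
                    f"rejection sampling failed near anchor {anchor_m} m"
                )
            m = max(64 * (n - len(out)), 256)
            xs = rng.uniform(bx_lo, bx_hi, m)
            ys = rng.uniform(miny, maxy, m)
            pts = shapely.points(xs, ys)
            ok = shapely.contains(self._open_water, pts)
            if not ok.any():
                continue
            cand = pts[ok]
            s = self._project_xy(shapely.get_x(cand), shapely.get_y(cand))
            cand = cand[(s >= lo) & (s <= hi)]
            out.extend(cand[: n - len(out)])
        return [Point(p.x, p.y) for p in out]

    def sample_date(self, rng: np.random.Generator) -> str:
        dates = sorted(self.discharge)
        return dates[int(rng.integers(len(dates)))]

    # -- serialization ------------------------------------------------------

    def to_geojson(self) -> str:
        """Serialize to a GeoJSON FeatureCollection (local planar metres)."""
        def coords(geom):
            return json.loads(shapely.to_geojson(geom, indent=None))

        features = [
            {
                "type": "Feature",
                "properties": {"role": "centerline"},
                "geometry": coords(self.centerline),
            },
            {
                "type": "Feature",
                "properties": {"role": "channel"},
                "geometry": coords(self.channel_polygon),
            },
        ]
        for role, polys in (
            ("dense_veg", self.dense_veg_patches),
            ("forest", self.forest_patches),
        ):
            for p in polys:
                features.append(
                    {
                        "type": "Feature",
                        "properties": {"role": role},
                        "geometry": coords(p),
                    }
                )
        doc = {
            "type": "FeatureCollection",
            "properties": {
                "crs": "local planar metres",
                "extent_km": self.extent_km,
                "discharge_cms": self.discharge,
                "wetted_fraction": self.wetted_fraction,
            },
            "features": features,
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_geojson(cls, text: str) -> "RiverLandscape":
        doc = json.loads(text)
        props = doc.get("properties", {})
        centerline = None
        channel = None
        veg: list[Polygon] = []
        forest: list[Polygon] = []
        for feat in doc["features"]:
            role = feat["properties"]["role"]
            geom = shape(feat["geometry"])
            if role == "centerline":
                centerline = geom
            elif role == "channel":
                channel = geom
            elif role == "dense_veg":
                veg.append(geom)
            elif role == "forest":
                forest.append(geom)
        if centerline is None or channel is None:
            raise ConfigurationError("GeoJSON landscape missing centerline or channel")
        return cls(
            centerline=centerline,
            channel_polygon=channel,
            dense_veg_patches=veg,
            forest_patches=forest,
            discharge=dict(props.get("discharge_cms", {})),
            wetted_fraction=dict(props.get("wetted_fraction", {})),
            extent_km=float(props.get("extent_km", centerline.length / 1000.0)),
        )


# ---------------------------------------------------------------------------
# generator internals


def _smooth_field(rng: np.random.Generator, x: np.ndarray, corr_m: float) -> np.ndarray:
    """Unit-variance smooth Gaussian field on grid ``x`` (correlation length
    ``corr_m``), built by kernel-smoothing white noise on a coarse grid."""
    step = corr_m / 4.0
    knots = np.arange(x[0] - 4 * corr_m, x[-1] + 4 * corr_m + step, step)
    z = rng.standard_normal(knots.size)
    half = int(round(4 * corr_m / step))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) * step / corr_m) ** 2)
    sm = np.convolve(z, k / np.sqrt(np.sum(k**2)), mode="same")
    return np.interp(x, knots, sm)


def _season_dates(cfg: LandscapeConfig) -> list[_dt.date]:
    out = []
    for year in range(cfg.start_year, cfg.start_year + cfg.n_years):
        d = _dt.date(year, 3, 21)
        while d <= _dt.date(year, 4, 29):
            out.append(d)
            d += _dt.timedelta(days=1)
        d = _dt.date(year, 10, 9)
        while d <= _dt.date(year, 11, 10):
            out.append(d)
            d += _dt.timedelta(days=1)
    return out


def season_of(date_iso: str) -> str:
    month = int(date_iso.split("-")[1])
    return "spring" if month < 7 else "fall"


def _as_polygons(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return [g for g in geom.geoms if g.area > 1.0]
    return []


def generate_landscape(
    config: LandscapeConfig | None = None, *, seed: int | None = None
) -> RiverLandscape:
    """Generate a seeded synthetic river landscape.

    Deterministic: the same configuration and seed always produce an
    identical landscape (byte-identical GeoJSON).
    """
    cfg = config or LandscapeConfig()
    if seed is not None:
        cfg = LandscapeConfig(**{**cfg.__dict__, "seed": seed})
    cfg.validate()

    length_m = cfg.extent_km * 1000.0
    x = np.arange(0.0, length_m + cfg.centerline_step_m, cfg.centerline_step_m)

    # centerline: long sine meander plus a softer random wander
    rng_c = rng_for(cfg.seed, "centerline")
    wave = 2 * np.pi * x / (cfg.meander_wavelength_km * 1000.0)
    y = cfg.meander_amp_m * np.sin(wave + rng_c.uniform(0, 2 * np.pi))
    y += 0.3 * cfg.meander_amp_m * _smooth_field(rng_c, x, 8000.0)
    centerline = LineString(np.column_stack([x, y]))

    # width profile (total half-width, split asymmetrically left/right)
    rng_w = rng_for(cfg.seed, "width")
    g = np.clip(
        cfg.width_sigma * _smooth_field(rng_w, x, cfg.width_corr_km * 1000.0),
        -cfg.width_log_clip,
        cfg.width_log_clip,
    )
    # periodic constrictions guarantee narrow reaches in every realization
    g += cfg.constriction_log_amp * np.sin(
        2 * np.pi * x / (cfg.constriction_wavelength_km * 1000.0)
        + rng_w.uniform(0, 2 * np.pi)
    )
    half_total = np.maximum(cfg.base_halfwidth_m * np.exp(g), 2 * cfg.min_halfwidth_m)
    frac = 0.5 + 0.2 * np.tanh(_smooth_field(rng_w, x, 6000.0))
    h_left = np.maximum(half_total * frac, cfg.min_halfwidth_m)
    h_right = np.maximum(half_total * (1 - frac), cfg.min_halfwidth_m)

    # bank lines offset along centerline normals
    dx = np.gradient(x)
    dy = np.gradient(y)
    norm = np.hypot(dx, dy)
    nx, ny = -dy / norm, dx / norm
    left = np.column_stack([x + nx * h_left, y + ny * h_left])
    right = np.column_stack([x - nx * h_right, y - ny * h_right])
    channel = Polygon(np.vstack([left, right[::-1]]))
    if not channel.is_valid:  # rare self-touching offsets at sharp meanders
        channel = channel.buffer(0)
        if isinstance(channel, MultiPolygon):
            channel = max(channel.geoms, key=lambda p: p.area)

    # dense vegetation islands: ellipses aligned to the local tangent
    rng_v = rng_for(cfg.seed, "veg")
    n_veg = int(rng_v.poisson(cfg.veg_per_km * cfg.extent_km))
    veg: list[Polygon] = []
    # islands are placed width-weighted (wide reaches braid) but the weight is
    # capped so the very widest water keeps open reaches
    w_cap = np.quantile(half_total, cfg.veg_weight_cap_quantile)
    cum_w = np.cumsum(np.minimum(half_total, w_cap))
    for _ in range(n_veg):
        s0 = float(np.interp(rng_v.uniform(0, cum_w[-1]), cum_w, x))
        i = min(int(s0 / cfg.centerline_step_m), x.size - 1)
        u = rng_v.uniform(-0.6, 0.6)  # relative cross-channel position
        cx = x[i] + nx[i] * u * half_total[i]
        cy = y[i] + ny[i] * u * half_total[i]
        a = rng_v.uniform(*cfg.veg_len_range_m) / 2.0
        b = rng_v.uniform(*cfg.veg_rel_width_range) * half_total[i]
        ang = math.degrees(math.atan2(dy[i], dx[i]))
        ell = shapely.affinity.rotate(
            shapely.affinity.scale(Point(cx, cy).buffer(1.0, quad_segs=8), a, b),
            ang,
        )
        veg.extend(_as_polygons(ell.intersection(channel)))

    # riparian forest: bank bands with random setback, depth and gaps
    rng_f = rng_for(cfg.seed, "forest")
    forest: list[Polygon] = []
    for side, h_side, sign in (("left", h_left, 1.0), ("right", h_right, -1.0)):
        s = rng_f.exponential(cfg.forest_gap_mean_m)
        while s < length_m:
            seg_len = rng_f.exponential(cfg.forest_len_mean_m) + 200.0
            s1 = min(s + seg_len, length_m)
            i0 = int(s / cfg.centerline_step_m)
            i1 = max(int(s1 / cfg.centerline_step_m), i0 + 2)
            i1 = min(i1, x.size - 1)
            if rng_f.uniform() < 0.5:
                setback = rng_f.uniform(0.0, 60.0)
            else:
                setback = rng_f.uniform(60.0, cfg.forest_setback_max_m)
            depth = rng_f.uniform(*cfg.forest_depth_range_m)
            sl = slice(i0, i1 + 1)
            inner = np.column_stack(
                [
                    x[sl] + sign * nx[sl] * (h_side[sl] + setback),
                    y[sl] + sign * ny[sl] * (h_side[sl] + setback),
                ]
            )
            outer = np.column_stack(
                [
                    x[sl] + sign * nx[sl] * (h_side[sl] + setback + depth),
                    y[sl] + sign * ny[sl] * (h_side[sl] + setback + depth),
                ]
            )
            band = Polygon(np.vstack([inner, outer[::-1]]))
            if not band.is_valid:
                band = band.buffer(0)
            forest.extend(_as_polygons(band.difference(channel)))
            s = s1 + rng_f.exponential(cfg.forest_gap_mean_m)

    # per-date discharge (lognormal) and wetted fraction
    rng_q = rng_for(cfg.seed, "discharge")
    dates = _season_dates(cfg)
    q = cfg.discharge_mean_cms * np.exp(
        rng_q.normal(-0.5 * cfg.discharge_log_sd**2, cfg.discharge_log_sd, len(dates))
    )
    wf = rng_q.uniform(*cfg.wetted_fraction_range, len(dates))
    discharge = {d.isoformat(): round(float(v), 4) for d, v in zip(dates, q)}
    wetted = {d.isoformat(): round(float(v), 4) for d, v in zip(dates, wf)}

    return RiverLandscape(
        centerline=centerline,
        channel_polygon=channel,
        dense_veg_patches=veg,
        forest_patches=forest,
        discharge=discharge,
        wetted_fraction=wetted,
        extent_km=cfg.extent_km,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# stopover simulation


def simulate_stopovers(landscape: RiverLandscape, spec: TrueSelectionSpec):
    """Simulate stopover choice sets from a known selection truth.

    For each stopover an anchor is drawn so the full window fits inside the
    landscape, ``n_avail + 1`` candidates are sampled uniformly in the open
    channel within the window, and the used alternative is drawn with
    probability proportional to ``exp(f_uocw + f_nf)``.  Returns a list of
    :class:`riverchoice.choice_sets.ChoiceSet`.
    """
    from riverchoice.choice_sets import Alternative, ChoiceSet
    from riverchoice.habitat_metrics import flow_metrics, measure_nf, measure_widths

    length = landscape.length_m
    w = spec.window_m
    lo, hi = w, length - w
    if hi < lo:
        raise ConfigurationError(
            "landscape shorter than one availability window; need extent >= "
            f"{2 * w / 1000:.0f} km"
        )
    sets: list[ChoiceSet] = []
    for i in range(spec.n_use):
        rng = rng_for(spec.seed, "stopover", i)
        anchor = float(rng.uniform(lo, hi)) if hi > lo else lo
        date = landscape.sample_date(rng)
        pts = None
        for _ in range(100):
            try:
                pts = landscape.sample_points(anchor, spec.n_avail + 1, rng, w)
                break
            except DomainError:
                anchor = float(rng.uniform(lo, hi)) if hi > lo else lo
        if pts is None:
            raise DomainError(f"could not place stopover window after 100 tries (set {i})")

        q = landscape.discharge[date]
        wf = landscape.wetted_fraction[date]
        alts = []
        eta = np.empty(len(pts))
        for j, p in enumerate(pts):
            uocw, tcw, ufcw = measure_widths(landscape, p)
            nf = measure_nf(landscape, p)
            ud, dis = flow_metrics(q, wf * tcw, tcw)
            eta[j] = spec.uocw_effect(uocw) + spec.nf_effect(nf)
            alts.append(
                Alternative(
                    alt_id=j,
                    used=False,
                    x_m=landscape.arc_coord(p),
                    uocw=uocw,
                    tcw=tcw,
                    ufcw=ufcw,
                    nf=nf,
                    ud=ud,
                    dis=dis,
                    px=p.x,
                    py=p.y,
                )
            )
        prob = np.exp(eta - eta.max())
        prob /= prob.sum()
        used_idx = int(rng.choice(len(alts), p=prob))
        alts[used_idx].used = True
        sets.append(
            ChoiceSet(
                set_id=i,
                alternatives=alts,
                anchor_m=anchor,
                window_m=w,
                date=date,
                season=season_of(date),
            )
        )
    return sets
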