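"""Penalized-spline conditional multinomial logit (discrete-choice GAM).

The model gives each alternative ``j`` of choice set ``i`` a weight
``w(x_ij) = exp(s_1(x1_ij) + ... + s_p(xp_ij))`` and the probability that
the used alternative was chosen is ``w(chosen) / sum_j w(alt_j)``.  Each
smooth ``s`` is a centered cubic B-spline expansion with a second-order
difference penalty; smoothing parameters are chosen on a log-spaced grid by
a GCV-style score, the inner problem is solved by penalized Newton, and
model complexity is summarized by trace-based effective degrees of freedom
(EDF).  AIC uses the unpenalized log-likelihood at the penalized optimum
plus total EDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

from riverchoice.choice_sets import CandidateModel, ChoiceSet
from riverchoice.errors import DomainError, FitError

DEFAULT_BASIS_DIM = 4  # keeps max smooth df below four (3 after centering)
DEFAULT_LAMBDA_GRID = np.logspace(-4, 6, 25)
NEWTON_TOL = 1e-8
NEWTON_MAX_ITER = 200
SEPARATION_NORM = 1e4
EDF_LINEAR_TOL = 0.05


# ---------------------------------------------------------------------------
# spline basis


@dataclass
class SplineBasis:
    """Centered cubic B-spline design with a second-difference penalty.

    ``design`` / ``penalty`` are the identifiable (centered) versions used in
    fitting; ``raw_design`` / ``raw_penalty`` are kept for inspection.  The
    centering constraint (columns sum to zero over the supplied values) is
    absorbed into ``transform`` so prediction uses the same parameterization.
    """

    knots: np.ndarray
    lo: float
    hi: float
    basis_dim: int
    transform: np.ndarray  # (k, k-1) null-space reparameterization
    raw_design: np.ndarray
    raw_penalty: np.ndarray
    design: np.ndarray
    penalty: np.ndarray

    def evaluate_raw(self, x: np.ndarray, clamp: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if clamp:
            if np.any((x < self.lo) | (x > self.hi)):
                warnings.warn(
                    "covariate values outside the fitted range were clamped",
                    stacklevel=2,
                )
            x = np.clip(x, self.lo, self.hi)
        elif np.any((x < self.lo) | (x > self.hi)):
            raise DomainError(
                f"values outside the basis range [{self.lo:g}, {self.hi:g}]"
            )
        # nudge the right endpoint inside so the last basis function is 1 there
        x = np.minimum(x, np.nextafter(self.hi, self.lo))
        return BSpline.design_matrix(x, self.knots, 3).toarray()

    def evaluate(self, x: np.ndarray, clamp: bool = False) -> np.ndarray:
        return self.evaluate_raw(x, clamp=clamp) @ self.transform


def spline_basis(
    x: np.ndarray, basis_dim: int = DEFAULT_BASIS_DIM, rng: tuple[float, float] | None = None
) -> SplineBasis:
    """Build a centered cubic B-spline basis over ``x`` (or over ``rng``).

    The raw basis is a partition of unity; the raw penalty is the
    second-order difference penalty ``D2' D2`` (rank ``basis_dim - 2``).
    Centering removes one dimension, so the centered design has
    ``basis_dim - 1`` columns and its penalty null space spans linear trends.
    """
    if basis_dim < 3:
        raise DomainError("basis_dim must be >= 3")
    x = np.asarray(x, dtype=float)
    lo, hi = rng if rng is not None else (float(x.min()), float(x.max()))
    if not hi > lo:
        raise DomainError("degenerate covariate range for spline basis")
    n_interior = basis_dim - 4
    if n_interior < 0:
        raise DomainError("cubic basis needs basis_dim >= 4")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])

    d2 = np.diff(np.eye(basis_dim), n=2, axis=0)
    raw_penalty = d2.T @ d2

    basis = SplineBasis(
        knots=knots,
        lo=lo,
        hi=hi,
        basis_dim=basis_dim,
        transform=np.eye(basis_dim),
        raw_design=np.empty((0, basis_dim)),
        raw_penalty=raw_penalty,
        design=np.empty((0, basis_dim)),
        penalty=raw_penalty,
    )
    raw = basis.evaluate_raw(x)
    cmean = raw.mean(axis=0, keepdims=True)
    z = null_space(cmean)  # (k, k-1)
    basis.transform = z
    basis.raw_design = raw
    basis.design = raw @ z
    basis.penalty = z.T @ raw_penalty @ z
    return basis


# ---------------------------------------------------------------------------
# design assembly


@dataclass
class TermDesign:
    """Columns of the model design belonging to one covariate."""

    covariate: str
    smooth: bool
    cols: slice
    basis: SplineBasis | None = None  # smooth terms
    center: float = 0.0  # linear terms: x - center

    @property
    def n_cols(self) -> int:
        return self.cols.stop - self.cols.start

    def columns_for(self, x: np.ndarray, clamp: bool = False) -> np.ndarray:
        if self.smooth:
            assert self.basis is not None
            return self.basis.evaluate(x, clamp=clamp)
        return (np.asarray(x, dtype=float) - self.center)[:, None]


@dataclass
class ModelDesign:
    """Stacked design over all alternatives of all sets (rows grouped by set)."""

    model: CandidateModel
    terms: list[TermDesign]
    X: np.ndarray  # (N, p)
    starts: np.ndarray  # first row of each set
    set_sizes: np.ndarray
    used_rows: np.ndarray  # row index of the chosen alternative per set
    n_sets: int

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def penalty_blocks(self) -> list[tuple[slice, np.ndarray]]:
        return [
            (t.cols, t.basis.penalty)
            for t in self.terms
            if t.smooth and t.basis is not None
        ]

    def total_penalty(self, lambdas: dict[str, float]) -> np.ndarray:
        p = self.n_params
        S = np.zeros((p, p))
        for t in self.terms:
            if t.smooth and t.basis is not None:
                S[t.cols, t.cols] += lambdas.get(t.covariate, 0.0) * t.basis.penalty
        return S

    def design_row(self, values: dict[str, np.ndarray], clamp: bool = True) -> np.ndarray:
        """Design rows for arbitrary covariate values (prediction)."""
        n = len(next(iter(values.values()))) if values else 1
        out = np.zeros((n, self.n_params))
        for t in self.terms:
            out[:, t.cols] = t.columns_for(np.asarray(values[t.covariate], float), clamp=clamp)
        return out


def build_design(
    sets: Sequence[ChoiceSet],
    model: CandidateModel,
    basis_dim: int = DEFAULT_BASIS_DIM,
) -> ModelDesign:
    """Assemble the stacked design matrix for ``model`` over ``sets``."""
    sizes = []
    used_local = []
    cov_values: dict[str, list[float]] = {c: [] for c in model.covariates}
    for cs in sets:
        used = cs.used_alternative()
        sizes.append(cs.n_alternatives)
        used_local.append(cs.alternatives.index(used))
        for c in model.covariates:
            vals = [a.covariate(c) for a in cs.alternatives]
            if not np.all(np.isfinite(vals)):
                raise DomainError(f"non-finite covariate {c!r} in set {cs.set_id}")
            cov_values[c].extend(vals)

    sizes_arr = np.asarray(sizes, dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(sizes_arr)[:-1]])
    used_rows = starts + np.asarray(used_local, dtype=np.int64)
    n_rows = int(sizes_arr.sum())

    terms: list[TermDesign] = []
    blocks: list[np.ndarray] = []
    col = 0
    for cov, smooth in model.terms:
        x = np.asarray(cov_values[cov], dtype=float)
        if smooth:
            basis = spline_basis(x, basis_dim=basis_dim)
            block = basis.design
            terms.append(
                TermDesign(cov, True, slice(col, col + block.shape[1]), basis=basis)
            )
        else:
            center = float(x.mean())
            block = (x - center)[:, None]
            terms.append(TermDesign(cov, False, slice(col, col + 1), center=center))
        blocks.append(block)
        col += block.shape[1]
    X = np.hstack(blocks) if blocks else np.empty((n_rows, 0))
    return ModelDesign(
        model=model,
        terms=terms,
        X=X,
        starts=starts,
        set_sizes=sizes_arr,
        used_rows=used_rows,
        n_sets=len(sets),
    )


# ---------------------------------------------------------------------------
# likelihood


def _loglik_parts(beta: np.ndarray, design: ModelDesign):
    """Unpenalized log-likelihood, per-row choice probabilities and per-set
    log-sum-exp (all numerically stabilized)."""
    eta = design.X @ beta if design.n_params else np.zeros(design.X.shape[0])
    mx = np.maximum.reduceat(eta, design.starts)
    shifted = np.exp(eta - np.repeat(mx, design.set_sizes))
    denom = np.add.reduceat(shifted, design.starts)
    lse = mx + np.log(denom)
    ll = float(np.sum(eta[design.used_rows] - lse))
    p = shifted / np.repeat(denom, design.set_sizes)
    return ll, p


def conditional_loglik(
    params: np.ndarray, sets: Sequence[ChoiceSet], model: CandidateModel, basis_dim: int = DEFAULT_BASIS_DIM
) -> float:
    """Conditional multinomial-logit log-likelihood at ``params``:
    ``sum_i [eta(chosen_i) - logsumexp_j eta_ij]``."""
    design = build_design(sets, model, basis_dim=basis_dim)
    params = np.asarray(params, dtype=float)
    if params.shape != (design.n_params,):
        raise DomainError(
            f"params has shape {params.shape}; model needs {design.n_params} coefficients"
        )
    ll, _ = _loglik_parts(params, design)
    return ll


def _gradient_hessian(beta: np.ndarray, design: ModelDesign):
    """Gradient and negative Hessian (observed information) of the
    unpenalized log-likelihood."""
    ll, p = _loglik_parts(beta, design)
    X = design.X
    y = np.zeros(X.shape[0])
    y[design.used_rows] = 1.0
    grad = X.T @ (y - p)
    pX = p[:, None] * X
    M = np.add.reduceat(pX, design.starts, axis=0)  # (n_sets, p): E[x | set]
    H = X.T @ pX - M.T @ M
    return ll, grad, H


def _newton(
    design: ModelDesign,
    S: np.ndarray,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, bool, str]:
    """Penalized Newton with step halving.  Returns (beta, converged, note)."""
    p = design.n_params
    beta = np.zeros(p) if beta0 is None else beta0.copy()

    def pen_ll(b):
        ll, _ = _loglik_parts(b, design)
        return ll - 0.5 * float(b @ S @ b)

    def separated(b) -> bool:
        if np.max(np.abs(b)) > SEPARATION_NORM:
            return True
        if design.n_params:
            eta = design.X @ b
            return bool(eta.max() - eta.min() > 100.0)
        return False

    note = ""
    for _ in range(NEWTON_MAX_ITER):
        ll, grad, H = _gradient_hessian(beta, design)
        g_pen = grad - S @ beta
        if np.max(np.abs(g_pen)) < NEWTON_TOL:
            if separated(beta):
                return beta, False, "coefficient norm diverged (possible complete separation)"
            return beta, True, note
        Hp = H + S
        try:
            step = np.linalg.solve(Hp + 1e-10 * np.eye(p), g_pen)
        except np.linalg.LinAlgError:  # pragma: no cover - heavy regularization path
            step = np.linalg.lstsq(Hp, g_pen, rcond=None)[0]
        f0 = ll - 0.5 * float(beta @ S @ beta)
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            if pen_ll(cand) > f0 - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if np.max(np.abs(beta)) > SEPARATION_NORM:
            return beta, False, "coefficient norm diverged (possible complete separation)"
        if separated(beta):
            return beta, False, "coefficient norm diverged (possible complete separation)"
    return beta, False, "no convergence in Newton iteration limit"


# ---------------------------------------------------------------------------
# EDF


def _edf_from_information(
    H: np.ndarray, S: np.ndarray, term_slices: dict[str, slice]
) -> tuple[dict[str, float], float]:
    """Trace-based EDF: block traces of ``(H + S)^-1 H``."""
    if H.size == 0:
        return {}, 0.0
    Hp = H + S
    try:
        A = np.linalg.solve(Hp, H)
    except np.linalg.LinAlgError:
        warnings.warn("singular penalized information; using pseudo-inverse", stacklevel=2)
        A = np.linalg.pinv(Hp) @ H
    per_term = {name: float(np.trace(A[sl, sl])) for name, sl in term_slices.items()}
    return per_term, float(np.trace(A))


# ---------------------------------------------------------------------------
# fit result


@dataclass
class DCGAMFit:
    """A fitted penalized-spline discrete-choice model."""

    model: CandidateModel
    design: ModelDesign = field(repr=False)
    beta: np.ndarray
    lambdas: dict[str, float]
    loglik: float
    penalized_loglik: float
    edf_per_term: dict[str, float]
    total_edf: float
    aic: float
    coef_covariance: np.ndarray
    converged: bool
    n_sets: int
    basis_dim: int
    gcv_score: float = float("nan")
    note: str = ""
    _information: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def name(self) -> str:
        return self.model.name

    @property
    def n_covariates(self) -> int:
        return len(self.model.covariates)

    def predict_eta(self, values: dict[str, np.ndarray], clamp: bool = True):
        """Linear predictor and its delta-method standard error at arbitrary
        covariate values (all model covariates must be supplied)."""
        rows = self.design.design_row(values, clamp=clamp)
        eta = rows @ self.beta if self.design.n_params else np.zeros(rows.shape[0])
        if self.design.n_params:
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", rows, self.coef_covariance, rows), 0.0))
        else:
            se = np.zeros_like(eta)
        return eta, se

    def predict_weights(self, sets: Iterable[ChoiceSet], clamp: bool = True) -> np.ndarray:
        """Unnormalized selection weights ``exp(eta)`` for every alternative
        of ``sets`` (row order: sets in order, alternatives in order)."""
        values = {
            c: np.array([a.covariate(c) for cs in sets for a in cs.alternatives])
            for c in self.model.covariates
        }
        if not self.model.covariates:
            n = sum(cs.n_alternatives for cs in sets)
            return np.ones(n)
        rows = self.design.design_row(values, clamp=clamp)
        eta = rows @ self.beta
        return np.exp(eta - eta.max())

    def to_dict(self) -> dict:
        return {
            "model": self.name,
            "covariates": list(self.model.covariates),
            "smooth": list(self.model.smooth),
            "coefficients": self.beta.tolist(),
            "lambdas": self.lambdas,
            "loglik": self.loglik,
            "edf_per_term": self.edf_per_term,
            "total_edf": self.total_edf,
            "aic": self.aic,
            "converged": self.converged,
            "n_sets": self.n_sets,
            "basis_dim": self.basis_dim,
            "gcv_score": self.gcv_score,
            "covariance": self.coef_covariance.tolist(),
            "note": self.note,
        }


def effective_df(fit: DCGAMFit) -> tuple[dict[str, float], float]:
    """Recompute trace-based EDF per term and in total from the fit."""
    slices = {t.covariate: t.cols for t in fit.design.terms}
    S = fit.design.total_penalty(fit.lambdas)
    return _edf_from_information(fit._information, S, slices)


# ---------------------------------------------------------------------------
# fitting


def _gcv_score(ll: float, n_sets: int, total_edf: float) -> float:
    denom = n_sets - total_edf
    if denom <= 0:
        return float("inf")
    return n_sets * (-2.0 * ll) / denom**2


def _fit_at_lambdas(
    design: ModelDesign, lambdas: dict[str, float], beta0: np.ndarray | None
):
    S = design.total_penalty(lambdas)
    beta, converged, note = _newton(design, S, beta0)
    ll, _, H = _gradient_hessian(beta, design)
    slices = {t.covariate: t.cols for t in design.terms}
    edf_per_term, total_edf = _edf_from_information(H, S, slices)
    return beta, converged, note, ll, H, S, edf_per_term, total_edf


def fit_dcgam(
    sets: Sequence[ChoiceSet],
    model: CandidateModel,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    basis_dim: int = DEFAULT_BASIS_DIM,
    lambdas: dict[str, float] | None = None,
) -> DCGAMFit:
    """Fit the discrete-choice GAM for ``model`` on ``sets``.

    Inner loop: penalized Newton on the conditional log-likelihood minus
    ``0.5 * sum_p lambda_p b' S_p b``.  Outer loop: each smooth term's
    smoothing parameter is chosen on a log-spaced grid by minimizing
    ``n * (-2 ll) / (n - EDF_total)^2`` with ``n`` the number of choice sets
    (coordinate descent when there are several smooth terms).  Fully
    deterministic; ``seed`` is accepted for interface symmetry only.

    Pass ``lambdas`` to skip the outer search and fit at fixed smoothing
    parameters.
    """
    sets = list(sets)
    if not sets:
        raise FitError("no choice sets supplied")
    design = build_design(sets, model, basis_dim=basis_dim)
    n_sets = design.n_sets

    if design.n_params == 0:  # null model
        ll, _ = _loglik_parts(np.zeros(0), design)
        return DCGAMFit(
            model=model,
            design=design,
            beta=np.zeros(0),
            lambdas={},
            loglik=ll,
            penalized_loglik=ll,
            edf_per_term={},
            total_edf=0.0,
            aic=-2.0 * ll,
            coef_covariance=np.zeros((0, 0)),
            converged=True,
            n_sets=n_sets,
            basis_dim=basis_dim,
            gcv_score=_gcv_score(ll, n_sets, 0.0),
            _information=np.zeros((0, 0)),
        )

    grid = np.asarray(lambda_grid if lambda_grid is not None else DEFAULT_LAMBDA_GRID, float)
    smooth_covs = [t.covariate for t in design.terms if t.smooth]

    if lambdas is not None:
        lam = {c: float(lambdas.get(c, 0.0)) for c in smooth_covs}
        beta0 = None
    elif not smooth_covs:
        lam = {}
        beta0 = None
    else:
        lam = {c: 1.0 for c in smooth_covs}
        beta0 = None
        n_sweeps = 1 if len(smooth_covs) == 1 else 2
        for _ in range(n_sweeps):
            for cov in smooth_covs:
                best = (np.inf, lam[cov], None)
                for lv in grid:
                    trial = {**lam, cov: float(lv)}
                    beta, conv, _, ll, _, _, _, total_edf = _fit_at_lambdas(
                        design, trial, beta0
                    )
                    score = _gcv_score(ll, n_sets, total_edf) if conv else np.inf
                    if score < best[0]:
                        best = (score, float(lv), beta)
                if best[2] is not None:
                    lam[cov] = best[1]
                    beta0 = best[2]

    beta, converged, note, ll, H, S, edf_per_term, total_edf = _fit_at_lambdas(
        design, lam, beta0
    )
    Hp = H + S
    try:
        cov = np.linalg.inv(Hp)
    except np.linalg.LinAlgError:  # pragma: no cover
        warnings.warn("singular penalized information; covariance via pseudo-inverse", stacklevel=2)
        cov = np.linalg.pinv(Hp)
    return DCGAMFit(
        model=model,
        design=design,
        beta=beta,
        lambdas=lam,
        loglik=ll,
        penalized_loglik=ll - 0.5 * float(beta @ S @ beta),
        edf_per_term=edf_per_term,
        total_edf=total_edf,
        aic=-2.0 * ll + 2.0 * total_edf,
        coef_covariance=cov,
        converged=converged,
        n_sets=n_sets,
        basis_dim=basis_dim,
        gcv_score=_gcv_score(ll, n_sets, total_edf),
        note=note,
        _information=H,
    )


def linear_fallback(
    fit: DCGAMFit, sets: Sequence[ChoiceSet] | None = None, tol: float = EDF_LINEAR_TOL
) -> DCGAMFit:
    """Refit with any smooth term whose EDF is within ``tol`` of 1 entered as
    a parametric straight line.  Returns the original fit unchanged when no
    term qualifies."""
    to_linear = [
        t.covariate
        for t in fit.design.terms
        if t.smooth and abs(fit.edf_per_term.get(t.covariate, np.inf) - 1.0) <= tol
    ]
    if not to_linear:
        return fit
    model = fit.model
    for cov in to_linear:
        model = model.with_linear(cov)
    if sets is None:
        raise FitError("linear_fallback needs the original choice sets to refit")
    return fit_dcgam(sets, model, basis_dim=fit.basis_dim)


# ---------------------------------------------------------------------------
# model ranking


@dataclass(frozen=True)
class RankedModel:
    name: str
    n_covariates: int
    df: float
    aic: float
    delta_aic: float
    weight: float


@dataclass
class ModelRanking:
    """AIC ranking table plus the parsimony-selected model."""

    rows: list[RankedModel]
    selected: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "Model": i + 1,
                    "Metrics": r.name,
                    "df": r.df,
                    "AIC": r.aic,
                    "dAIC": r.delta_aic,
                    "weight": r.weight,
                }
                for i, r in enumerate(self.rows)
            ]
        )

    def __getitem__(self, name: str) -> RankedModel:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)


def rank_from_aic(
    names: Sequence[str],
    aics: Sequence[float],
    n_covariates: Sequence[int],
    dfs: Sequence[float] | None = None,
    delta_rule: float = 2.0,
) -> ModelRanking:
    """Rank models from raw AIC values.

    ``delta = aic - min(aic)``; Akaike weights are ``exp(-delta/2)``
    normalized to sum to one.  The selected model is, among those with
    ``delta <= delta_rule``, the one with fewest covariates (ties broken by
    lower AIC).
    """
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    dfs = list(dfs) if dfs is not None else [float("nan")] * len(aics)
    rows = [
        RankedModel(name=n, n_covariates=int(k), df=float(d), aic=float(a), delta_aic=float(dl), weight=float(wt))
        for n, k, d, a, dl, wt in zip(names, n_covariates, dfs, aics, delta, w)
    ]
    rows.sort(key=lambda r: r.aic)
    candidates = [r for r in rows if r.delta_aic <= delta_rule]
    selected = min(candidates, key=lambda r: (r.n_covariates, r.aic))
    return ModelRanking(rows=rows, selected=selected.name)


def rank_models(fits: Sequence[DCGAMFit], delta_rule: float = 2.0) -> ModelRanking:
    """Rank fitted models by AIC (all fits must share the same data)."""
    if not fits:
        raise FitError("no fits to rank")
    n_sets = {f.n_sets for f in fits}
    if len(n_sets) != 1:
        raise FitError(f"fits were made on differing numbers of sets: {sorted(n_sets)}")
    return rank_from_aic(
        [f.name for f in fits],
        [f.aic for f in fits],
        [f.n_covariates for f in fits],
        dfs=[f.total_edf for f in fits],
        delta_rule=delta_rule,
    )
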