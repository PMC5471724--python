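"""Additive mixed models with penalized cubic splines, random intercepts,
precision weights, and optional AR(1) residual correlation.

The model for a response record i is

    y_i = alpha + sum_j f_j(x_ij) + x_i' beta + b_animal(i) + b_study(i) + e_i

where each f_j is a cubic B-spline smooth (default basis size k=10, equally
spaced knots over the observed range; a cyclic basis for seasonal terms)
with a second-order difference penalty plus a small identity shrinkage
penalty so weakly supported smooths shrink towards zero; linear terms cover
covariates believed linearly related (landscape distances); random
intercepts are represented the standard mixed-model way, as indicator
blocks with a ridge (identity) penalty whose smoothing parameter maps to
the variance component.  Every model also carries univariate smooths of
latitude and longitude to absorb broad spatial correlation.  Records are
weighted by their fix counts; fits are invariant to the overall weight
scale.

Smoothing parameters (one per smooth, one per random-effect block) are
chosen by restricted maximum likelihood (REML) with a GCV fallback; the fit
itself is penalized weighted least squares, so with fixed smoothing
parameters the solution is exactly (X'WX + sum_j lambda_j S_j)^{-1} X'Wy.

At the daily scale, strong serial correlation of within-animal residuals is
handled with a Cochrane–Orcutt style iteration: fit, estimate the pooled
lag-1 residual autocorrelation rho over consecutive-day pairs, quasi-
difference response and design within unbroken daily runs (Prais–Winsten
scaling of each run's first row), refit; iterate to |d rho| < 1e-3.

Each smooth is subject to a centering (sum-to-zero over the data)
constraint for identifiability, so fitted reaction norms are partial
effects around the model intercept.  Approximate Wald tests per term block
use the Bayesian posterior covariance; no multiplicity correction is
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space
from scipy.stats import chi2

__all__ = [
    "SmoothTerm",
    "LinearTerm",
    "FactorTerm",
    "RandomIntercept",
    "ModelSpec",
    "Design",
    "GAMMFit",
    "ReactionNorm",
    "build_design",
    "fit",
    "fit_ar1",
    "reaction_norm",
]

SHRINKAGE = 1e-4  # identity penalty multiple added to every smooth penalty


# ---------------------------------------------------------------------------
# term declarations


@dataclass
class SmoothTerm:
    col: str
    k: int = 10
    cyclic: bool = False
    period: tuple[float, float] | None = None  # for cyclic terms, e.g. (0.5, 12.5)


@dataclass
class LinearTerm:
    col: str


@dataclass
class FactorTerm:
    col: str


@dataclass
class RandomIntercept:
    col: str


@dataclass
class ModelSpec:
    response: str
    scale: str  # daily | monthly | overall
    category: str
    terms: list
    weights_col: str | None = None
    ar1: bool = False
    series_col: str = "animal_id"
    time_col: str = "bio_day"

    def __post_init__(self) -> None:
        if self.ar1 and self.scale != "daily":
            raise ValueError("AR(1) residuals apply only at the daily scale")


# ---------------------------------------------------------------------------
# basis construction


class _SmoothBasis:
    """Cubic B-spline basis with equally spaced knots, sum-to-zero
    constrained; handles cyclic wrapping and small-support degree fallback."""

    def __init__(self, x: np.ndarray, k: int, cyclic: bool,
                 period: tuple[float, float] | None, warnings_out: list[str],
                 name: str):
        xu = np.unique(x)
        self.cyclic = cyclic
        if cyclic:
            lo, hi = period if period is not None else (float(x.min()), float(x.max()) + 1.0)
            self.lo, self.hi = lo, hi
            self.k = min(k, max(4, len(xu)))
            self.degree = 3
            h = (hi - lo) / self.k
            self.knots = lo + h * np.arange(-3, self.k + 4)
        else:
            lo, hi = float(x.min()), float(x.max())
            if hi <= lo:
                hi = lo + 1.0
            self.lo, self.hi = lo, hi
            kk = min(k, len(xu))
            if kk < k:
                warnings_out.append(
                    f"smooth({name}): basis size reduced to {kk} "
                    f"({len(xu)} distinct values)"
                )
            self.k = kk
            self.degree = min(3, self.k - 1)
            h = (hi - lo) / (self.k - self.degree)
            self.knots = lo + h * np.arange(-self.degree, self.k + 1)
        B = self._raw(x)
        self.constraint = B.mean(axis=0)
        self.Z = null_space(self.constraint[None, :])  # k x (k-1)
        self.S = self._penalty()

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.cyclic:
            period = self.hi - self.lo
            xm = self.lo + np.mod(x - self.lo, period)
            B = BSpline.design_matrix(xm, self.knots, 3, extrapolate=True).toarray()
            out = B[:, : self.k].copy()
            out[:, :3] += B[:, self.k : self.k + 3]
            return out
        xc = np.clip(x, self.lo, self.hi - 1e-12 * max(abs(self.hi), 1.0))
        return BSpline.design_matrix(xc, self.knots, self.degree,
                                     extrapolate=True).toarray()

    def _penalty(self) -> np.ndarray:
        k = self.k
        if self.cyclic:
            D = np.zeros((k, k))
            for i in range(k):
                D[i, i] = 1.0
                D[i, (i + 1) % k] = -2.0
                D[i, (i + 2) % k] = 1.0
        else:
            if k < 3:
                D = np.zeros((0, k))
            else:
                D = np.diff(np.eye(k), n=2, axis=0)
        S0 = D.T @ D + SHRINKAGE * np.eye(k)
        return self.Z.T @ S0 @ self.Z

    def design(self, x: np.ndarray) -> np.ndarray:
        return self._raw(np.asarray(x, dtype=float)) @ self.Z

    @property
    def ncols(self) -> int:
        return self.Z.shape[1]


@dataclass
class _Block:
    name: str
    kind: str  # intercept | linear | factor | smooth | random
    sl: slice
    S: np.ndarray | None = None  # penalty on the block (None = unpenalized)
    basis: _SmoothBasis | None = None
    levels: list | None = None
    col: str | None = None


@dataclass
class Design:
    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    blocks: list[_Block]
    spec: ModelSpec
    df: pd.DataFrame = field(repr=False)
    n_dropped: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def penalized_blocks(self) -> list[_Block]:
        return [b for b in self.blocks if b.S is not None]

    @property
    def n_unpenalized(self) -> int:
        return sum(
            b.sl.stop - b.sl.start for b in self.blocks if b.S is None
        )


def build_design(spec: ModelSpec, data: pd.DataFrame) -> Design:
    """Assemble the penalized design matrix for a model specification.

    Rows with missing values in any used column are dropped and counted.
    Factors with a single level are dropped with a warning; smooths over
    covariates with fewer distinct values than the basis size get a reduced
    basis.
    """
    used_cols = [spec.response]
    if spec.weights_col:
        used_cols.append(spec.weights_col)
    for t in spec.terms:
        used_cols.append(t.col)
    if spec.ar1:
        used_cols += [spec.series_col, spec.time_col]
    used_cols = list(dict.fromkeys(c for c in used_cols if c in data.columns))
    missing = [c for c in (t.col for t in spec.terms) if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")

    df = data[used_cols + [c for c in data.columns if c not in used_cols]].copy()
    ok = df[used_cols].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    df = df.loc[ok].reset_index(drop=True)
    n = len(df)
    if n == 0:
        raise ValueError("no complete rows for this model")

    warns: list[str] = []
    cols: list[np.ndarray] = [np.ones((n, 1))]
    blocks: list[_Block] = [_Block("(intercept)", "intercept", slice(0, 1))]
    p = 1
    for t in spec.terms:
        if isinstance(t, LinearTerm):
            cols.append(df[t.col].to_numpy(dtype=float)[:, None])
            blocks.append(_Block(t.col, "linear", slice(p, p + 1), col=t.col))
            p += 1
        elif isinstance(t, FactorTerm):
            levels = sorted(pd.unique(df[t.col].astype(str)))
            if len(levels) < 2:
                warns.append(f"factor({t.col}): single level, dropped")
                continue
            M = np.column_stack([
                (df[t.col].astype(str) == lev).to_numpy(dtype=float)
                for lev in levels[1:]
            ])
            cols.append(M)
            blocks.append(_Block(t.col, "factor", slice(p, p + M.shape[1]),
                                 levels=levels, col=t.col))
            p += M.shape[1]
        elif isinstance(t, SmoothTerm):
            x = df[t.col].to_numpy(dtype=float)
            if len(np.unique(x)) < 2:
                warns.append(f"smooth({t.col}): constant covariate, dropped")
                continue
            if len(np.unique(x)) < 4 and not t.cyclic:
                # too few support points for a useful smooth: use linear
                warns.append(f"smooth({t.col}): <4 distinct values, using linear term")
                cols.append(x[:, None])
                blocks.append(_Block(t.col, "linear", slice(p, p + 1), col=t.col))
                p += 1
                continue
            basis = _SmoothBasis(x, t.k, t.cyclic, t.period, warns, t.col)
            M = basis.design(x)
            cols.append(M)
            blocks.append(_Block(t.col, "smooth", slice(p, p + M.shape[1]),
                                 S=basis.S, basis=basis, col=t.col))
            p += M.shape[1]
        elif isinstance(t, RandomIntercept):
            levels = sorted(pd.unique(df[t.col].astype(str)))
            if len(levels) < 2:
                warns.append(f"random({t.col}): single level, dropped")
                continue
            codes = pd.Categorical(df[t.col].astype(str), categories=levels).codes
            M = np.zeros((n, len(levels)))
            M[np.arange(n), codes] = 1.0
            cols.append(M)
            blocks.append(_Block(t.col, "random", slice(p, p + len(levels)),
                                 S=np.eye(len(levels)), levels=levels, col=t.col))
            p += len(levels)
        else:  # pragma: no cover
            raise TypeError(f"unknown term type {type(t)!r}")

    X = np.hstack(cols)
    y = df[spec.response].to_numpy(dtype=float)
    if spec.weights_col:
        w = df[spec.weights_col].to_numpy(dtype=float)
        w = w / w.mean()  # weight-scale invariance, explicit
    else:
        w = np.ones(n)
    return Design(X=X, y=y, w=w, blocks=blocks, spec=spec, df=df,
                  n_dropped=n_dropped, warnings=warns)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class GAMMFit:
    design: Design = field(repr=False)
    beta: np.ndarray = field(repr=False)
    Vb: np.ndarray = field(repr=False)
    sigma2: float = 0.0
    lambdas: dict = field(default_factory=dict)
    edf: dict = field(default_factory=dict)
    edf_total: float = 0.0
    adj_r2: float = np.nan
    pvalues: dict = field(default_factory=dict)
    variance_components: dict = field(default_factory=dict)
    rho: float | None = None
    converged: bool = True
    method: str = "reml"
    fitted: np.ndarray = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)

    def summary_dict(self) -> dict:
        return {
            "response": self.design.spec.response,
            "scale": self.design.spec.scale,
            "category": self.design.spec.category,
            "n": int(len(self.design.y)),
            "sigma2": float(self.sigma2),
            "lambdas": {k: float(v) for k, v in self.lambdas.items()},
            "edf": {k: float(v) for k, v in self.edf.items()},
            "edf_total": float(self.edf_total),
            "adj_r2": float(self.adj_r2),
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "rho": None if self.rho is None else float(self.rho),
            "converged": bool(self.converged),
            "method": self.method,
            "warnings": list(self.design.warnings),
        }


def _assemble_penalty(design: Design, lam: np.ndarray) -> np.ndarray:
    p = design.X.shape[1]
    S = np.zeros((p, p))
    for lj, b in zip(lam, design.penalized_blocks):
        S[b.sl, b.sl] += lj * b.S
    return S


def _solve(A: np.ndarray, S: np.ndarray, bvec: np.ndarray):
    H = A + S
    try:
        c = cho_factor(H, lower=True)
    except np.linalg.LinAlgError:
        H = H + 1e-8 * np.mean(np.diag(H)) * np.eye(H.shape[0])
        c = cho_factor(H, lower=True)
    beta = cho_solve(c, bvec)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return beta, c, logdet


def fit(
    design: Design,
    lambdas: np.ndarray | list | None = None,
    method: str = "reml",
) -> GAMMFit:
    """Penalized weighted least squares with smoothing parameters by REML
    (GCV fallback).

    ``lambdas`` fixes the smoothing parameters (one per penalized block, in
    block order) and skips the criterion optimisation — the solution is
    then the closed-form (X'WX + sum lambda_j S_j)^{-1} X'Wy.
    """
    X, y, w = design.X, design.y, design.w
    n, p = X.shape
    A = X.T @ (w[:, None] * X)
    bvec = X.T @ (w * y)
    yWy = float(w @ (y * y))
    pen = design.penalized_blocks
    m0 = design.n_unpenalized
    ranks = np.array([b.S.shape[0] for b in pen], dtype=float)

    converged = True
    used_method = method
    if lambdas is not None:
        lam = np.asarray(lambdas, dtype=float)
        if len(lam) != len(pen):
            raise ValueError("one lambda per penalized block required")
        used_method = "fixed"
    elif not pen:
        lam = np.array([])
    else:
        logdet_S_parts = []
        for b in pen:
            sign, ld = np.linalg.slogdet(b.S)
            logdet_S_parts.append(ld)
        logdet_S_parts = np.array(logdet_S_parts)

        def neg_reml(rho: np.ndarray) -> float:
            lamv = np.exp(rho)
            S = _assemble_penalty(design, lamv)
            beta, _, logdetH = _solve(A, S, bvec)
            rss_p = max(yWy - float(bvec @ beta), 1e-300)
            logdet_S = float(np.sum(ranks * rho) + np.sum(logdet_S_parts))
            return (n - m0) * np.log(rss_p) + logdetH - logdet_S

        def neg_gcv(rho: np.ndarray) -> float:
            lamv = np.exp(rho)
            S = _assemble_penalty(design, lamv)
            beta, c, _ = _solve(A, S, bvec)
            F = cho_solve(c, A)
            edf = float(np.trace(F))
            resid = y - X @ beta
            rss = float(w @ (resid * resid))
            return n * rss / max(n - edf, 1e-6) ** 2

        crit = neg_reml if method == "reml" else neg_gcv
        x0 = np.zeros(len(pen))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                crit, x0, method="L-BFGS-B",
                bounds=[(-12.0, 14.0)] * len(pen),
                options={"maxiter": 200},
            )
        if not res.success and method == "reml":
            res2 = optimize.minimize(
                neg_gcv, x0, method="L-BFGS-B",
                bounds=[(-12.0, 14.0)] * len(pen),
                options={"maxiter": 200},
            )
            if res2.success:
                res = res2
                used_method = "gcv"
            else:
                converged = False
        lam = np.exp(res.x)

    S = _assemble_penalty(design, lam)
    beta, c, _ = _solve(A, S, bvec)
    F = cho_solve(c, A)  # hat-trace contributions: edf_j = tr(F[block])
    edf = {}
    for b in design.blocks:
        edf[b.name] = float(np.trace(F[b.sl, b.sl]))
    edf_total = float(np.trace(F))

    fitted = X @ beta
    resid = y - fitted
    rss_w = float(w @ (resid * resid))
    ybar = float(np.sum(w * y) / np.sum(w))
    tss_w = float(w @ ((y - ybar) ** 2))
    df_res = max(n - edf_total, 1.0)
    sigma2 = rss_w / df_res
    adj_r2 = 1.0 - (rss_w / df_res) / (tss_w / max(n - 1, 1)) if tss_w > 0 else np.nan

    Vb = sigma2 * cho_solve(c, np.eye(p))

    pvalues = {}
    variance_components = {}
    lam_by_block = {}
    for lj, b in zip(lam, pen):
        lam_by_block[b.name] = float(lj)
        if b.kind == "random":
            variance_components[b.name] = float(np.sqrt(sigma2 / lj))
    for b in design.blocks:
        if b.kind in {"intercept", "random"}:
            continue
        bb = beta[b.sl]
        V = Vb[b.sl, b.sl]
        try:
            stat = float(bb @ np.linalg.pinv(V, rcond=1e-10) @ bb)
        except np.linalg.LinAlgError:  # pragma: no cover
            stat = np.nan
        dfj = (b.sl.stop - b.sl.start) if b.kind != "smooth" else max(
            1.0, round(edf[b.name])
        )
        pvalues[b.name] = float(chi2.sf(stat, dfj)) if np.isfinite(stat) else np.nan

    return GAMMFit(
        design=design, beta=beta, Vb=Vb, sigma2=sigma2,
        lambdas=lam_by_block, edf=edf, edf_total=edf_total, adj_r2=adj_r2,
        pvalues=pvalues, variance_components=variance_components,
        converged=converged, method=used_method, fitted=fitted, residuals=resid,
    )


# ---------------------------------------------------------------------------
# AR(1) residuals at the daily scale


def _runs(series_ids: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Start-of-run flags: a run breaks at an animal change or a day gap."""
    n = len(series_ids)
    start = np.ones(n, dtype=bool)
    if n > 1:
        same = series_ids[1:] == series_ids[:-1]
        consec = days[1:] - days[:-1] == 1
        start[1:] = ~(same & consec)
    return start


def _pooled_rho(resid: np.ndarray, start: np.ndarray) -> float:
    lagged_ok = ~start
    r1 = resid[lagged_ok]
    r0 = resid[np.flatnonzero(lagged_ok) - 1]
    denom = float(r0 @ r0)
    if denom <= 0 or len(r0) == 0:
        return 0.0
    return float(r1 @ r0) / denom


def fit_ar1(
    design: Design,
    max_iter: int = 20,
    tol: float = 1e-3,
    method: str = "reml",
) -> GAMMFit:
    """Cochrane–Orcutt / Prais–Winsten iteration for daily-scale models.

    Days must be ordered within animal; gaps (missing days) break runs and
    contribute no lag pairs.  The estimated rho is clipped to (-0.99, 0.99).
    """
    spec = design.spec
    df = design.df
    sids = pd.factorize(df[spec.series_col].astype(str))[0]
    days = (
        pd.to_datetime(df[spec.time_col]).astype("int64")
        // (24 * 3600 * 10**9)
    ).to_numpy()
    order = np.lexsort((days, sids))
    if not np.all(order == np.arange(len(order))):
        # reorder everything consistently
        design = Design(
            X=design.X[order], y=design.y[order], w=design.w[order],
            blocks=design.blocks, spec=spec,
            df=df.iloc[order].reset_index(drop=True),
            n_dropped=design.n_dropped, warnings=design.warnings,
        )
        sids, days = sids[order], days[order]
    start = _runs(sids, days)

    current = fit(design, method=method)
    rho = 0.0
    clipped = False
    for _ in range(max_iter):
        resid = design.y - design.X @ current.beta
        rho_new = _pooled_rho(resid, start)
        if abs(rho_new) > 0.99:
            rho_new = float(np.clip(rho_new, -0.99, 0.99))
            clipped = True
        if abs(rho_new - rho) < tol:
            rho = rho_new
            break
        rho = rho_new
        Xs = design.X.copy()
        ys = design.y.copy()
        lag = ~start
        prev = np.flatnonzero(lag) - 1
        Xs[lag] = design.X[lag] - rho * design.X[prev]
        ys[lag] = design.y[lag] - rho * design.y[prev]
        fac = np.sqrt(max(1.0 - rho**2, 1e-8))
        Xs[start] = design.X[start] * fac
        ys[start] = design.y[start] * fac
        tdesign = Design(
            X=Xs, y=ys, w=design.w, blocks=design.blocks, spec=spec,
            df=design.df, n_dropped=design.n_dropped, warnings=design.warnings,
        )
        current = fit(tdesign, method=method)
    if clipped:
        design.warnings.append("ar1: rho clipped to (-0.99, 0.99)")
    current.rho = rho
    # report fits/residuals on the original (untransformed) scale
    current.fitted = design.X @ current.beta
    current.residuals = design.y - current.fitted
    return current


# ---------------------------------------------------------------------------
# reaction norms


@dataclass
class ReactionNorm:
    covariate: str
    grid: np.ndarray
    effect: np.ndarray
    se: np.ndarray
    argmax: float
    shape: str  # concave | convex | none
    amplitude: float


def reaction_norm(fit_result: GAMMFit, col: str, n_grid: int = 100) -> ReactionNorm:
    """Centered partial-effect curve of a smooth with +-2 SE band and shape
    diagnostics.

    The concavity indicator is the sign of the quadratic component of the
    fitted curve over the central 50% of the grid, required to contribute at
    least 10% of the curve amplitude; otherwise the shape is "none".
    """
    block = None
    for b in fit_result.design.blocks:
        if b.kind == "smooth" and b.col == col:
            block = b
            break
    if block is None:
        raise KeyError(f"no smooth term for covariate {col!r} in this model")
    basis = block.basis
    grid = np.linspace(basis.lo, basis.hi, n_grid)
    B = basis.design(grid)
    beta = fit_result.beta[block.sl]
    eff = B @ beta
    V = fit_result.Vb[block.sl, block.sl]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))

    amp = float(eff.max() - eff.min())
    lo_i, hi_i = n_grid // 4, 3 * n_grid // 4
    gx = grid[lo_i:hi_i]
    ge = eff[lo_i:hi_i]
    shape = "none"
    if amp > 1e-10 and len(gx) >= 3:
        q = np.polyfit(gx - gx.mean(), ge, 2)
        half = (gx[-1] - gx[0]) / 2.0
        quad_amp = abs(q[0]) * half**2
        if quad_amp > 0.1 * amp:
            shape = "concave" if q[0] < 0 else "convex"
    return ReactionNorm(
        covariate=col,
        grid=grid,
        effect=eff,
        se=se,
        argmax=float(grid[int(np.argmax(eff))]),
        shape=shape,
        amplitude=amp,
    )
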