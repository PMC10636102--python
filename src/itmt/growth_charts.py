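"""Sex-specific LMS growth charts for TMT: fitting, centiles, diagnostics.

The LMS method models an age-conditional measurement distribution with
three smooth curves — the Box-Cox power L(t), the median M(t) and the
coefficient of variation S(t) — under the Box-Cox Cole-Green (BCCG)
family: for a measurement y at age t,

    z = ((y/M)^L - 1) / (L*S)    (L != 0)
    z = log(y/M) / S             (L == 0)

is standard normal, so the centile of y is 100*Phi(z) and the value at
centile alpha is M*(1 + L*S*z_alpha)^(1/L).  Curves are cubic (or
lower-order, for small df) B-splines in age with log links on M and S to
keep them positive; coefficients are fitted by direct maximum likelihood
and the per-curve degrees of freedom are selected jointly by BIC.  Ages
above a cap (default 30) are collapsed to the cap before fitting, for
curve stability in the sparse upper tail.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

log = logging.getLogger(__name__)

_L_EPS = 1e-8  # |L| below this uses the log (L -> 0) branch

REQUIRED_COHORT_COLUMNS = ("subject_id", "study_id", "age_years", "sex", "tmt_mm")


def validate_cohort(df: pd.DataFrame, age_range=(4.0, 35.0)) -> pd.DataFrame:
    """Check the cohort schema and ranges; returns the validated frame."""
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if not df["sex"].isin(["M", "F"]).all():
        raise ValueError("sex must be coded M/F")
    if (df["tmt_mm"] <= 0).any():
        raise ValueError("tmt_mm must be positive")
    ages = df["age_years"]
    if (ages < age_range[0]).any() or (ages > age_range[1]).any():
        raise ValueError(f"ages outside configured range {age_range}")
    return df


# ---------------------------------------------------------------------------
# spline basis


@dataclass
class SplineCurve:
    """One fitted curve: B-spline knots/degree/coefficients over the age domain."""

    knots: np.ndarray
    degree: int
    coefs: np.ndarray
    link: str = "identity"  # or "log"

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return BSpline.design_matrix(x, self.knots, self.degree, extrapolate=False).toarray()

    def __call__(self, x) -> np.ndarray:
        eta = self.design(np.atleast_1d(x)) @ self.coefs
        return np.exp(eta) if self.link == "log" else eta

    @property
    def df(self) -> int:
        return int(self.coefs.size)


def make_basis(x: np.ndarray, df: int, domain: tuple[float, float]) -> tuple[np.ndarray, int]:
    """Knot vector and degree giving exactly ``df`` B-spline coefficients.

    df=1 is a constant, df=2 linear, df=3 quadratic; df>=4 are cubic with
    df-4 interior knots at age quantiles.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    degree = min(3, df - 1)
    n_interior = df - degree - 1
    lo, hi = domain
    pad = 1e-6 * max(hi - lo, 1.0)
    if n_interior > 0:
        qs = np.linspace(0, 100, n_interior + 2)[1:-1]
        interior = np.percentile(np.asarray(x, dtype=float), qs)
    else:
        interior = np.array([])
    knots = np.concatenate(
        [np.full(degree + 1, lo - pad), interior, np.full(degree + 1, hi + pad)]
    )
    return knots, degree


# ---------------------------------------------------------------------------
# model object


@dataclass
class CentileModel:
    """Fitted sex-specific L/M/S age curves with fit metadata."""

    sex: str
    L: SplineCurve
    M: SplineCurve
    S: SplineCurve
    age_domain: tuple[float, float]
    n: int
    loglik: float
    bic: float
    df: dict = field(default_factory=dict)

    def _check_age(self, age) -> np.ndarray:
        age = np.atleast_1d(np.asarray(age, dtype=float))
        lo, hi = self.age_domain
        if (age < lo).any() or (age > hi).any():
            raise ValueError(f"age outside fitted domain [{lo}, {hi}]")
        return age

    def lms_at(self, age):
        age = self._check_age(age)
        return self.L(age), self.M(age), self.S(age)

    def to_json(self, path=None) -> str:
        def curve(c: SplineCurve) -> dict:
            return {
                "knots": c.knots.tolist(),
                "degree": c.degree,
                "coefs": c.coefs.tolist(),
                "link": c.link,
            }

        blob = json.dumps(
            {
                "sex": self.sex,
                "L": curve(self.L),
                "M": curve(self.M),
                "S": curve(self.S),
                "age_domain": list(self.age_domain),
                "n": self.n,
                "loglik": self.loglik,
                "bic": self.bic,
                "df": self.df,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob

    @staticmethod
    def from_json(src) -> "CentileModel":
        if isinstance(src, str) and src.lstrip().startswith("{"):
            payload = json.loads(src)
        else:
            with open(src) as fh:
                payload = json.load(fh)

        def curve(d: dict) -> SplineCurve:
            return SplineCurve(
                knots=np.asarray(d["knots"], dtype=float),
                degree=int(d["degree"]),
                coefs=np.asarray(d["coefs"], dtype=float),
                link=d["link"],
            )

        return CentileModel(
            sex=payload["sex"],
            L=curve(payload["L"]),
            M=curve(payload["M"]),
            S=curve(payload["S"]),
            age_domain=tuple(payload["age_domain"]),
            n=int(payload["n"]),
            loglik=float(payload["loglik"]),
            bic=float(payload["bic"]),
            df=dict(payload["df"]),
        )


# ---------------------------------------------------------------------------
# likelihood


def bccg_z(y, L, M, S) -> np.ndarray:
    """LMS transform to a standard-normal score."""
    y, L, M, S = (np.asarray(a, dtype=float) for a in (y, L, M, S))
    u = np.log(y / M)
    small = np.abs(L) < _L_EPS
    L_safe = np.where(small, 1.0, L)
    z = np.where(small, u / S, np.expm1(np.clip(L_safe * u, -700, 700)) / (L_safe * S))
    return z


def _trunc_const(L, S) -> np.ndarray:
    """Positive-support normalizer: the Box-Cox normal mass on y > 0 is
    Phi(1/(|L| S)) for L != 0 (1 for the lognormal branch)."""
    L, S = np.broadcast_arrays(np.asarray(L, float), np.asarray(S, float))
    a = np.where(np.abs(L) < _L_EPS, np.inf, 1.0 / (np.maximum(np.abs(L), _L_EPS) * S))
    return stats.norm.cdf(a)


def bccg_neg_loglik(y, L, M, S) -> float:
    """Negative log-likelihood of y under the (truncated) BCCG family."""
    y = np.asarray(y, dtype=float)
    z = bccg_z(y, L, M, S)
    # log f = log phi(z) + (L-1) log y - L log M - log S - log C
    ll = (
        stats.norm.logpdf(z)
        + (L - 1.0) * np.log(y)
        - L * np.log(M)
        - np.log(S)
        - np.log(_trunc_const(L, S))
    )
    return float(-np.sum(ll))


def bccg_pdf(y, L, M, S) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    z = bccg_z(y, L, M, S)
    return stats.norm.pdf(z) * y ** (L - 1.0) / (M**L * S) / _trunc_const(L, S)


# ---------------------------------------------------------------------------
# fitting


def _fit_one(ages, y, df_L, df_M, df_S, domain, seed=0):
    """Direct ML fit of (L, M, S) spline coefficients for one df combination."""
    rng = np.random.default_rng(seed)
    kL, dL = make_basis(ages, df_L, domain)
    kM, dM = make_basis(ages, df_M, domain)
    kS, dS = make_basis(ages, df_S, domain)
    BL = BSpline.design_matrix(ages, kL, dL, extrapolate=False).toarray()
    BM = BSpline.design_matrix(ages, kM, dM, extrapolate=False).toarray()
    BS = BSpline.design_matrix(ages, kS, dS, extrapolate=False).toarray()

    # init: least-squares of log y for M, residual spread for S, L = 1
    logy = np.log(y)
    cM0, *_ = np.linalg.lstsq(BM, logy, rcond=None)
    resid = logy - BM @ cM0
    s0 = max(float(resid.std()), 1e-3)
    cS0 = np.zeros(BS.shape[1])
    cS0[:] = np.log(s0)
    cL0 = np.zeros(BL.shape[1])
    cL0[:] = 1.0
    theta0 = np.concatenate([cL0, cM0, cS0]) + 1e-8 * rng.standard_normal(df_L + df_M + df_S)

    def nll_and_grad(theta):
        cL = theta[:df_L]
        cM = theta[df_L : df_L + df_M]
        cS = theta[df_L + df_M :]
        L = BL @ cL
        m = BM @ cM
        s = BS @ cS
        if np.any(~np.isfinite(m)) or np.any(~np.isfinite(s)) or np.any(s > 2.0):
            return 1e12, np.zeros_like(theta)
        M = np.exp(m)
        S = np.exp(s)
        u = np.log(y) - m
        small = np.abs(L) < _L_EPS
        L_safe = np.where(small, 1.0, L)
        eLu = np.exp(np.clip(L_safe * u, -700, 700))
        z = np.where(small, u / S, (eLu - 1.0) / (L_safe * S))
        a = np.where(small, np.inf, 1.0 / (np.abs(L_safe) * S))
        logC = stats.norm.logcdf(a)
        nll = np.sum(0.5 * z**2 - (L - 1.0) * np.log(y) + L * m + s + logC) + 0.5 * y.size * np.log(
            2 * np.pi
        )
        # per-observation partials of the nll w.r.t. m = log M, s = log S, L
        hazard = np.where(small, 0.0, np.exp(stats.norm.logpdf(a) - logC))
        d_m = np.where(small, -z / S, -z * eLu / S) + L
        d_s = 1.0 - z**2 - a * hazard
        dz_dL = np.where(small, u**2 / (2.0 * S), u * eLu / (L_safe * S) - z / L_safe)
        d_L = z * dz_dL - u - np.where(small, 0.0, (a / L_safe) * hazard)
        grad = np.concatenate([BL.T @ d_L, BM.T @ d_m, BS.T @ d_s])
        if not np.isfinite(nll):
            return 1e12, np.zeros_like(theta)
        return float(nll), grad

    res = optimize.minimize(
        nll_and_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"LMS fit diverged: {res.message}")
    if not res.success and "ABNORMAL" in str(res.message):
        raise RuntimeError(f"LMS fit failed to converge: {res.message}")
    theta = res.x
    curves = {
        "L": SplineCurve(kL, dL, theta[:df_L], link="identity"),
        "M": SplineCurve(kM, dM, theta[df_L : df_L + df_M], link="log"),
        "S": SplineCurve(kS, dS, theta[df_L + df_M :], link="log"),
    }
    return curves, float(-res.fun)


def fit_lms(
    cohort: pd.DataFrame,
    sex: str,
    df_candidates=(2, 3, 4, 5),
    seed: int = 0,
    df_L: int = 1,
    collapse_age: float | None = 30.0,
    min_rows: int = 50,
) -> CentileModel:
    """Fit the sex-specific LMS curves; df for M and S chosen jointly by BIC.

    L(t) is held constant (df_L=1) by default, which stabilizes moderate-n
    fits; M and S use log links.  Requires >= ``min_rows`` rows spanning at
    least 5 distinct integer years of age.
    """
    validate_cohort(cohort)
    sub = cohort[cohort["sex"] == sex]
    if len(sub) < min_rows:
        raise ValueError(f"insufficient data for sex={sex}: {len(sub)} rows < {min_rows}")
    ages = sub["age_years"].to_numpy(dtype=float)
    if collapse_age is not None:
        ages = np.minimum(ages, collapse_age)
    if np.unique(np.floor(ages)).size < 5:
        raise ValueError("ages must span >= 5 distinct years")
    y = sub["tmt_mm"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate data: constant tmt values")
    domain = (float(np.floor(ages.min())), float(np.ceil(ages.max())))
    n = len(sub)

    best = None
    for df_M in df_candidates:
        for df_S in df_candidates:
            try:
                curves, loglik = _fit_one(ages, y, df_L, df_M, df_S, domain, seed)
            except RuntimeError as exc:
                log.warning("fit (df_M=%d, df_S=%d) failed: %s", df_M, df_S, exc)
                continue
            k = df_L + df_M + df_S
            bic = -2.0 * loglik + k * np.log(n)
            log.info("fit sex=%s df=(%d,%d,%d): loglik %.2f BIC %.2f", sex, df_L, df_M, df_S, loglik, bic)
            if best is None or bic < best[0]:
                best = (bic, curves, loglik, {"L": df_L, "M": df_M, "S": df_S})
    if best is None:
        raise RuntimeError("all LMS fits failed; see warnings for traces")
    bic, curves, loglik, dfs = best
    return CentileModel(
        sex=sex,
        L=curves["L"],
        M=curves["M"],
        S=curves["S"],
        age_domain=domain,
        n=n,
        loglik=loglik,
        bic=float(bic),
        df=dfs,
    )


def bic_score(model: CentileModel, cohort: pd.DataFrame, collapse_age: float | None = 30.0) -> float:
    """-2 loglik + k log n with k the total fitted degrees of freedom."""
    sub = cohort[cohort["sex"] == model.sex]
    ages = sub["age_years"].to_numpy(dtype=float)
    if collapse_age is not None:
        ages = np.minimum(ages, collapse_age)
    ages = np.clip(ages, *model.age_domain)
    y = sub["tmt_mm"].to_numpy(dtype=float)
    L, M, S = model.lms_at(ages)
    nll = bccg_neg_loglik(y, L, M, S)
    k = model.L.df + model.M.df + model.S.df
    return float(2.0 * nll + k * np.log(len(sub)))


# ---------------------------------------------------------------------------
# conversions


def value_to_centile(model: CentileModel, age, value_mm) -> np.ndarray | float:
    """Centile (0..100) of a TMT value at an age: 100*Phi(z(value))."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    value = np.atleast_1d(np.asarray(value_mm, dtype=float))
    if (value <= 0).any():
        raise ValueError("value_mm must be positive")
    L, M, S = model.lms_at(age)
    z = bccg_z(value, L, M, S)
    out = 100.0 * stats.norm.cdf(z)
    return float(out[0]) if out.size == 1 else out


def centile_to_value(model: CentileModel, age, centile) -> np.ndarray | float:
    """Inverse conversion: the TMT value at a given centile and age."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    cent = np.atleast_1d(np.asarray(centile, dtype=float))
    if (cent <= 0).any() or (cent >= 100).any():
        raise ValueError("centile must lie strictly inside (0, 100)")
    L, M, S = model.lms_at(age)
    z = stats.norm.ppf(cent / 100.0)
    base = 1.0 + L * S * z
    small = np.abs(L) < _L_EPS
    if np.any(base[~small] <= 0):
        raise ValueError("centile outside the Box-Cox support at this age")
    y = np.where(small, M * np.exp(S * z), M * np.sign(base) * np.abs(base) ** (1.0 / np.where(small, 1.0, L)))
    out = np.asarray(y, dtype=float)
    return float(out[0]) if out.size == 1 else out


def pit_values(model: CentileModel, cohort: pd.DataFrame, collapse_age: float | None = 30.0) -> np.ndarray:
    """Probability integral transform (fitted centile / 100) per row; uniform
    on [0,1] when the model matches the data-generating distribution."""
    sub = cohort[cohort["sex"] == model.sex]
    ages = sub["age_years"].to_numpy(dtype=float)
    if collapse_age is not None:
        ages = np.minimum(ages, collapse_age)
    ages = np.clip(ages, *model.age_domain)
    return np.asarray(value_to_centile(model, ages, sub["tmt_mm"].to_numpy(dtype=float))) / 100.0


def chart_curves(
    model: CentileModel,
    centiles=(3, 10, 25, 50, 75, 90, 97),
    age_grid: np.ndarray | None = None,
    band: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Centile curves over an age grid (plus the outer band), strictly ordered."""
    if age_grid is None:
        age_grid = np.linspace(model.age_domain[0], model.age_domain[1], 101)
    cols: dict[str, np.ndarray] = {"age_years": np.asarray(age_grid, dtype=float)}
    for c in sorted(set(tuple(centiles) + tuple(band))):
        cols[f"P{c:g}"] = np.asarray(centile_to_value(model, age_grid, np.full_like(age_grid, c)))
    return pd.DataFrame(cols)


def mm_per_centile(model: CentileModel, age_grid: np.ndarray | None = None) -> float:
    """Mean mm change per one-centile step, averaged over ages and over the
    adjacent centile pairs (alpha, alpha+1) for alpha = 1..98."""
    if age_grid is None:
        age_grid = np.arange(np.ceil(model.age_domain[0]), np.floor(model.age_domain[1]) + 1.0)
    alphas = np.arange(1.0, 100.0)
    gaps = []
    for a in np.asarray(age_grid, dtype=float):
        vals = np.asarray(centile_to_value(model, np.full_like(alphas, a), alphas))
        gaps.append(np.diff(vals))
    return float(np.mean(np.concatenate(gaps)))


def centile_precision(
    model: CentileModel,
    mae_mm: float,
    age_grid: np.ndarray | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Centile displacement induced by a measurement error of ``mae_mm``.

    At each age, perturb the median by +mae_mm and record the centile shift
    |centile(M + mae) - 50|; returns the median over ages with a bootstrap
    95% interval over the age grid.
    """
    if mae_mm < 0:
        raise ValueError("mae_mm must be >= 0")
    if age_grid is None:
        age_grid = np.arange(np.ceil(model.age_domain[0]), np.floor(model.age_domain[1]) + 1.0)
    age_grid = np.asarray(age_grid, dtype=float)
    _, M, _ = model.lms_at(age_grid)
    shifts = np.abs(np.asarray(value_to_centile(model, age_grid, M + mae_mm)) - 50.0)
    rng = np.random.default_rng(seed)
    boots = np.median(
        shifts[rng.integers(0, len(shifts), size=(n_boot, len(shifts)))], axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(np.median(shifts)), (float(lo), float(hi))


def plot_chart(
    model: CentileModel,
    path=None,
    centiles=(3, 10, 25, 50, 75, 90, 97),
    band: tuple[float, float] = (2.5, 97.5),
    cohort: pd.DataFrame | None = None,
):
    """Growth-chart template: centile curves with a shaded outer band.

    Optionally scatters a cohort behind the curves.  Returns the figure;
    saves to ``path`` (PNG/PDF) when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = chart_curves(model, centiles=centiles, band=band)
    fig, ax = plt.subplots(figsize=(7, 5))
    if cohort is not None:
        sub = cohort[cohort["sex"] == model.sex]
        ax.scatter(sub["age_years"], sub["tmt_mm"], s=4, alpha=0.15, color="grey", lw=0)
    ax.fill_between(
        table["age_years"],
        table[f"P{band[0]:g}"],
        table[f"P{band[1]:g}"],
        alpha=0.12,
        color="tab:blue",
        label=f"{band[0]}-{band[1]} band",
    )
    for c in centiles:
        lw = 2.0 if c == 50 else 1.0
        ax.plot(table["age_years"], table[f"P{c:g}"], lw=lw, color="tab:blue")
        ax.annotate(f"P{c}", (table["age_years"].iloc[-1], table[f"P{c:g}"].iloc[-1]), fontsize=7)
    ax.set_xlabel("age [years]")
    ax.set_ylabel("TMT [mm]")
    ax.set_title(f"TMT growth chart — sex {model.sex} (n={model.n})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def loso_curves(
    cohort: pd.DataFrame,
    sex: str,
    df_candidates=(2, 3),
    age_grid: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-study-out: refit without each study and report the maximum
    absolute deviation of M(t) from the full fit (mm) per held-out study."""
    studies = sorted(cohort.loc[cohort["sex"] == sex, "study_id"].unique())
    if len(studies) < 3:
        raise ValueError("LOSO needs >= 3 distinct studies")
    full = fit_lms(cohort, sex, df_candidates=df_candidates, seed=seed)
    if age_grid is None:
        age_grid = np.linspace(full.age_domain[0], full.age_domain[1], 53)
    age_grid = np.asarray(age_grid, dtype=float)
    m_full = full.M(age_grid)
    rows = []
    for study in studies:
        part = cohort[cohort["study_id"] != study]
        refit = fit_lms(part, sex, df_candidates=df_candidates, seed=seed)
        grid = np.clip(age_grid, *refit.age_domain)
        delta = float(np.max(np.abs(refit.M(grid) - m_full)))
        rows.append({"held_out_study": study, "max_abs_delta_M_mm": delta})
    return pd.DataFrame(rows)
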