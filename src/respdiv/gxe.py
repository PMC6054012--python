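"""Cultivar × environment-category mixed model and gap classification.

For one species and one categorized agroclimatic variable the annual
dry-matter yield is modelled as

    y = μ + cultivar_i + category_j + (cultivar × category)_ij
        + u_{unit(j)} + ε,

with fixed genotype (G), environment category (E, three levels) and G×E
interaction effects, a random intercept for each site × year ×
experiment unit nested in its category, and i.i.d. residuals.  The fit
is by REML; G, E and G×E get marginal (Type-III-style) F tests with
Satterthwaite denominator degrees of freedom (residual/containment df
as fallback).  Response diversity is read off the interaction: the
max-diff statistic is the spread among cultivars of the high-minus-low
category contrast of LS-means, and a *gap in adaptive capacity* is an
agroclimatic variable with a significant E effect but no significant
G×E — all cultivars respond, and respond alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trials import CATEGORY_LEVELS

__all__ = [
    "GxEFit",
    "TermTest",
    "fit_gxe_model",
    "significance_stars",
    "response_profile",
    "max_diff",
    "classify_gap",
    "summarize_species",
]

REML_MAXITER = 200
REML_TOL = 1e-8


@dataclass(frozen=True)
class TermTest:
    fstat: float
    df_num: float
    df_den: float
    pvalue: float


@dataclass
class GxEFit:
    species: str
    variable_id: str
    n_obs: int
    n_units: int
    cultivars: list[str]
    sigma2_unit: float
    sigma2_resid: float
    tests: dict[str, TermTest]
    lsmeans: pd.DataFrame            # columns: cultivar, category, lsmean, se
    converged: bool
    df_method: str
    warnings: list[str] = field(default_factory=list)
    excluded_cultivars: list[str] = field(default_factory=list)

    def lsmean(self, cultivar: str, category: str) -> float:
        sel = self.lsmeans[
            (self.lsmeans["cultivar"] == cultivar)
            & (self.lsmeans["category"] == category)
        ]
        return float(sel["lsmean"].iloc[0])


def _sum_code(labels: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding; the last level is the reference."""
    k = len(levels)
    out = np.zeros((len(labels), k - 1))
    pos = {lev: m for m, lev in enumerate(levels)}
    idx = np.array([pos[v] for v in labels])
    for m in range(k - 1):
        out[idx == m, m] = 1.0
    out[idx == k - 1, :] = -1.0
    return out


def _design(cultivar, category, cultivar_levels, category_levels):
    """Fixed-effects design with term column slices."""
    a = _sum_code(np.asarray(cultivar), cultivar_levels)
    b = _sum_code(np.asarray(category), category_levels)
    inter = np.einsum("ni,nj->nij", a, b).reshape(len(a), -1)
    X = np.column_stack([np.ones(len(a)), a, b, inter])
    pa, pb = a.shape[1], b.shape[1]
    slices = {
        "G": slice(1, 1 + pa),
        "E": slice(1 + pa, 1 + pa + pb),
        "GxE": slice(1 + pa + pb, 1 + pa + pb + pa * pb),
    }
    return X, slices


def _satterthwaite_df(L, C, beta_cov_parts, W, q):
    """Fai–Cornelius multi-dimensional Satterthwaite approximation.

    ``beta_cov_parts[i]`` is ∂C/∂θ_i for the variance parameters
    θ = (σ²_unit, σ²_ε); ``W`` is the asymptotic covariance of θ̂.
    Returns the denominator df, or None when the approximation is
    unusable (then the caller falls back to containment df).
    """
    M = L @ C @ L.T
    evals, evecs = np.linalg.eigh(M)
    E_sum = 0.0
    for r in range(len(evals)):
        d_r = evals[r]
        if d_r <= 1e-12 * max(evals.max(), 1.0):
            continue
        lr = evecs[:, r] @ L  # 1 x p contrast
        grad = np.array([lr @ dC @ lr for dC in beta_cov_parts])
        denom = grad @ W @ grad
        if denom <= 0:
            continue
        nu_r = 2.0 * d_r**2 / denom
        if nu_r > 2.0:
            E_sum += nu_r / (nu_r - 2.0)
    if E_sum <= q:
        return None
    return 2.0 * E_sum / (E_sum - q)


def fit_gxe_model(
    data: pd.DataFrame,
    species: str = "",
    variable_id: str = "",
    response: str = "annual_dm_yield_kg_ha",
    df_method: str = "satterthwaite",
) -> GxEFit:
    """REML fit of the G×E model for one species × variable.

    ``data`` needs columns ``cultivar``, ``category`` (low/moderate/high),
    ``unit`` and the response.  Requires all three categories, at least
    two cultivars and at least two units per category.  Cultivars absent
    from some category make their interaction cells inestimable; they
    are dropped from the fit with a warning and the tests are computed
    on the estimable subspace.
    """
    import statsmodels.api as sm

    notes: list[str] = []
    df = data.dropna(subset=["category", response]).copy()
    cats = sorted(df["category"].unique(), key=list(CATEGORY_LEVELS).index)
    if len(cats) < 3:
        raise ValueError(f"need all three categories, have {cats}")
    units_per_cat = df.groupby("category")["unit"].nunique()
    if (units_per_cat < 2).any():
        raise ValueError(
            f"need >= 2 units per category, have {units_per_cat.to_dict()}"
        )

    cell = df.groupby(["cultivar", "category"]).size().unstack(fill_value=0)
    estimable = cell.index[(cell.reindex(columns=CATEGORY_LEVELS, fill_value=0) > 0).all(axis=1)]
    excluded = sorted(set(cell.index) - set(estimable))
    if excluded:
        notes.append(
            f"cultivars without observations in every category excluded "
            f"from the fit (inestimable interaction cells): {excluded}"
        )
        df = df[df["cultivar"].isin(estimable)]
    cultivars = sorted(df["cultivar"].unique())
    if len(cultivars) < 2:
        raise ValueError("need >= 2 cultivars with estimable cells")

    y = df[response].to_numpy(float)
    X, term_slices = _design(
        df["cultivar"].to_numpy(), df["category"].to_numpy(),
        cultivars, list(CATEGORY_LEVELS),
    )
    groups = df["unit"].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True, maxiter=REML_MAXITER)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        notes.append("REML optimizer reported non-convergence")

    sigma2_e = float(res.scale)
    sigma2_u = float(np.asarray(res.cov_re)[0, 0])
    if not np.isfinite(sigma2_e) or sigma2_e <= 0.0:
        notes.append("degenerate residual variance; clamped for the GLS step")
        sigma2_e = max(sigma2_e if np.isfinite(sigma2_e) else 0.0, 1e-10)
    sigma2_u = max(sigma2_u, 0.0) if np.isfinite(sigma2_u) else 0.0
    beta = np.asarray(res.fe_params, float)

    # GLS quantities at the REML variance estimates, built per unit block.
    codes, uniques = pd.factorize(pd.Series(groups), sort=False)
    g = len(uniques)
    n, p = X.shape
    XtViX = np.zeros((p, p))
    # accumulate X'V^-1 X and the pieces needed for derivatives/traces
    order = np.argsort(codes, kind="stable")
    Xs, ys, cs = X[order], y[order], codes[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(cs) != 0, True])
    Vinv_blocks = []
    Z = np.zeros((n, g))
    Z[np.arange(n), cs] = 1.0
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        ng = b1 - b0
        shrink = sigma2_u / (sigma2_e + ng * sigma2_u)
        Vg_inv = (np.eye(ng) - shrink * np.ones((ng, ng))) / sigma2_e
        Vinv_blocks.append(Vg_inv)
        Xg = Xs[b0:b1]
        XtViX += Xg.T @ Vg_inv @ Xg
    from scipy.linalg import block_diag

    Vinv = block_diag(*Vinv_blocks)
    C = np.linalg.pinv(XtViX)

    # Satterthwaite machinery: dC/dθ and Var(θ̂) from the expected information.
    ViX = Vinv @ Xs
    P = Vinv - ViX @ C @ ViX.T
    V_u = Z @ Z.T
    PVu = P @ V_u
    info = 0.5 * np.array(
        [
            [np.trace(PVu @ PVu), np.trace(PVu @ P)],
            [np.trace(P @ PVu), np.trace(P @ P)],
        ]
    )
    W = np.linalg.pinv(info)
    dC_u = C @ ViX.T @ V_u @ ViX @ C
    dC_e = C @ ViX.T @ ViX @ C
    beta_cov_parts = [dC_u, dC_e]

    n_units = g
    rank_X = int(np.linalg.matrix_rank(X))
    containment = {
        "E": max(n_units - 3, 1),
        "G": max(n - n_units - (rank_X - 3), 1),
        "GxE": max(n - n_units - (rank_X - 3), 1),
    }

    tests: dict[str, TermTest] = {}
    for term, sl in term_slices.items():
        q = sl.stop - sl.start
        L = np.zeros((q, p))
        L[np.arange(q), np.arange(sl.start, sl.stop)] = 1.0
        M = L @ C @ L.T
        Lb = L @ beta
        fstat = float(Lb @ np.linalg.solve(M, Lb) / q)
        ddf = None
        if df_method == "satterthwaite":
            ddf = _satterthwaite_df(L, C, beta_cov_parts, W, q)
        if ddf is None:
            ddf = containment[term]
            if df_method == "satterthwaite":
                notes.append(f"Satterthwaite df unusable for {term}; containment df used")
        pval = float(stats.f.sf(fstat, q, ddf))
        tests[term] = TermTest(fstat, float(q), float(ddf), pval)

    # LS-means: model cell means over the sum-coded design.
    rows = []
    for cv in cultivars:
        for cat in CATEGORY_LEVELS:
            x_cell, _ = _design(np.array([cv]), np.array([cat]), cultivars,
                                list(CATEGORY_LEVELS))
            mu = float((x_cell @ beta)[0])
            se = float(np.sqrt((x_cell @ C @ x_cell.T)[0, 0]))
            rows.append({"cultivar": cv, "category": cat, "lsmean": mu, "se": se})
    lsmeans = pd.DataFrame(rows)

    return GxEFit(
        species=species,
        variable_id=variable_id,
        n_obs=n,
        n_units=n_units,
        cultivars=cultivars,
        sigma2_unit=sigma2_u,
        sigma2_resid=sigma2_e,
        tests=tests,
        lsmeans=lsmeans,
        converged=converged,
        df_method=df_method,
        warnings=notes,
        excluded_cultivars=excluded,
    )


def significance_stars(p: float) -> str:
    """Star code for a p-value: * 0.10, ** 0.05, *** 0.01, **** 0.001."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p <= 0.001:
        return "****"
    if p <= 0.01:
        return "***"
    if p <= 0.05:
        return "**"
    if p <= 0.10:
        return "*"
    return ""


def response_profile(
    fit: GxEFit,
    reporting_cultivars: list[str],
    species_mean_yield: float,
) -> pd.DataFrame:
    """LS-means expressed as percent of the species' average yield.

    The denominator is the mean annual yield of the reporting cultivars,
    so 100 % marks the species average in every panel.
    """
    if not np.isfinite(fit.lsmeans["lsmean"]).all():
        raise ValueError("response profile requires finite LS-means")
    if species_mean_yield <= 0:
        raise ValueError("species mean yield must be positive")
    sub = fit.lsmeans[fit.lsmeans["cultivar"].isin(reporting_cultivars)].copy()
    sub["percent_of_average"] = 100.0 * sub["lsmean"] / species_mean_yield
    return sub.reset_index(drop=True)


def max_diff(fit: GxEFit, reporting_cultivars: list[str] | None = None) -> float | None:
    """Signed spread of cultivar responses (high minus low category).

    The response of cultivar *i* is ``LSmean_i(high) − LSmean_i(low)``;
    the magnitude is the largest minus the smallest response among the
    reporting cultivars, and the sign is that of the species-level
    high-minus-low contrast.  Undefined (None) with fewer than two
    cultivars.
    """
    cultivars = reporting_cultivars if reporting_cultivars is not None else fit.cultivars
    cultivars = [c for c in cultivars if c in fit.cultivars]
    if len(cultivars) < 2:
        return None
    wide = fit.lsmeans.pivot(index="cultivar", columns="category", values="lsmean")
    resp_all = wide["high"] - wide["low"]
    resp = resp_all.loc[cultivars]
    magnitude = float(resp.max() - resp.min())
    # species-level high-minus-low contrast fixes the reported sign
    sign = 1.0 if float(resp_all.mean()) >= 0 else -1.0
    return sign * magnitude


def classify_gap(
    p_e: float | None,
    p_gxe: float | None,
    alpha_e: float = 0.05,
    alpha_gxe: float = 0.05,
) -> tuple[bool | None, str]:
    """Gap in adaptive capacity: significant E, non-significant G×E.

    A significant environment effect with no significant interaction
    means every cultivar of the species shifts yield the same way — the
    cultivar pool offers no response diversity to buffer that factor.
    """
    if p_e is None or p_gxe is None or np.isnan(p_e) or np.isnan(p_gxe):
        return None, "undefined: missing p-values"
    gap = (p_e <= alpha_e) and (p_gxe > alpha_gxe)
    rationale = (
        f"p_E={p_e:.4g} {'<=' if p_e <= alpha_e else '>'} {alpha_e}; "
        f"p_GxE={p_gxe:.4g} {'>' if p_gxe > alpha_gxe else '<='} {alpha_gxe}"
        f" -> {'gap' if gap else 'no gap'}"
    )
    return gap, rationale


def summarize_species(
    fits: dict[str, GxEFit | Exception],
    reporting_cultivars: dict[str, list[str]] | list[str] | None = None,
    alpha_e: float = 0.05,
    alpha_gxe: float = 0.05,
) -> tuple[pd.DataFrame, int, list[str]]:
    """Species summary over variables: one row per attempted variable.

    Returns the table, the count of variables with significant G×E
    (p ≤ ``alpha_gxe``) and the list of variables whose fit failed.
    """
    rows, failed, n_sig = [], [], 0
    for var_id, fit in fits.items():
        if isinstance(fit, Exception):
            failed.append(var_id)
            continue
        reps = (
            reporting_cultivars.get(var_id)
            if isinstance(reporting_cultivars, dict)
            else reporting_cultivars
        )
        p_e, p_gxe = fit.tests["E"].pvalue, fit.tests["GxE"].pvalue
        if p_gxe <= alpha_gxe:
            n_sig += 1
        md = max_diff(fit, reps)
        gap, rationale = classify_gap(p_e, p_gxe, alpha_e, alpha_gxe)
        rows.append(
            {
                "species": fit.species,
                "variable_id": var_id,
                "n_obs": fit.n_obs,
                "n_cultivars": len(fit.cultivars),
                "sigma2_unit": fit.sigma2_unit,
                "sigma2_resid": fit.sigma2_resid,
                "F_G": fit.tests["G"].fstat, "p_G": fit.tests["G"].pvalue,
                "F_E": fit.tests["E"].fstat, "p_E": p_e,
                "F_GxE": fit.tests["GxE"].fstat, "p_GxE": p_gxe,
                "stars_E": significance_stars(p_e),
                "stars_GxE": significance_stars(p_gxe),
                "max_diff": np.nan if md is None else abs(md),
                "max_diff_sign": "" if md is None else ("-" if md < 0 else "+"),
                "gap": gap,
                "gap_rationale": rationale,
            }
        )
    return pd.DataFrame(rows), n_sig, failed
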