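"""Mixed models for route placement, with a residual spatial-autocorrelation
control.

Three model families are used downstream:

* Gaussian linear mixed models (buffer counts vs. location type; log trees
  per meter vs. segment usage), fitted by ML through statsmodels MixedLM so
  likelihood-ratio tests are valid.
* Binomial (logistic) mixed models for quadrat-level route presence,
  fitted by Laplace-approximate ML with a random intercept and uncorrelated
  random slopes per group (the "||" structure). No installed Python package
  provides this fit, so it is implemented here: for fixed variance
  parameters the joint mode of (beta, u) is found by penalized Newton
  iterations, the Laplace-approximate marginal log-likelihood is maximized
  over the log random-effect SDs, and Wald SEs come from the joint observed
  information.
* The autocorrelation term: for each observation, the Gaussian-kernel
  distance-weighted average of same-group residuals of the model fitted
  without the term (the focal observation excluded from its own average).
  The kernel SD ``D`` is chosen on a grid to maximize the refitted full
  model's log-likelihood.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "build_design",
    "fit_mixed",
    "autocorr_term",
    "optimize_D",
    "lrt",
    "drop1_tests",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model specification.

    ``fixed`` terms may be plain columns, ``sqrt(col)``/``log(col)``
    transforms, or one ``a:b`` interaction (whose main effects must also be
    listed). ``random_slopes=None`` gives every fixed term an uncorrelated
    random slope (plus the random intercept); ``[]`` keeps only the random
    intercept. Continuous covariates are z-standardized by default
    (binary 0/1 columns and terms named in ``no_standardize`` are left raw).
    """

    response: str
    fixed: tuple[str, ...]
    group: str
    random_slopes: tuple[str, ...] | None = None
    family: str = "gaussian"
    standardize: bool = True
    no_standardize: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in {"gaussian", "binomial"}:
            raise ValueError(f"unknown family {self.family!r}")
        for t in self.fixed:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.fixed or b not in self.fixed:
                    raise ValueError(
                        f"interaction {t!r} requires both main effects in fixed terms"
                    )

    @property
    def slope_terms(self) -> tuple[str, ...]:
        return tuple(self.fixed) if self.random_slopes is None else tuple(self.random_slopes)


@dataclass
class FitResult:
    params: pd.DataFrame          # term, estimate, se, ci_lower, ci_upper, p
    loglik: float
    n_obs: int
    n_params: int                 # fixed + variance parameters (for LRT df)
    converged: bool
    family: str
    spec: ModelSpec
    fitted: np.ndarray            # mean-scale fitted values (BLUPs included)
    varcomp: dict[str, float] = field(default_factory=dict)

    def coef(self, term: str) -> float:
        row = self.params.loc[self.params["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["estimate"].iloc[0])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.loc[self.params["term"] == term].iloc[0]
        return float(row["ci_lower"]), float(row["ci_upper"])


_TRANSFORM_RE = re.compile(r"(sqrt|log)\(([A-Za-z_]\w*)\)")


def _eval_base(term: str, data: pd.DataFrame) -> np.ndarray:
    m = _TRANSFORM_RE.fullmatch(term)
    if m:
        fn, col = m.groups()
        if col not in data.columns:
            raise KeyError(f"data is missing column {col!r}")
        v = data[col].to_numpy(dtype=float)
        if fn == "sqrt":
            if (v < 0).any():
                raise ValueError(f"negative values under sqrt for {col!r}")
            return np.sqrt(v)
        if (v <= 0).any():
            raise ValueError(f"non-positive values under log for {col!r}")
        return np.log(v)
    if term not in data.columns:
        raise KeyError(f"data is missing column {term!r}")
    return data[term].to_numpy(dtype=float)


def _is_binary(v: np.ndarray) -> bool:
    u = np.unique(v)
    return len(u) <= 2


def build_design(spec: ModelSpec, data: pd.DataFrame):
    """Response, fixed-effects matrix, and random-term matrix for a spec.

    Interactions are products of the (possibly standardized) main-effect
    columns. Returns (y, X, names, Z, slope_names, group_codes, group_levels).
    """
    for col in (spec.response, spec.group):
        if col not in data.columns:
            raise KeyError(f"data is missing column {col!r}")
    used = {c for t in spec.fixed for c in re.findall(r"[A-Za-z_]\w*", t)
            if c in data.columns}
    if used and data[sorted(used)].isna().any().any():
        raise ValueError("missing values in model covariates")
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"missing values in response {spec.response!r}")
    base: dict[str, np.ndarray] = {}
    for t in spec.fixed:
        if ":" in t:
            continue
        v = _eval_base(t, data)
        if spec.standardize and t not in spec.no_standardize and not _is_binary(v):
            sd = v.std(ddof=0)
            v = (v - v.mean()) / (sd if sd > 0 else 1.0)
        base[t] = v
    cols, names = [np.ones(len(data))], ["(Intercept)"]
    for t in spec.fixed:
        if ":" in t:
            a, b = t.split(":")
            cols.append(base[a] * base[b])
        else:
            cols.append(base[t])
        names.append(t)
    X = np.column_stack(cols)
    slope_names = [t for t in spec.slope_terms if t in names]
    Z = np.column_stack([np.ones(len(data))] +
                        [X[:, names.index(t)] for t in slope_names])
    groups, levels = pd.factorize(data[spec.group], sort=True)
    if len(levels) < 2:
        raise ValueError("grouping column must have at least 2 levels")
    return y, X, names, Z, ["(Intercept)"] + slope_names, groups, list(levels)


# ---------------------------------------------------------------------------
# gaussian family: statsmodels MixedLM (ML)


def _fit_gaussian(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    import statsmodels.formula.api as smf

    y, X, names, Z, rnames, groups, levels = build_design(spec, data)
    df = pd.DataFrame(X[:, 1:], columns=[f"t{i}" for i in range(X.shape[1] - 1)])
    df["y"] = y
    df["g"] = groups
    fixed_formula = "y ~ " + (" + ".join(df.columns[:X.shape[1] - 1]) or "1")
    vc = {f"s{i}": f"0 + t{names.index(t) - 1}" for i, t in enumerate(rnames[1:])}
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(fixed_formula, df, groups=df["g"],
                                re_formula="1", vc_formula=vc or None)
            res = model.fit(reml=False, method="powell", maxiter=2000)
            if not (res.converged and np.isfinite(res.llf)):
                res = model.fit(reml=False, method="nm", maxiter=2000)
            converged = bool(res.converged and np.isfinite(res.llf))
        except Exception:
            # singular fit: fall back to near-zero random effects via OLS
            import statsmodels.api as sm
            res = sm.OLS(y, X).fit()
            converged = False
    if hasattr(res, "fe_params"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = np.asarray(res.fe_params)
            se = np.asarray(res.bse_fe)
            try:
                fitted = np.asarray(res.fittedvalues)
            except (ValueError, np.linalg.LinAlgError):
                fitted = X @ est  # singular RE covariance: fixed-effects fit
        ll = float(res.llf)
        varcomp = {"residual_sd": float(np.sqrt(res.scale))}
        try:
            varcomp["(Intercept)_sd"] = float(np.sqrt(res.cov_re.iloc[0, 0]))
            for i, t in enumerate(rnames[1:]):
                varcomp[f"{t}_sd"] = float(np.sqrt(res.vcomp[i]))
        except Exception:
            pass
        n_var = 2 + len(rnames[1:])  # intercept var + slopes + residual
    else:
        est = np.asarray(res.params)
        se = np.asarray(res.bse)
        fitted = np.asarray(res.fittedvalues)
        ll = float(res.llf)
        varcomp = {"residual_sd": float(np.sqrt(res.scale))}
        n_var = 2 + len(rnames[1:])  # parameter count kept comparable
    z = stats.norm.ppf(0.975)
    with np.errstate(invalid="ignore"):
        params = pd.DataFrame({
            "term": names,
            "estimate": est,
            "se": se,
            "ci_lower": est - z * se,
            "ci_upper": est + z * se,
            "p": 2 * stats.norm.sf(np.abs(est / np.where(se > 0, se, np.nan))),
        })
    ok = converged and np.isfinite(ll) and np.isfinite(est).all()
    return FitResult(params, ll, len(y), X.shape[1] + n_var, ok,
                     "gaussian", spec, fitted, varcomp)


# ---------------------------------------------------------------------------
# binomial family: Laplace-approximate ML (hand-rolled)


def _pirls(y, W, pen, theta0, max_iter=60, tol=1e-9):
    """Penalized Newton for logistic joint mode; returns (theta, mu, H)."""
    theta = theta0.copy()
    eta = W @ theta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * theta @ (pen * theta)
    for _ in range(max_iter):
        s = np.clip(mu * (1 - mu), 1e-10, None)
        H = (W * s[:, None]).T @ W + np.diag(pen)
        grad = W.T @ (y - mu) - pen * theta
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            cand = theta + t * step
            eta = W @ cand
            ll_new = y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * cand @ (pen * cand)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        moved = np.abs(t * step).max()
        theta = theta + t * step
        eta = W @ theta
        mu = 1.0 / (1.0 + np.exp(-eta))
        if ll_new - ll < tol and moved < 1e-8:
            ll = ll_new
            break
        ll = ll_new
    s = np.clip(mu * (1 - mu), 1e-10, None)
    H = (W * s[:, None]).T @ W + np.diag(pen)
    return theta, mu, H, ll


def _fit_binomial(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    y, X, names, Z, rnames, groups, levels = build_design(spec, data)
    u_ok = set(np.unique(y))
    if not u_ok <= {0.0, 1.0}:
        raise ValueError("binomial response must be 0/1")
    n, p = X.shape
    G, K = len(levels), Z.shape[1]
    # dense random-effects design: column g*K + k = Z[:, k] * 1[group == g]
    U = np.zeros((n, G * K))
    for g in range(G):
        m = groups == g
        U[m, g * K:(g + 1) * K] = Z[m]
    W = np.hstack([X, U])

    def laplace_nll(log_tau: np.ndarray, state={"theta": np.zeros(p + G * K)}):
        tau = np.exp(np.clip(log_tau, -8.0, 5.0))
        pen = np.concatenate([np.zeros(p), np.tile(1.0 / tau ** 2, G)])
        theta, mu, H, ll_pen = _pirls(y, W, pen, state["theta"])
        state["theta"] = theta
        Huu = H[p:, p:]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return 1e10
        ll = ll_pen - G * np.log(tau).sum() - 0.5 * logdet
        return -ll

    x0 = np.zeros(K)  # tau = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(laplace_nll, x0, method="Powell",
                                options={"xtol": 1e-3, "ftol": 1e-6,
                                         "maxiter": 200 * K,
                                         "maxfev": 250 * K + 100})
    tau = np.exp(np.clip(res.x, -8.0, 5.0))
    pen = np.concatenate([np.zeros(p), np.tile(1.0 / tau ** 2, G)])
    theta, mu, H, _ = _pirls(y, W, pen, np.zeros(p + G * K))
    loglik = -laplace_nll(res.x)
    cov = np.linalg.pinv(H)
    est = theta[:p]
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    separation = bool(np.abs(est).max() > 25 or not np.isfinite(se).all())
    z = stats.norm.ppf(0.975)
    params = pd.DataFrame({
        "term": names,
        "estimate": est,
        "se": se,
        "ci_lower": est - z * se,
        "ci_upper": est + z * se,
        "p": 2 * stats.norm.sf(np.abs(est) / np.where(se > 0, se, np.nan)),
    })
    varcomp = {f"{t}_sd": float(tau[i]) for i, t in enumerate(rnames)}
    ok = bool(res.success or res.fun < 1e9) and np.isfinite(loglik) and not separation
    return FitResult(params, float(loglik), n, p + K, ok, "binomial",
                     spec, mu, varcomp)


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit a mixed model by ML (Gaussian) or Laplace ML (binomial).

    Random effects are a per-group intercept plus uncorrelated per-term
    slopes. Non-convergent or separated fits are returned with
    ``converged=False`` so downstream inference can refuse them.
    """
    if spec.family == "gaussian":
        return _fit_gaussian(spec, data)
    return _fit_binomial(spec, data)


# ---------------------------------------------------------------------------
# residual spatial autocorrelation


def autocorr_term(residuals: np.ndarray, coords: np.ndarray,
                  group_ids: Sequence, D: float) -> np.ndarray:
    """Gaussian-kernel distance-weighted average of same-group residuals.

    ac_i = sum_{j != i, same group} w_ij e_j / sum w_ij with
    w_ij = exp(-d_ij^2 / (2 D^2)). Observations alone in their group get 0.
    Invariant under rigid motions of the coordinates (depends on distances
    only).
    """
    if D <= 0:
        raise ValueError("D must be positive")
    e = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    gid = np.asarray(group_ids)
    out = np.zeros(len(e))
    for g in np.unique(gid):
        m = np.where(gid == g)[0]
        if len(m) < 2:
            continue
        pts = xy[m]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / (2.0 * D * D))
        np.fill_diagonal(w, 0.0)
        denom = w.sum(axis=1)
        vals = w @ e[m]
        out[m] = np.where(denom > 0, vals / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def optimize_D(
    spec: ModelSpec,
    data: pd.DataFrame,
    D_grid: Sequence[float] = tuple(range(1, 31)),
    coord_cols: tuple[str, str] = ("x", "y"),
    term_name: str = "ac",
) -> tuple[float, FitResult, pd.DataFrame]:
    """Choose the autocorrelation kernel SD maximizing full-model loglik.

    Fits ``spec`` without the term, takes mean-scale residuals, then for
    each D on the grid computes the term, refits the model with it as an
    extra fixed covariate, and returns (D*, refit at D*, profile table).
    Ties break toward the smallest D.
    """
    if len(D_grid) == 0:
        raise ValueError("empty D grid")
    base = fit_mixed(spec, data)
    resid = data[spec.response].to_numpy(dtype=float) - base.fitted
    coords = data[list(coord_cols)].to_numpy(dtype=float)
    gid = data[spec.group].to_numpy()
    full_spec = replace(
        spec,
        fixed=tuple(spec.fixed) + (term_name,),
        random_slopes=(None if spec.random_slopes is None
                       else tuple(spec.random_slopes) + (term_name,)),
        no_standardize=tuple(spec.no_standardize) + (term_name,),
    )
    rows = []
    best: tuple[float, float, FitResult, np.ndarray] | None = None
    for D in D_grid:
        d2 = data.copy()
        ac = autocorr_term(resid, coords, gid, float(D))
        d2[term_name] = ac
        fit = fit_mixed(full_spec, d2)
        rows.append({"D": float(D), "loglik": fit.loglik,
                     "converged": fit.converged})
        if fit.converged and (best is None or fit.loglik > best[1] + 1e-9):
            best = (float(D), fit.loglik, fit, ac)
    profile = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("no converged fit on the D grid")
    profile.attrs["ac"] = best[3]          # the selected term's values
    profile.attrs["base_fit"] = base
    return best[0], best[2], profile


# ---------------------------------------------------------------------------
# inference


def lrt(full: FitResult, null: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square test of nested ML fits."""
    if full.n_obs != null.n_obs:
        raise ValueError("fits are on different data")
    if not (full.converged and null.converged):
        raise ValueError("refusing LRT on non-converged fits")
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    df = full.n_params - null.n_params
    if df <= 0:
        df = max(df, 0)
        return chi2, df, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


def drop1_tests(spec: ModelSpec, data: pd.DataFrame,
                full: FitResult | None = None,
                protected: tuple[str, ...] = ()) -> pd.DataFrame:
    """Single-term LRT deletions respecting marginality.

    Interactions are tested first; a main effect participating in a present
    interaction is not tested (hierarchy respected). ``protected`` terms
    (e.g. controls) are never dropped. Each kept random slope follows its
    fixed term out of the model.
    """
    if full is None:
        full = fit_mixed(spec, data)
    if not full.converged:
        raise ValueError("refusing drop1 on a non-converged full fit")
    interactions = [t for t in spec.fixed if ":" in t]
    in_inter = {c for t in interactions for c in t.split(":")}
    rows = []
    for t in spec.fixed:
        if t in protected:
            continue
        if ":" not in t and t in in_inter:
            continue  # marginality: main effect shielded by its interaction
        reduced = replace(
            spec,
            fixed=tuple(x for x in spec.fixed if x != t),
            random_slopes=(None if spec.random_slopes is None else
                           tuple(x for x in spec.random_slopes if x != t)),
        )
        fit_r = fit_mixed(reduced, data)
        if not fit_r.converged:
            rows.append({"term": t, "chi2": np.nan, "df": np.nan, "p": np.nan,
                         "converged": False})
            continue
        chi2, df, p = lrt(full, fit_r)
        rows.append({"term": t, "chi2": chi2, "df": df, "p": p, "converged": True})
    order = {t: (0 if ":" in t else 1) for t in spec.fixed}
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(by="term", key=lambda s: s.map(order)).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# the three headline models


def _log_with_zero_policy(x: np.ndarray) -> np.ndarray:
    """log of a non-negative rate; zeros get half the minimum positive value."""
    x = np.asarray(x, dtype=float)
    pos = x[x > 0]
    if len(pos) == 0:
        raise ValueError("all rates are zero; nothing to model")
    return np.log(np.where(x > 0, x, 0.5 * pos.min()))


def run_core_models(
    buffer_counts: pd.DataFrame,
    segment_rates: pd.DataFrame,
    quadrats: pd.DataFrame,
    exclude_group: str | None = None,
    D_grid: Sequence[float] = tuple(range(1, 31)),
    min_weeks_rate: int = 1,
) -> dict:
    """Fit the three route-placement models and collect a report.

    * model 1 (Gaussian LMM): tree count per network buffer ~ location type
      (real vs. CSR-simulated mean) + buffer size, random slopes by group.
    * model 2 (Gaussian LMM): log trees-per-meter per segment x buffer ~
      segment usage frequency + buffer size, random slopes by group
      (zero rates get log(half the minimum positive rate)).
    * model 3 (binomial GLMM, twice): quadrat route presence (used >= 2,
      >= 4 weeks) ~ sqrt(slope) + gap presence + relative elevation x
      food-tree density + overlap + core flags + optimized autocorrelation
      term, uncorrelated random slopes by group.

    ``exclude_group`` drops one group from models 1-2 (used when a group's
    range shifted mid-study). Returns fits, per-term drop1 tables, full/null
    comparisons and a flat report table.
    """
    out: dict = {"fits": {}, "drop1": {}, "lrt_full_null": {}}
    rows: list[dict] = []

    bc = buffer_counts.copy()
    sr = segment_rates[segment_rates["weeks_used"] >= min_weeks_rate].copy()
    if exclude_group is not None:
        bc = bc[bc["group_id"] != exclude_group]
        sr = sr[sr["group_id"] != exclude_group]

    # --- model 1
    long = pd.concat([
        bc.assign(type_real=1, n_fts=bc["observed_count"]),
        bc.assign(type_real=0, n_fts=bc["sim_mean"]),
    ], ignore_index=True)[["group_id", "buffer_m", "type_real", "n_fts"]]
    spec1 = ModelSpec("n_fts", ("type_real", "buffer_m"), "group_id",
                      family="gaussian", standardize=False)
    fit1 = fit_mixed(spec1, long)
    null1 = fit_mixed(replace(spec1, fixed=("buffer_m",),
                              random_slopes=("buffer_m",)), long)
    out["fits"]["m1"] = fit1
    if fit1.converged and null1.converged:
        out["lrt_full_null"]["m1"] = lrt(fit1, null1)
    for _, r in fit1.params.iterrows():
        rows.append({"model": "m1", **r})

    # --- model 2
    sr = sr.copy()
    sr["log_tpm"] = _log_with_zero_policy(sr["trees_per_m"].to_numpy())
    spec2 = ModelSpec("log_tpm", ("weeks_used", "buffer_m"), "group_id",
                      family="gaussian", standardize=False)
    fit2 = fit_mixed(spec2, sr)
    null2 = fit_mixed(replace(spec2, fixed=("buffer_m",),
                              random_slopes=("buffer_m",)), sr)
    out["fits"]["m2"] = fit2
    if fit2.converged and null2.converged:
        out["lrt_full_null"]["m2"] = lrt(fit2, null2)
    for _, r in fit2.params.iterrows():
        rows.append({"model": "m2", **r})

    # --- model 3, for each usage threshold
    q = quadrats.copy()
    q["gap_presence"] = (q["gap_pct"] > 0).astype(int)
    fixed3 = ("sqrt(slope_deg)", "gap_presence", "rel_elevation", "ft_density",
              "rel_elevation:ft_density", "overlap_flag", "core_flag")
    controls = ("overlap_flag", "core_flag", "ac")
    for resp in ("route_ge2", "route_ge4"):
        spec3 = ModelSpec(resp, fixed3, "group_id", family="binomial",
                          standardize=True)
        D, fit3, profile = optimize_D(spec3, q, D_grid=D_grid)
        d3 = q.copy()
        d3["ac"] = profile.attrs["ac"]
        full_spec = fit3.spec
        null_spec = replace(full_spec,
                            fixed=tuple(t for t in full_spec.fixed
                                        if t in controls),
                            random_slopes=None)
        null3 = fit_mixed(null_spec, d3)
        out["fits"][f"m3_{resp}"] = fit3
        out["lrt_full_null"][f"m3_{resp}"] = (
            lrt(fit3, null3) if (fit3.converged and null3.converged) else None
        )
        out[f"D_{resp}"] = D
        out[f"D_profile_{resp}"] = profile
        try:
            out["drop1"][f"m3_{resp}"] = drop1_tests(
                full_spec, d3, full=fit3, protected=controls)
        except ValueError:
            out["drop1"][f"m3_{resp}"] = pd.DataFrame()
        for _, r in fit3.params.iterrows():
            rows.append({"model": f"m3_{resp}", **r})

    out["report"] = pd.DataFrame(rows)
    return out
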