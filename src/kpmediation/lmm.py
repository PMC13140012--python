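"""Random-intercept linear mixed models by profiled REML.

The only random effect the mediation pipeline ever needs is a per-subject
intercept, so the model is

    y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)

with clusters i (subjects) and within-cluster records j (visits). For
this structure REML reduces to a one-dimensional optimization over the
variance ratio lambda = tau^2 / sigma^2: at fixed lambda the GLS fixed
effects, the residual variance and the restricted log-likelihood are all
closed-form, using the rank-one cluster precision

    W_i = I - lambda / (1 + lambda * n_i) * J_i      (V_i = sigma^2 (I + lambda J_i))

so each candidate lambda costs O(sum n_i * p + G * p^2). The boundary
lambda = 0 is always evaluated explicitly and clamped, at which point the
fit is exactly ordinary least squares. Inference on fixed effects is
Wald/normal (z), matching the Monte Carlo procedure downstream which
samples coefficients from normal distributions at the REML covariance.

Estimation is deterministic; no small-sample (Satterthwaite /
Kenward-Roger) degrees-of-freedom correction is applied.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

try:  # sklearn is only needed for the estimator base conveniences
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .errors import ContractError, ConvergenceError, SingularFitError

#: Reference level of each categorical covariate (first level of its
#: natural ordering); remaining levels are dummy-coded against it.
DEFAULT_REFERENCE_LEVELS = {
    "sex": "male",
    "chemotherapy": "no",
    "stoma": "no",
    "comorbidities": "0",
    "smoking": "never",
    "education": "low",
}

#: Natural level orderings used when expanding dummies.
CATEGORY_LEVELS = {
    "sex": ("male", "female"),
    "chemotherapy": ("no", "yes"),
    "stoma": ("no", "yes"),
    "comorbidities": ("0", "1", "2+"),
    "smoking": ("never", "former", "current"),
    "education": ("low", "medium", "high"),
}


def build_design(
    df: pd.DataFrame,
    terms: Sequence[str],
    reference_levels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Expand ``terms`` into an intercept-first numeric design matrix.

    Continuous columns enter as-is; categorical columns (object/category
    dtype) are reference-coded with dummies named ``col[level]``.
    """
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    for term in terms:
        col = df[term]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            observed = [str(v) for v in pd.unique(col.dropna())]
            order = [
                lv for lv in CATEGORY_LEVELS.get(term, sorted(observed))
                if lv in observed
            ]
            order += [lv for lv in observed if lv not in order]
            ref = refs.get(term, order[0] if order else None)
            for lv in order:
                if lv == ref:
                    continue
                cols[f"{term}[{lv}]"] = (col.astype(str) == lv).to_numpy(float)
        else:
            cols[term] = col.to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    bad = np.flatnonzero(d < tol)
    if bad.size:
        raise SingularFitError([names[piv[i]] for i in bad])


class RandomInterceptLMM(BaseEstimator):
    """Linear mixed model with a single random intercept, fitted by REML.

    Parameters
    ----------
    response
        Name of the outcome column.
    terms
        Fixed-effect columns (continuous, or categorical to be
        reference-coded). The intercept is always included.
    groups
        Clustering column (the subject identifier).
    reference_levels
        Overrides for categorical reference levels.
    tol
        Relative tolerance on the restricted log-likelihood.
    maxiter
        Maximum optimizer iterations.

    Fitted attributes (trailing underscore) follow scikit-learn
    conventions: ``params_``, ``bse_``, ``cov_params_``,
    ``random_intercept_var_``, ``resid_var_``, ``n_obs_``, ``n_groups_``,
    ``n_dropped_``, ``converged_``.
    """

    def __init__(
        self,
        response: str,
        terms: Sequence[str] = (),
        groups: str = "subject_id",
        reference_levels: Mapping[str, str] | None = None,
        tol: float = 1e-8,
        maxiter: int = 200,
    ):
        self.response = response
        self.terms = tuple(terms)
        self.groups = groups
        self.reference_levels = reference_levels
        self.tol = tol
        self.maxiter = maxiter

    # -- internals -----------------------------------------------------
    @staticmethod
    def _profile(lam, n_i, xtx, xty, yty, S, t, n, p):
        """Profiled REML criterion and GLS solution at variance ratio lam."""
        c = lam / (1.0 + lam * n_i)  # per-cluster rank-one downweight
        xtwx = xtx - (S * c[:, None]).T @ S
        xtwy = xty - S.T @ (c * t)
        ytwy = yty - np.sum(c * t * t)
        cho = linalg.cho_factor(xtwx)
        beta = linalg.cho_solve(cho, xtwy)
        rss = ytwy - beta @ xtwy
        sigma2 = rss / (n - p)
        logdet_xtwx = 2.0 * np.sum(np.log(np.diag(cho[0])))
        # -2 * restricted log-likelihood, up to an additive constant
        crit = (
            (n - p) * np.log(sigma2)
            + np.sum(np.log1p(lam * n_i))
            + logdet_xtwx
        )
        return crit, beta, sigma2, xtwx

    def fit(self, data: pd.DataFrame) -> "RandomInterceptLMM":
        """Fit on a long-format table; listwise-deletes incomplete rows."""
        if self.response in self.terms:
            raise ContractError("response cannot appear among fixed terms")
        needed = [self.response, *self.terms, self.groups]
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise ContractError(f"columns not in data: {missing}")
        sub = data[needed].dropna()
        self.n_dropped_ = len(data) - len(sub)
        codes, _ = pd.factorize(sub[self.groups])
        n_groups = codes.max() + 1 if len(codes) else 0
        if n_groups < 2:
            raise ContractError("need >= 2 subjects with complete records")

        design = build_design(sub, self.terms, self.reference_levels)
        names = list(design.columns)
        X = design.to_numpy(float)
        y = sub[self.response].to_numpy(float)
        n, p = X.shape
        if n <= p:
            raise ContractError(f"{n} records cannot identify {p} fixed effects")
        _check_rank(X, names)

        # sufficient statistics: totals and per-cluster sums
        xtx, xty, yty = X.T @ X, X.T @ y, float(y @ y)
        n_i = np.bincount(codes).astype(float)
        S = np.zeros((n_groups, p))
        np.add.at(S, codes, X)
        t = np.bincount(codes, weights=y)

        def crit(log_lam):
            return self._profile(
                np.exp(log_lam), n_i, xtx, xty, yty, S, t, n, p
            )[0]

        res = optimize.minimize_scalar(
            crit,
            bounds=(-25.0, 25.0),
            method="bounded",
            options={"xatol": self.tol, "maxiter": self.maxiter},
        )
        if not res.success:  # pragma: no cover - bounded Brent rarely fails
            raise ConvergenceError(
                "REML optimization did not converge",
                diagnostics={"log_lambda": float(res.x), "criterion": float(res.fun)},
            )
        lam = float(np.exp(res.x))
        c0 = self._profile(0.0, n_i, xtx, xty, yty, S, t, n, p)[0]
        # boundary clamp: variance ratio estimated at (or below) zero
        if c0 <= res.fun + self.tol * abs(c0) or lam < 1e-10:
            lam = 0.0
        crit_val, beta, sigma2, xtwx = self._profile(
            lam, n_i, xtx, xty, yty, S, t, n, p
        )

        cov = sigma2 * linalg.inv(xtwx)
        cov = (cov + cov.T) / 2.0
        self.design_columns_ = names
        self.params_ = pd.Series(beta, index=names)
        self.cov_params_ = pd.DataFrame(cov, index=names, columns=names)
        self.bse_ = pd.Series(np.sqrt(np.diag(cov)), index=names)
        self.random_intercept_var_ = lam * sigma2
        self.resid_var_ = float(sigma2)
        self.n_obs_ = int(n)
        self.n_groups_ = int(n_groups)
        self.converged_ = True
        self.reml_criterion_ = float(crit_val)
        return self

    # -- post-fit API --------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise ContractError("model is not fitted yet; call fit first")

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Population-level (fixed-effects only) prediction."""
        self._check_fitted()
        design = build_design(data, self.terms, self.reference_levels)
        design = design.reindex(columns=self.design_columns_, fill_value=0.0)
        return design.to_numpy(float) @ self.params_.to_numpy()

    def coef(self, term: str) -> tuple[float, float]:
        """(estimate, SE) of one design column."""
        self._check_fitted()
        if term not in self.params_.index:
            raise ContractError(
                f"unknown term {term!r}; have {list(self.params_.index)}"
            )
        return float(self.params_[term]), float(self.bse_[term])

    def summary_frame(self) -> pd.DataFrame:
        """Flat per-term results (estimate, SE, z, p, Wald CI) for audit."""
        self._check_fitted()
        est, se = self.params_.to_numpy(), self.bse_.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, est / se, np.inf * np.sign(est))
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        zq = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {
                "term": self.params_.index,
                "estimate": est,
                "se": se,
                "z": z,
                "p": pvals,
                "ci_lower": est - zq * se,
                "ci_upper": est + zq * se,
            }
        ).reset_index(drop=True)


def fit_random_intercept(
    response: str,
    terms: Sequence[str],
    data: pd.DataFrame,
    groups: str = "subject_id",
    **kwargs,
) -> RandomInterceptLMM:
    """Functional wrapper over :class:`RandomInterceptLMM`."""
    return RandomInterceptLMM(response, terms, groups=groups, **kwargs).fit(data)


def normal_interval(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-based (Wald) interval ``estimate +/- z * se``."""
    if not 0.0 < level < 1.0:
        raise ContractError("confidence level must be in (0, 1)")
    if se < 0:
        raise ContractError("standard error must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return estimate - z * se, estimate + z * se


def wald_interval(
    fit: RandomInterceptLMM, term: str, level: float = 0.95
) -> tuple[float, float]:
    """Wald interval for one fixed-effect term of a fitted model."""
    est, se = fit.coef(term)
    return normal_interval(est, se, level)
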