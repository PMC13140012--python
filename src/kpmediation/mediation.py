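"""Parallel-multiple and single mediator decompositions.

One analysis relates a dietary exposure X (per-SD standardized), a set of
mediators M_1..M_K (the nine kynurenine-pathway metabolites together, or
a single metabolite ratio), and an HRQoL outcome Y, all measured
repeatedly per subject:

* a-paths: one random-intercept model per mediator, M_k ~ X + covariates;
* outcome model: Y ~ X + M_1 + ... + M_K + covariates, giving the
  b-paths and the direct effect c' simultaneously;
* mediator-specific indirect effects a_k * b_k, the total indirect
  effect sum_k a_k b_k, and the total effect c' + sum_k a_k b_k.

Because the mediators are measured simultaneously in plasma, no causal
ordering among them is assumed: the products are reported as
*interventional* indirect effects (the effect through M_k and anything
causally upstream of it), which is exactly what the parallel model
identifies. Confidence intervals come from :mod:`kpmediation.montecarlo`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .cohort import LongCohortTable
from .derived import StandardizationScale, apply_standardization, standardization_scale
from .errors import ContractError
from .lmm import RandomInterceptLMM, normal_interval
from .montecarlo import (
    IntervalEstimate,
    MCConfig,
    mc_composite_ci,
    mc_product_ci,
    significance_flag,
)


@dataclass(frozen=True)
class ModelSpec:
    """One mediation analysis: exposure, mediator set, outcome, covariates."""

    exposure: str
    mediators: tuple[str, ...]
    outcome: str
    covariates: tuple[str, ...] = ()
    standardize: bool = True

    def __post_init__(self):
        if not self.mediators:
            raise ContractError("mediator set must be non-empty")
        overlap = set(self.mediators) & ({self.exposure} | set(self.covariates))
        if overlap:
            raise ContractError(f"mediators overlap exposure/covariates: {overlap}")
        if self.outcome in self.mediators:
            raise ContractError("outcome cannot be a mediator")


@dataclass
class PathFits:
    """Fitted a-path models and the joint outcome model of one spec."""

    exposure_term: str
    mediators: tuple[str, ...]
    a_fits: list[RandomInterceptLMM]
    outcome_fit: RandomInterceptLMM
    scale: StandardizationScale | None = None

    @property
    def a(self) -> np.ndarray:
        return np.array([f.coef(self.exposure_term)[0] for f in self.a_fits])

    @property
    def se_a(self) -> np.ndarray:
        return np.array([f.coef(self.exposure_term)[1] for f in self.a_fits])

    @property
    def b(self) -> np.ndarray:
        return np.array([self.outcome_fit.coef(m)[0] for m in self.mediators])

    @property
    def se_b(self) -> np.ndarray:
        return np.array([self.outcome_fit.coef(m)[1] for m in self.mediators])

    @property
    def c_prime(self) -> float:
        return self.outcome_fit.coef(self.exposure_term)[0]

    @property
    def se_c_prime(self) -> float:
        return self.outcome_fit.coef(self.exposure_term)[1]

    @property
    def cov_cb(self) -> np.ndarray:
        """Outcome-model covariance over (c', b_1..b_K)."""
        idx = [self.exposure_term, *self.mediators]
        return self.outcome_fit.cov_params_.loc[idx, idx].to_numpy()


@dataclass
class MediationEstimates:
    """Effect decomposition of one fitted spec, with optional intervals."""

    mediators: tuple[str, ...]
    a: np.ndarray
    se_a: np.ndarray
    b: np.ndarray
    se_b: np.ndarray
    indirect: np.ndarray
    total_indirect: float
    direct: float
    total: float
    intervals: dict[str, IntervalEstimate] = field(default_factory=dict)

    def __post_init__(self):
        # decomposition identities must hold to machine precision
        assert np.isclose(
            self.total_indirect, float(np.sum(self.indirect)), rtol=0, atol=1e-12
        )
        assert np.isclose(
            self.total, self.direct + self.total_indirect, rtol=0, atol=1e-12
        )


def total_from_paths(direct: float, indirects: Sequence[float]) -> float:
    """Total effect as direct plus the sum of per-mediator indirects."""
    return float(direct + np.sum(np.asarray(indirects, float)))


def decompose(paths: PathFits) -> MediationEstimates:
    """Point-estimate decomposition (products, sums) of fitted paths."""
    a, b = paths.a, paths.b
    indirect = a * b
    total_indirect = float(np.sum(indirect))
    direct = float(paths.c_prime)
    return MediationEstimates(
        mediators=paths.mediators,
        a=a,
        se_a=paths.se_a,
        b=b,
        se_b=paths.se_b,
        indirect=indirect,
        total_indirect=total_indirect,
        direct=direct,
        total=total_from_paths(direct, indirect),
    )


def add_intervals(
    estimates: MediationEstimates, paths: PathFits, cfg: MCConfig
) -> MediationEstimates:
    """Attach Monte Carlo / Wald intervals to a decomposition in place."""
    rng = cfg.rng()
    for k, name in enumerate(estimates.mediators):
        estimates.intervals[f"indirect:{name}"] = mc_product_ci(
            estimates.a[k], estimates.se_a[k],
            estimates.b[k], estimates.se_b[k],
            cfg, rng=rng,
        )
    estimates.intervals["total_indirect"] = mc_composite_ci(
        paths.c_prime, estimates.a, estimates.se_a, estimates.b,
        paths.cov_cb, "total_indirect", cfg, rng=rng,
    )
    lo, hi = normal_interval(paths.c_prime, paths.se_c_prime, cfg.level)
    estimates.intervals["direct"] = IntervalEstimate(
        paths.c_prime, lo, hi, "normal", cfg.level
    )
    estimates.intervals["total"] = mc_composite_ci(
        paths.c_prime, estimates.a, estimates.se_a, estimates.b,
        paths.cov_cb, "total_effect", cfg, rng=rng,
    )
    return estimates


class MediationModel(BaseEstimator):
    """Multilevel mediation analysis as a scikit-learn style estimator.

    Parameters mirror :class:`ModelSpec` plus the Monte Carlo settings.
    ``fit`` standardizes the exposure (dividing by the mean of per-visit
    SDs), fits the a-path and outcome random-intercept models, decomposes
    the effects and computes intervals. Fitted attributes:

    ``paths_`` (:class:`PathFits`), ``estimates_``
    (:class:`MediationEstimates`), ``scale_`` (per-SD scale or None),
    ``results_`` (tidy one-row-per-effect DataFrame).
    """

    def __init__(
        self,
        exposure: str,
        mediators: Sequence[str],
        outcome: str,
        covariates: Sequence[str] = (),
        groups: str = "subject_id",
        standardize: bool = True,
        draws: int = 20_000,
        level: float = 0.95,
        random_state: int | None = None,
        joint_outcome_block: bool = True,
    ):
        self.exposure = exposure
        self.mediators = tuple(mediators)
        self.outcome = outcome
        self.covariates = tuple(covariates)
        self.groups = groups
        self.standardize = standardize
        self.draws = draws
        self.level = level
        self.random_state = random_state
        self.joint_outcome_block = joint_outcome_block

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            self.exposure, self.mediators, self.outcome,
            self.covariates, self.standardize,
        )

    def fit(self, data: pd.DataFrame | LongCohortTable) -> "MediationModel":
        spec = self._spec()  # validates the variable roles
        df = data.data if isinstance(data, LongCohortTable) else data
        df = df.copy()
        if self.standardize:
            self.scale_ = standardization_scale(df, self.exposure)
            xterm = f"{self.exposure}_per_sd"
            df[xterm] = apply_standardization(df[self.exposure], self.scale_)
        else:
            self.scale_ = None
            xterm = self.exposure

        cov = list(spec.covariates)
        a_fits = [
            RandomInterceptLMM(m, [xterm, *cov], groups=self.groups).fit(df)
            for m in spec.mediators
        ]
        outcome_fit = RandomInterceptLMM(
            self.outcome, [xterm, *spec.mediators, *cov], groups=self.groups
        ).fit(df)
        self.paths_ = PathFits(
            xterm, spec.mediators, a_fits, outcome_fit, self.scale_
        )
        cfg = MCConfig(
            draws=self.draws,
            level=self.level,
            seed=self.random_state,
            joint_outcome_block=self.joint_outcome_block,
        )
        self.estimates_ = add_intervals(decompose(self.paths_), self.paths_, cfg)
        self.results_ = self._tidy()
        return self

    # -- reporting -----------------------------------------------------
    def _tidy(self) -> pd.DataFrame:
        est = self.estimates_
        paths = self.paths_
        rows = []

        def row(effect, mediator, value, se=None, interval=None):
            rows.append(
                {
                    "exposure": self.exposure,
                    "outcome": self.outcome,
                    "mediator": mediator,
                    "effect": effect,
                    "estimate": value,
                    "se": se,
                    "ci_lower": interval.lower if interval else None,
                    "ci_upper": interval.upper if interval else None,
                    "ci_method": interval.method if interval else None,
                    "significant": (
                        significance_flag(interval) if interval else None
                    ),
                }
            )

        for k, m in enumerate(est.mediators):
            row("a_path", m, est.a[k], est.se_a[k])
            row("b_path", m, est.b[k], est.se_b[k])
            row("indirect", m, est.indirect[k],
                interval=est.intervals[f"indirect:{m}"])
        row("total_indirect", None, est.total_indirect,
            interval=est.intervals["total_indirect"])
        row("direct", None, est.direct, paths.se_c_prime,
            interval=est.intervals["direct"])
        row("total", None, est.total, interval=est.intervals["total"])
        out = pd.DataFrame(rows)
        out["n_records"] = paths.outcome_fit.n_obs_
        out["n_subjects"] = paths.outcome_fit.n_groups_
        return out


def fit_a_paths(
    spec: ModelSpec, data: pd.DataFrame, exposure_term: str | None = None,
    groups: str = "subject_id",
) -> list[RandomInterceptLMM]:
    """One random-intercept fit per mediator (mediator as response)."""
    xterm = exposure_term or spec.exposure
    return [
        RandomInterceptLMM(m, [xterm, *spec.covariates], groups=groups).fit(data)
        for m in spec.mediators
    ]


def fit_outcome_model(
    spec: ModelSpec, data: pd.DataFrame, exposure_term: str | None = None,
    groups: str = "subject_id",
) -> RandomInterceptLMM:
    """Outcome on exposure + all mediators + covariates (b-paths and c')."""
    xterm = exposure_term or spec.exposure
    return RandomInterceptLMM(
        spec.outcome, [xterm, *spec.mediators, *spec.covariates], groups=groups
    ).fit(data)
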