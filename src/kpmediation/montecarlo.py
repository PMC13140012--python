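"""Monte Carlo confidence intervals for products of path coefficients.

The sampling distribution of an indirect effect a*b is skewed even when
a-hat and b-hat are each normal, so symmetric Wald intervals undercover.
The distribution-of-the-product approach instead simulates the
coefficient sampling distributions: draw a* ~ N(a-hat, SE_a^2) and
b* ~ N(b-hat, SE_b^2) (jointly multivariate normal for coefficients that
come from the same fitted model, using that model's covariance block),
form the product (or sum of products) per draw, and read off empirical
percentiles. Default 20,000 draws, 95% level.

Mediator-model coefficients a_k come from separate fits and are drawn
independently of each other and of the outcome-model block (c', b_1..b_K),
which is drawn jointly at the outcome fit's covariance. Direct and total
effects use normal-based intervals, the total effect taking its SE from
the Monte Carlo SD of the composite draw c'* + sum_k a_k* b_k*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ContractError, DomainError


@dataclass(frozen=True)
class MCConfig:
    """Draw count, level and seeding of the Monte Carlo procedure."""

    draws: int = 20_000
    level: float = 0.95
    seed: int | None = None
    joint_outcome_block: bool = True

    def __post_init__(self):
        if self.draws < 1000:
            raise ContractError("Monte Carlo needs >= 1000 draws")
        if not 0.0 < self.level < 1.0:
            raise ContractError("confidence level must be in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a confidence interval and its provenance."""

    estimate: float
    lower: float
    upper: float
    method: str  # "mc_percentile" | "normal"
    level: float = 0.95
    draw_mean: float | None = None
    draw_sd: float | None = None

    def __post_init__(self):
        if self.lower > self.upper:
            raise DomainError("interval has lower > upper")


def _percentiles(draws: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def mc_product_ci(
    a: float,
    se_a: float,
    b: float,
    se_b: float,
    cfg: MCConfig = MCConfig(),
    rng: np.random.Generator | None = None,
) -> IntervalEstimate:
    """Percentile interval for the product of two independent normals.

    The point estimate is the plain product ``a * b`` (not the mean of
    the draws, which carries the product-of-estimators bias).
    """
    if se_a < 0 or se_b < 0:
        raise ContractError("standard errors must be non-negative")
    rng = cfg.rng() if rng is None else rng
    prod = rng.normal(a, se_a, cfg.draws) * rng.normal(b, se_b, cfg.draws)
    lo, hi = _percentiles(prod, cfg.level)
    return IntervalEstimate(
        estimate=a * b,
        lower=lo,
        upper=hi,
        method="mc_percentile",
        level=cfg.level,
        draw_mean=float(prod.mean()),
        draw_sd=float(prod.std(ddof=1)),
    )


def _check_psd(cov: np.ndarray) -> None:
    cov = np.asarray(cov, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise DomainError("covariance block must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise DomainError("covariance block must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise DomainError("covariance block is not positive semidefinite")


def mc_composite_ci(
    c_prime: float,
    a: Sequence[float],
    se_a: Sequence[float],
    b: Sequence[float],
    cov_cb: np.ndarray,
    target: str,
    cfg: MCConfig = MCConfig(),
    rng: np.random.Generator | None = None,
) -> IntervalEstimate:
    """Interval for the total indirect or total effect of K mediators.

    ``cov_cb`` is the (K+1) x (K+1) outcome-model covariance over
    (c', b_1 .. b_K). Per draw, (c'*, b*) is sampled jointly from a
    multivariate normal at that covariance while each a_k* is drawn
    independently; the total-indirect draw is sum_k a_k* b_k*.

    * ``target="total_indirect"``: percentile interval of the draws,
      point estimate sum_k a_k b_k.
    * ``target="total_effect"``: normal-based interval around
      c' + sum_k a_k b_k with SE = SD of the composite draws
      c'* + sum_k a_k* b_k*.
    """
    a = np.asarray(a, float)
    se_a = np.asarray(se_a, float)
    b = np.asarray(b, float)
    k = a.size
    if not (se_a.size == b.size == k):
        raise ContractError("a, se_a, b must have equal length")
    if (se_a < 0).any():
        raise ContractError("standard errors must be non-negative")
    cov_cb = np.asarray(cov_cb, float)
    if cov_cb.shape != (k + 1, k + 1):
        raise ContractError(
            f"cov_cb must be ({k + 1}, {k + 1}) over (c', b_1..b_K)"
        )
    _check_psd(cov_cb)
    if target not in ("total_indirect", "total_effect"):
        raise ContractError(f"unknown target {target!r}")

    rng = cfg.rng() if rng is None else rng
    mean_cb = np.concatenate([[c_prime], b])
    if cfg.joint_outcome_block:
        cb = rng.multivariate_normal(
            mean_cb, cov_cb, size=cfg.draws, method="svd"
        )
    else:  # marginal draws, within-model dependence ignored
        cb = rng.normal(
            mean_cb, np.sqrt(np.diag(cov_cb)), size=(cfg.draws, k + 1)
        )
    a_draws = rng.normal(a, se_a, size=(cfg.draws, k))
    ti_draws = np.sum(a_draws * cb[:, 1:], axis=1)

    if target == "total_indirect":
        lo, hi = _percentiles(ti_draws, cfg.level)
        return IntervalEstimate(
            estimate=float(a @ b),
            lower=lo,
            upper=hi,
            method="mc_percentile",
            level=cfg.level,
            draw_mean=float(ti_draws.mean()),
            draw_sd=float(ti_draws.std(ddof=1)),
        )
    total_draws = cb[:, 0] + ti_draws
    est = float(c_prime + a @ b)
    sd = float(total_draws.std(ddof=1))
    z = stats.norm.ppf(0.5 + cfg.level / 2.0)
    return IntervalEstimate(
        estimate=est,
        lower=est - z * sd,
        upper=est + z * sd,
        method="normal",
        level=cfg.level,
        draw_mean=float(total_draws.mean()),
        draw_sd=sd,
    )


def product_sum_variance(
    a: Sequence[float],
    se_a: Sequence[float],
    b: Sequence[float],
    cov_b: np.ndarray,
) -> float:
    """Exact variance of sum_k a_k* b_k* under the sampling model.

    With a_k* independent N(a_k, se_a_k^2) and b* ~ MVN(b, cov_b)
    independent of the a*'s, exact moments give

        Var = sum_k (a_k^2 S_kk + b_k^2 se_a_k^2 + se_a_k^2 S_kk)
              + sum_{j != k} a_j a_k S_jk

    where S = cov_b. Serves as the analytic oracle for the Monte Carlo
    spread of the total indirect effect.
    """
    a = np.asarray(a, float)
    se_a = np.asarray(se_a, float)
    b = np.asarray(b, float)
    S = np.asarray(cov_b, float)
    var = float(
        np.sum(a**2 * np.diag(S) + b**2 * se_a**2 + se_a**2 * np.diag(S))
    )
    off = S - np.diag(np.diag(S))
    var += float(a @ off @ a)
    return var


def significance_flag(interval: IntervalEstimate) -> bool:
    """True iff zero lies strictly outside the interval.

    An interval touching zero exactly counts as covering it (ties are
    non-significant), mirroring the two-sided p < .05 rule.
    """
    return bool(interval.lower > 0.0 or interval.upper < 0.0)
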