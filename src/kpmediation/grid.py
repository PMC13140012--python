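"""Config-driven analysis grid: every exposure x mediator set x outcome.

The default grid mirrors the full analysis surface: 17 dietary exposures
(11 macronutrient intakes in kcal/day, 4 micronutrients, 2 dietary
pattern scores), 4 mediator sets (all nine metabolites in parallel, or
one of the ratios KTR / HKr / KA-QA as single mediator), and the two
primary HRQoL outcomes — 136 cells. Each cell standardizes its exposure,
builds the scheme-appropriate energy-adjustment covariates, fits the
path models and reports the full effect decomposition with intervals.

A failed cell (rank deficiency, too few complete cases, ...) yields an
error row; the rest of the grid completes. Cell-level RNG seeds derive
deterministically from the grid seed, so a grid run is a pure function
of (cohort, config, seed). No multiplicity correction is applied — the
number of tests performed is logged as a caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .cohort import LongCohortTable
from .derived import EXPOSURE_SCHEME, METABOLITES, build_covariates
from .errors import ContractError
from .mediation import MediationModel, ModelSpec

log = logging.getLogger(__name__)

try:
    __version__ = version("kpmediation")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"

MEDIATOR_SETS: dict[str, tuple[str, ...]] = {
    "all_metabolites": METABOLITES,
    "KTR": ("KTR",),
    "HKr": ("HKr",),
    "KA_QA": ("KA_QA",),
}

DEFAULT_EXPOSURES = tuple(EXPOSURE_SCHEME)  # 11 macro + 4 micro + 2 patterns
PRIMARY_OUTCOMES = ("physical_functioning", "role_functioning")
SECONDARY_OUTCOMES = ("global_qol", "summary_score")


@dataclass
class AnalysisGrid:
    """Exposure / mediator-set / outcome grid plus Monte Carlo settings."""

    exposures: tuple[str, ...] = DEFAULT_EXPOSURES
    mediator_sets: tuple[str, ...] = tuple(MEDIATOR_SETS)
    outcomes: tuple[str, ...] = PRIMARY_OUTCOMES
    draws: int = 20_000
    level: float = 0.95
    seed: int = 0
    extra_mediator_sets: dict = field(default_factory=dict)

    def mediators_of(self, set_name: str) -> tuple[str, ...]:
        if set_name in self.extra_mediator_sets:
            return tuple(self.extra_mediator_sets[set_name])
        try:
            return MEDIATOR_SETS[set_name]
        except KeyError:
            raise ContractError(f"unknown mediator set {set_name!r}") from None

    def resolve(self, table: LongCohortTable | pd.DataFrame) -> list[dict]:
        """Expand and validate every grid cell before any fitting.

        Raises :class:`ContractError` if any cell cannot be resolved to
        a valid :class:`ModelSpec` against the table's columns.
        """
        df = table.data if isinstance(table, LongCohortTable) else table
        cells = []
        for exposure in self.exposures:
            covariates = tuple(build_covariates(exposure))
            for set_name in self.mediator_sets:
                mediators = self.mediators_of(set_name)
                for outcome in self.outcomes:
                    spec = ModelSpec(exposure, mediators, outcome, covariates)
                    needed = {exposure, outcome, *mediators, *covariates}
                    missing = sorted(needed - set(df.columns))
                    if missing:
                        raise ContractError(
                            f"grid cell ({exposure}, {set_name}, {outcome}): "
                            f"missing column(s) {missing}"
                        )
                    cells.append(
                        {"spec": spec, "mediator_set": set_name,
                         "exposure": exposure, "outcome": outcome}
                    )
        return cells


def run_grid(
    grid: AnalysisGrid, table: LongCohortTable | pd.DataFrame
) -> pd.DataFrame:
    """Execute every grid cell; failed cells become error rows."""
    cells = grid.resolve(table)
    log.info(
        "running %d grid cells at alpha=%.3g with no multiplicity "
        "correction (%d significance tests will be performed)",
        len(cells), 1.0 - grid.level, len(cells),
    )
    frames = []
    for i, cell in enumerate(cells):
        spec: ModelSpec = cell["spec"]
        model = MediationModel(
            exposure=spec.exposure,
            mediators=spec.mediators,
            outcome=spec.outcome,
            covariates=spec.covariates,
            draws=grid.draws,
            level=grid.level,
            random_state=grid.seed + i,
        )
        try:
            model.fit(table)
            res = model.results_.copy()
            res["error"] = None
            log.info(
                "cell (%s, %s, %s): n=%d records / %d subjects, "
                "%d rows dropped listwise in the outcome model",
                spec.exposure, cell["mediator_set"], spec.outcome,
                model.paths_.outcome_fit.n_obs_,
                model.paths_.outcome_fit.n_groups_,
                model.paths_.outcome_fit.n_dropped_,
            )
        except Exception as exc:  # fault isolation: record, continue
            log.warning(
                "cell (%s, %s, %s) failed: %s",
                spec.exposure, cell["mediator_set"], spec.outcome, exc,
            )
            res = pd.DataFrame(
                [{"exposure": spec.exposure, "outcome": spec.outcome,
                  "mediator": None, "effect": "error",
                  "estimate": float("nan"), "se": float("nan"),
                  "ci_lower": float("nan"), "ci_upper": float("nan"),
                  "ci_method": None, "significant": None,
                  "n_records": float("nan"), "n_subjects": float("nan"),
                  "error": f"{type(exc).__name__}: {exc}"}]
            )
        res["mediator_set"] = cell["mediator_set"]
        res["cell_seed"] = grid.seed + i
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out["software_version"] = __version__
    return out


def render_results(
    results: pd.DataFrame, style: str = "long", path: str | Path | None = None
) -> str:
    """Serialize a results table.

    ``long``: tidy CSV at full precision. ``paperlike``: per-exposure
    blocks with "estimate (lower, upper)" strings rounded to 2 decimals
    and significant entries starred. Rounding happens only here.
    """
    if len(results) == 0:
        raise ContractError("results table is empty")
    if style == "long":
        text = results.to_csv(index=False)
    elif style == "paperlike":
        lines = []
        ok = results[results["effect"] != "error"]
        for (exp, mset, out), grp in ok.groupby(
            ["exposure", "mediator_set", "outcome"], sort=False
        ):
            lines.append(f"== {exp} | mediators: {mset} | outcome: {out} ==")
            for _, r in grp.iterrows():
                label = r["effect"] + (f" [{r['mediator']}]" if r["mediator"] else "")
                if pd.notna(r.get("ci_lower")):
                    cell = format_estimate(r["estimate"], r["ci_lower"], r["ci_upper"])
                    star = " *" if r.get("significant") else ""
                else:
                    cell = f"{r['estimate']:.2f}"
                    star = ""
                lines.append(f"  {label:<28s} {cell}{star}")
            lines.append("")
        text = "\n".join(lines)
    else:
        raise ContractError(f"unknown render style {style!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def format_estimate(estimate: float, lower: float, upper: float) -> str:
    """Report-style "estimate (lower, upper)" rounded to 2 decimals."""
    return f"{estimate:.2f} ({lower:.2f}, {upper:.2f})"
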