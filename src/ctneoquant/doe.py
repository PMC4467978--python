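"""Fractional factorial design and standardized-effect Pareto screening.

The staining study varies three factors at three levels each — neo-tissue
volume (low/mid/high culture condition), staining time (30/120/240 min) and
contrast-agent concentration — in a 9-run fractional factorial design (a
Graeco-Latin square: one third of the full 3^3 factorial, orthogonal in
every factor pair). Main effects are estimated by ordinary least squares of
the response on the coded linear factor levels (-1/0/+1); the standardized
effect of a factor is |coefficient| / SE(coefficient), a |t| statistic, and
a factor is significant when its standardized effect exceeds the two-sided
t critical value at alpha = 0.05 with the residual degrees of freedom — the
reference line of the Pareto chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FactorSpec",
    "DoEDesign",
    "EffectsTable",
    "DEFAULT_FACTORS",
    "build_design",
    "fit_main_effects",
    "pareto_data",
]


@dataclass(frozen=True)
class FactorSpec:
    """One design factor: a name and its three physical level values."""

    name: str
    levels: tuple = (0, 1, 2)   # physical values, low -> high

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError(f"factor {self.name!r} needs exactly 3 levels")


#: The staining study's factors: neo-tissue volume level (coded by culture
#: condition), staining time in minutes, and contrast-agent concentration
#: (volume % for an equilibrium agent; the tungstate stain uses 2.5/5/7.5
#: weight %).
DEFAULT_FACTORS = (
    FactorSpec("neo_tissue_volume", ("low", "mid", "high")),
    FactorSpec("staining_time_min", (30, 120, 240)),
    FactorSpec("concentration_pct", (20, 40, 60)),
)


@dataclass
class DoEDesign:
    """A 9-run, 3-factor, 3-level orthogonal design.

    ``runs`` holds level indices (0/1/2 per factor); ``coded()`` maps them
    to -1/0/+1. Each level of each factor appears exactly three times and
    every ordered level pair of any two factors appears exactly once.
    """

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    runs: np.ndarray          # (9, 3) level indices, in randomized run order
    replicates: int = 3
    seed: int = 0

    def coded(self) -> np.ndarray:
        return self.runs.astype(float) - 1.0

    def physical(self) -> list[tuple]:
        return [tuple(f.levels[k] for f, k in zip(self.factors, row))
                for row in self.runs]


def build_design(factor_specs=DEFAULT_FACTORS, seed: int = 0,
                 replicates: int = 3) -> DoEDesign:
    """Build the 9-run Graeco-Latin-square design used by the staining study.

    The run set is fixed — levels ``(v, t, c)`` with ``c = 2 (v + t) mod 3``
    over all ``(v, t)`` pairs, which is exactly the published condition
    table — and only the run *order* is shuffled by ``seed`` (standing in
    for the randomized run selection of the original statistics software).
    """
    factors = tuple(factor_specs)
    if len(factors) != 3 or any(len(f.levels) != 3 for f in factors):
        raise ValueError("the design needs exactly 3 factors with 3 levels each")
    runs = np.array([(v, t, (2 * (v + t)) % 3)
                     for v in range(3) for t in range(3)], dtype=int)
    rng = np.random.default_rng(seed)
    runs = runs[rng.permutation(9)]
    return DoEDesign(factors=factors, runs=runs, replicates=replicates, seed=seed)


@dataclass
class EffectsTable:
    """Main-effect estimates with the p = 0.05 Pareto reference line."""

    factor_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    standardized_effects: np.ndarray   # |t| per factor
    p_values: np.ndarray
    residual_df: int
    reference_line: float              # two-sided t critical value, alpha=0.05
    ranking: list[int] = field(default_factory=list)  # factor idx, descending |t|

    def __post_init__(self) -> None:
        if not self.ranking:
            self.ranking = list(np.argsort(-self.standardized_effects, kind="stable"))


def fit_main_effects(design: DoEDesign, responses: np.ndarray) -> EffectsTable:
    """OLS of the responses on the coded linear main effects.

    ``responses`` is shaped (runs, replicates) or flat with run-major order;
    replicates >= 2 are needed for a nonzero-df error estimate. With zero
    residual variance and all effects zero (constant responses) the
    standardized effects are 0 with p = 1.
    """
    y = np.asarray(responses, dtype=float).ravel()
    n_runs = design.runs.shape[0]
    if y.size % n_runs:
        raise ValueError(f"response count {y.size} is not a multiple of {n_runs} runs")
    reps = y.size // n_runs
    if reps < 2:
        raise ValueError("need >= 2 replicates per run for an error estimate")
    if not np.isfinite(y).all():
        raise ValueError("responses contain non-finite values")

    X = np.column_stack([np.ones(y.size),
                         np.repeat(design.coded(), reps, axis=0)])
    p = X.shape[1]
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = y.size - p
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(xtx_inv))

    coef = beta[1:]
    se_coef = se[1:]
    # with zero residual variance, coefficients at numerical zero are null
    # effects (constant responses), not infinitely significant ones
    zero_tol = 1e-10 * max(1.0, float(np.abs(y).max()))
    effectively_zero = np.abs(coef) <= zero_tol
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_coef > 0, np.abs(coef) / np.where(se_coef > 0, se_coef, 1.0),
                     np.where(effectively_zero, 0.0, np.inf))
    pvals = np.where(np.isinf(t), 0.0,
                     np.where(se_coef > 0, 2 * stats.t.sf(t, df), 1.0))
    ref = float(stats.t.ppf(0.975, df))
    return EffectsTable(factor_names=[f.name for f in design.factors],
                        coefficients=coef, standard_errors=se_coef,
                        standardized_effects=t, p_values=pvals,
                        residual_df=df, reference_line=ref)


def pareto_data(effects: EffectsTable) -> list[dict]:
    """Pareto chart data: factors by descending standardized effect.

    A factor is significant when its standardized effect extends beyond the
    p = 0.05 reference line.
    """
    out = []
    for i in effects.ranking:
        t = float(effects.standardized_effects[i])
        out.append({
            "factor": effects.factor_names[i],
            "standardized_effect": t,
            "coefficient": float(effects.coefficients[i]),
            "p_value": float(effects.p_values[i]),
            "significant": bool(t > effects.reference_line),
        })
    return out
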