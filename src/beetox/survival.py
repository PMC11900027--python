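"""Survival, food-intake, and dose accounting.

Cox proportional-hazards comparisons of each treatment against the control
(single binary covariate, Breslow tie handling, Newton-Raphson on the partial
likelihood), Kaplan-Meier mortality proportions, an ordinary least squares
model of per-bee food intake with a day-by-treatment interaction, and
solution-concentration / cumulative-dose arithmetic.

Acute arms are only exposed during the final two days of the experiment, so
their survival comparison re-zeroes time at the window start; individuals
dying before the window opened never experienced exposure and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .config import CONTROL


@dataclass(frozen=True)
class CoxResult:
    """Single-covariate Cox fit (treatment vs control)."""

    beta: float
    se: float
    hazard_ratio: float
    z: float
    p: float
    score_chi2: float
    score_p: float
    n: int
    n_events: int
    converged: bool
    ties_method: str = "breslow"


@dataclass(frozen=True)
class SolutionSpec:
    """A pesticide feeding solution: mass concentration and density."""

    pesticide_mass_conc: float  # µg per litre of solution
    solution_density: float = 1130.0  # g per litre (30% sucrose)

    def __post_init__(self):
        if self.pesticide_mass_conc < 0:
            raise ValueError("pesticide_mass_conc must be non-negative")
        if self.solution_density <= 0:
            raise ValueError("solution_density must be positive")


# ---------------------------------------------------------------------------
# Cox partial likelihood, single binary covariate, Breslow ties
# ---------------------------------------------------------------------------

def _breslow_score_info(time, event, x, beta: float) -> tuple[float, float]:
    """Score U(beta) and information I(beta) of the Breslow partial likelihood."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    t, e, xx = time[order], event[order], x[order]
    ebx = np.exp(beta * xx)
    s0 = np.cumsum(ebx)
    s1 = np.cumsum(xx * ebx)  # x binary: s2 == s1
    U = 0.0
    info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # risk set for this time = all subjects with time >= t[i] = indices [0, j)
        S0, S1 = s0[j - 1], s1[j - 1]
        for k in range(i, j):
            if e[k]:
                U += xx[k] - S1 / S0
                info += S1 / S0 - (S1 / S0) ** 2
        i = j
    return float(U), float(info)


def _fit_breslow(time, event, x, max_iter: int = 50, tol: float = 1e-10):
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        U, info = _breslow_score_info(time, event, x, beta)
        if info <= 0:
            break
        step = U / info
        beta += step
        if abs(beta) > 20:  # monotone likelihood
            break
        if abs(step) < tol:
            converged = True
            break
    return beta, converged


def cox_ph(records: pd.DataFrame, treatment: str, control: str = CONTROL) -> CoxResult:
    """Cox proportional-hazards comparison of one treatment vs the control.

    ``records`` needs columns treatment, time_days, event and (optionally)
    window_start.  The analysis window starts at the treatment arm's
    ``window_start`` (0 for chronic arms, day 12 for acute arms): both arms
    are restricted to individuals surviving past the window start and times
    are shifted so the window starts at zero.

    When the likelihood is monotone (all events in one arm before any in the
    other), the Wald statistics are reported as non-finite and the score test
    at beta = 0 -- which equals the log-rank test under Breslow ties --
    supplies the p-value.
    """
    df = records.loc[records["treatment"].isin([treatment, control])].copy()
    if df.loc[df["treatment"] == treatment].empty or df.loc[df["treatment"] == control].empty:
        raise ValueError("both groups must be non-empty")
    window = 0.0
    if "window_start" in df.columns:
        window = float(df.loc[df["treatment"] == treatment, "window_start"].max())
    if window > 0:
        df = df.loc[df["time_days"] > window]
        df["time_days"] = df["time_days"] - window
    time = df["time_days"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    x = (df["treatment"] == treatment).to_numpy(dtype=float)
    if event.sum() == 0:
        raise ValueError("no events in the analysis window")

    score_U, score_I = _breslow_score_info(time, event, x, 0.0)
    score_chi2 = score_U**2 / score_I if score_I > 0 else float("nan")
    score_p = float(stats.chi2.sf(score_chi2, df=1)) if np.isfinite(score_chi2) else float("nan")

    beta, converged = _fit_breslow(time, event, x)
    if converged:
        _, info = _breslow_score_info(time, event, x, beta)
        se = float(np.sqrt(1.0 / info))
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        import warnings

        warnings.warn(
            f"Cox fit for {treatment!r} did not converge (monotone likelihood?); "
            "reporting the score test p-value",
            stacklevel=2,
        )
        beta = float(np.sign(beta) * np.inf) if beta != 0 else float("nan")
        se = float("nan")
        z = float("nan")
        p = score_p
    return CoxResult(
        beta=float(beta),
        se=se,
        hazard_ratio=float(np.exp(beta)),
        z=float(z),
        p=p,
        score_chi2=float(score_chi2),
        score_p=score_p,
        n=len(df),
        n_events=int(event.sum()),
        converged=converged,
    )


def survival_proportion(records: pd.DataFrame, treatment: str, horizon: float) -> float:
    """Kaplan-Meier cumulative mortality of one treatment group at a horizon.

    With no censoring before the horizon this equals the simple death
    fraction.
    """
    df = records.loc[records["treatment"] == treatment]
    if df.empty:
        raise ValueError(f"no records for treatment {treatment!r}")
    km = KaplanMeierFitter()
    km.fit(df["time_days"], event_observed=df["event"])
    return float(1.0 - km.predict(horizon))


# ---------------------------------------------------------------------------
# food intake
# ---------------------------------------------------------------------------

def intake_ols(
    records: pd.DataFrame,
    treatments: list[str] | None = None,
    acute_window: bool = False,
) -> pd.DataFrame:
    """OLS of per-bee daily intake on colony + treatment + day + day:treatment.

    ``acute_window=True`` restricts to the day-12 (last pre-exposure) and
    day-14 (sampling) measurements, the comparison relevant for acute arms.
    Returns a coefficient table with columns term, coef, se, t, p.
    """
    import statsmodels.formula.api as smf

    df = records.copy()
    if treatments is not None:
        df = df.loc[df["treatment"].isin(set(treatments) | {CONTROL})]
    if acute_window:
        df = df.loc[df["day"].isin([12, 14])]
    if df["treatment"].nunique() < 2:
        raise ValueError("need the control plus at least one treatment")
    if df.groupby("treatment")["day"].nunique().min() < 2:
        raise ValueError("need at least two measurement days per treatment")
    model = smf.ols(
        "intake_ml_per_bee ~ C(colony) + C(treatment, Treatment('control')) "
        "+ day + day:C(treatment, Treatment('control'))",
        data=df,
    )
    fit = model.fit()
    table = pd.DataFrame(
        {
            "term": fit.params.index,
            "coef": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    ).reset_index(drop=True)
    # friendlier term names: day:treatment[x] etc.
    table["term"] = (
        table["term"]
        .str.replace("C(treatment, Treatment('control'))", "treatment", regex=False)
        .str.replace("C(colony)", "colony", regex=False)
    )
    return table


def interaction_coefficient(table: pd.DataFrame, treatment: str) -> float:
    """Pull the day-by-treatment interaction coefficient out of an OLS table."""
    mask = table["term"].str.contains("day:") & table["term"].str.contains(
        f"[T.{treatment}]", regex=False
    )
    if mask.sum() != 1:
        raise KeyError(f"no unique day:treatment interaction for {treatment!r}")
    return float(table.loc[mask, "coef"].iloc[0])


# ---------------------------------------------------------------------------
# dose accounting
# ---------------------------------------------------------------------------

def ppb_concentration(spec: SolutionSpec) -> float:
    """Concentration in parts per billion by mass (µg per kg of solution).

    ``µg/L`` divided by the solution density in kg/L, rounded half-up to one
    decimal (5 µg/L in a 1130 g/L sucrose solution -> 4.4 ppb).
    """
    value = spec.pesticide_mass_conc / (spec.solution_density / 1000.0)
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cumulative_dose(
    intakes: pd.DataFrame,
    spec: SolutionSpec,
    bees_per_colony: int = 6,
    interval_days: int = 2,
    per_bee: bool = True,
) -> tuple[pd.Series, float]:
    """Cumulative pesticide dose per bee (µg) per microcolony, plus the median.

    Intake records hold average daily intake in mL; each measurement covers
    ``interval_days`` days.  With ``per_bee=False`` the intake column is read
    as microcolony totals and divided by ``bees_per_colony``.
    """
    if (intakes["intake_ml_per_bee"] < 0).any():
        raise ValueError("negative intake")
    ml_per_bee = intakes.groupby("microcolony")["intake_ml_per_bee"].sum() * interval_days
    if not per_bee:
        ml_per_bee = ml_per_bee / bees_per_colony
    dose = ml_per_bee * spec.pesticide_mass_conc / 1000.0  # mL * µg/L / 1000 = µg
    dose.name = "dose_ug_per_bee"
    return dose, float(dose.median())
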