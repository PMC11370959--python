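"""Hypothesis-testing harness: candidate phenotypes vs condition in cohort data.

Given the traits harvested from the catalog (mapped onto cohort variable
names) this module produces the descriptive case/control summary table,
screens each variable for adequate numbers (the fewer-than-five rule),
z-scores continuous exposures on each model's complete-case sample, and runs
unadjusted and SEP/AAM-adjusted logistic regressions with the condition as
outcome. Every model is complete-case on exactly the variables it uses, so
denominators legitimately differ between models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "AssociationTest",
    "round_half_up",
    "summarize",
    "eligibility",
    "zscore",
    "logistic_test",
    "run_battery",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention of printed cohort tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _is_binary(values: pd.Series) -> bool:
    v = values.dropna().unique()
    return len(v) > 0 and set(np.asarray(v, dtype=float)) <= {0.0, 1.0}


@dataclass(frozen=True)
class AssociationTest:
    """One exposure-vs-condition logistic regression result."""

    exposure: str
    condition: str
    model: str  # unadjusted | adjusted
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    n: int
    omitted: bool = False
    reason: str = ""

    def as_row(self) -> dict:
        return asdict(self)


def summarize(
    pheno: pd.DataFrame,
    condition: str,
    variables: list[str] | None = None,
    types: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Case/control descriptive summary for one condition.

    For binary variables: positive count and percentage, where the
    percentage denominator is the *total* group size including missing
    (matching how such cohort tables are printed). For continuous variables:
    mean and SD over non-missing values. Missing counts per group are always
    reported. Percent/mean/SD are rounded to one decimal, half-up.
    """
    if condition not in pheno.columns:
        raise KeyError(f"unknown condition column {condition!r}")
    status = pheno[condition]
    groups = {"cases": pheno[status == 1], "controls": pheno[status == 0]}
    if variables is None:
        variables = [c for c in pheno.columns if c not in (condition, "dysmenorrhea", "hmb")]

    rows = []
    for var in variables:
        declared = (types or {}).get(var)
        binary = declared == "binary" if declared else _is_binary(pheno[var])
        row: dict = {"variable": var, "type": "binary" if binary else "continuous"}
        for gname, g in groups.items():
            col = g[var]
            n_group = len(g)
            n_missing = int(col.isna().sum())
            if binary:
                pos = int((col == 1).sum())
                pct = round_half_up(100.0 * pos / n_group, 1) if n_group else 0.0
                row[f"{gname}_positive"] = pos
                row[f"{gname}_percent"] = pct
                row[f"{gname}_display"] = f"{pos} ({pct:.1f}%)"
            else:
                vals = col.dropna()
                mean = round_half_up(float(vals.mean()), 1) if len(vals) else np.nan
                sd = round_half_up(float(vals.std(ddof=1)), 1) if len(vals) > 1 else np.nan
                row[f"{gname}_mean"] = mean
                row[f"{gname}_sd"] = sd
                row[f"{gname}_display"] = f"{mean:.1f} ({sd:.1f})"
            row[f"{gname}_n"] = n_group
            row[f"{gname}_missing"] = n_missing
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def eligibility(
    pheno: pd.DataFrame,
    variable: str,
    condition: str,
    minimum: int = 5,
    var_type: str | None = None,
) -> tuple[bool, str]:
    """Screen a variable for adequate numbers ("fewer than five" rule).

    Binary exposure: every cell of the non-missing exposure x condition 2x2
    must reach the minimum. Continuous exposure: the non-missing count must
    reach the minimum within cases and within controls. The rule is strict —
    a cell of exactly ``minimum`` is eligible.
    """
    df = pheno[[variable, condition]].dropna()
    binary = var_type == "binary" if var_type else _is_binary(pheno[variable])
    if binary:
        for cond_val, cond_name in ((1, "cases"), (0, "controls")):
            for exp_val in (0, 1):
                cell = int(((df[condition] == cond_val) & (df[variable] == exp_val)).sum())
                if cell < minimum:
                    return False, (
                        f"{cond_name} with {variable}={exp_val}: {cell} < {minimum}"
                    )
        return True, ""
    for cond_val, cond_name in ((1, "cases"), (0, "controls")):
        count = int((df[condition] == cond_val).sum())
        if count < minimum:
            return False, f"non-missing {variable} in {cond_name}: {count} < {minimum}"
    return True, ""


def zscore(values: pd.Series | np.ndarray) -> pd.Series:
    """Standardize to mean 0, sample SD 1 over non-missing entries.

    Missing entries are preserved in place. Raises on fewer than two
    non-missing values or zero SD (the caller skips the variable and logs).
    """
    s = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    vals = s.dropna()
    if len(vals) < 2:
        raise ValueError("need >= 2 non-missing values to z-score")
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero standard deviation: cannot z-score")
    return (s - float(vals.mean())) / sd


def logistic_test(
    pheno: pd.DataFrame,
    exposure: str,
    condition: str,
    adjusters: list[str] | None = None,
    zscore_continuous: bool = True,
) -> AssociationTest:
    """Logistic regression of the condition on one exposure.

    Complete-case on {exposure, condition, adjusters}; continuous exposures
    are converted to z-scores on that complete-case sample so effect sizes
    are per SD. Maximum likelihood via iteratively reweighted least squares;
    OR = exp(coefficient) with a 95% Wald interval on the log scale. Perfect
    separation or non-convergence yields an omitted result with the reason
    flagged rather than an unstable estimate.
    """
    adjusters = list(adjusters or [])
    model_label = "adjusted" if adjusters else "unadjusted"
    cols = [exposure, condition] + adjusters
    df = pheno[cols].dropna().astype(float)
    n = len(df)
    y = df[condition]
    if y.nunique() < 2:
        return AssociationTest(exposure, condition, model_label, None, None, None, None,
                               n, omitted=True, reason="outcome has a single class")

    x = df[[exposure] + adjusters].copy()
    if zscore_continuous and not _is_binary(df[exposure]):
        x[exposure] = zscore(x[exposure])
    for adj in adjusters:
        if zscore_continuous and not _is_binary(df[adj]):
            x[adj] = zscore(x[adj])
    x = sm.add_constant(x, prepend=True)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=100)
    except (PerfectSeparationError, PerfectSeparationWarning):
        return AssociationTest(exposure, condition, model_label, None, None, None, None,
                               n, omitted=True, reason="perfect separation")
    if not getattr(res, "converged", True):
        return AssociationTest(exposure, condition, model_label, None, None, None, None,
                               n, omitted=True, reason="did not converge")
    coef = float(res.params[exposure])
    se = float(res.bse[exposure])
    if not np.isfinite(se) or se > 1e3:
        return AssociationTest(exposure, condition, model_label, None, None, None, None,
                               n, omitted=True, reason="unstable fit (quasi-separation)")
    zval = coef / se
    from scipy import stats as sps

    p = float(2.0 * sps.norm.sf(abs(zval)))
    return AssociationTest(
        exposure,
        condition,
        model_label,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p=p,
        n=n,
    )


def run_battery(
    pheno: pd.DataFrame,
    hypotheses,
    variable_map: dict[str, str],
    conditions: list[str],
    adjusters: list[str] | None = None,
    a_priori: list[str] | None = None,
    minimum: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full unadjusted + adjusted battery.

    Parameters
    ----------
    hypotheses : HypothesisSet (or anything with ``.entries['trait_key']``).
    variable_map : normalized trait name -> cohort variable column.
    conditions : condition status columns to test against.
    adjusters : adjustment set for the adjusted model (SEP and AAM).
    a_priori : variable names appended regardless of the harvested traits.

    Returns
    -------
    results : DataFrame of association tests, sorted by condition then
        variable then model.
    unmapped : DataFrame of traits with no cohort variable (reported, not
        fatal) — the omission log the narrative of exclusions comes from.
    """
    adjusters = list(adjusters or [])
    from .catalog import normalize_trait

    trait_keys = list(getattr(hypotheses, "entries", pd.DataFrame()).get("trait_key", []))
    norm_map = {normalize_trait(k): v for k, v in variable_map.items()}

    mapped_vars: list[str] = []
    unmapped_rows = []
    for key in trait_keys:
        var = norm_map.get(key)
        if var is None:
            unmapped_rows.append({"trait": key, "reason": "no cohort variable mapped"})
        elif var not in pheno.columns:
            unmapped_rows.append({"trait": key, "reason": f"mapped variable {var!r} absent"})
        elif var not in mapped_vars:
            mapped_vars.append(var)
    for var in a_priori or []:
        if var in pheno.columns and var not in mapped_vars:
            mapped_vars.append(var)

    rows = []
    for condition in conditions:
        for var in sorted(mapped_vars):
            ok, reason = eligibility(pheno, var, condition, minimum=minimum)
            if not ok:
                for model in ("unadjusted", "adjusted"):
                    rows.append(AssociationTest(var, condition, model, None, None, None,
                                                None, 0, omitted=True, reason=reason).as_row())
                continue
            rows.append(logistic_test(pheno, var, condition, adjusters=None).as_row())
            rows.append(logistic_test(pheno, var, condition, adjusters=adjusters).as_row())

    results = pd.DataFrame(
        rows,
        columns=["exposure", "condition", "model", "odds_ratio", "ci_low",
                 "ci_high", "p", "n", "omitted", "reason"],
    )
    results = results.sort_values(["condition", "exposure", "model"]).reset_index(drop=True)
    unmapped = pd.DataFrame(unmapped_rows, columns=["trait", "reason"])
    return results, unmapped
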