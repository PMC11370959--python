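"""Case/control derivation from repeated puberty-questionnaire responses.

A participant is asked at several waves whether they have ever experienced a
symptom and, if so, whether a doctor was visited for it. "Ever having
visited the doctor" defines a case; reporting the symptom without ever
seeing a doctor defines the less-severe stratum; never reporting the symptom
(or, for menstrual cramps, only "mild" severity at the age-15 wave) defines
a control. Sensitivity variants — comorbidity exclusion, dropping samples
whose first report postdates their methylation measurement — are re-runs
with different :class:`CaseRules`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CaseRules", "derive_status", "read_responses", "write_status"]

_STATUS_ORDER = ["case", "less_severe", "control", "excluded"]


@dataclass(frozen=True)
class CaseRules:
    """Switches controlling case derivation.

    Defaults reproduce the primary analysis: a case requires a doctor visit,
    and a sole "mild" report at the age-15 wave still counts as a control.
    ``measurement_wave`` maps sample id -> wave at which methylation was
    measured; with ``exclude_post_measurement`` on, samples whose first
    symptom report comes after that wave are excluded.
    """

    require_doctor: bool = True
    mild_age15_as_control: bool = True
    mild_wave: float = 15.0
    comorbidity_exclusions: frozenset[str] = frozenset()
    exclude_post_measurement: bool = False
    measurement_wave: dict[str, float] = field(default_factory=dict)


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read long-format responses CSV: sample, wave, symptom, doctor, severity."""
    df = pd.read_csv(path, dtype={"sample": str, "severity": str})
    required = {"sample", "wave", "symptom", "doctor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"responses file missing columns: {sorted(missing)}")
    if "severity" not in df.columns:
        df["severity"] = pd.NA
    return df


def _norm_yn(series: pd.Series) -> pd.Series:
    # yes/no/missing in any of several spellings -> {"yes","no",NA}
    s = series.astype("string").str.strip().str.lower()
    s = s.replace({"y": "yes", "n": "no", "1": "yes", "0": "no", "": pd.NA})
    bad = s.dropna()[~s.dropna().isin(["yes", "no"])]
    if len(bad):
        raise ValueError(f"unrecognised yes/no values: {sorted(bad.unique())}")
    return s


def derive_status(responses: pd.DataFrame, rules: CaseRules | None = None) -> pd.DataFrame:
    """Assign each sample exactly one status.

    Parameters
    ----------
    responses : long-format DataFrame with columns
        sample, wave, symptom (yes/no/missing), doctor (yes/no/missing),
        severity (optional, e.g. "mild").
    rules : CaseRules, defaults to the primary-analysis settings.

    Returns
    -------
    DataFrame indexed by sample with columns ``status`` (case | less_severe
    | control | excluded), ``first_report_wave`` (earliest symptom=yes wave,
    NaN otherwise) and ``reason`` for exclusions.

    Notes
    -----
    "Ever" semantics: any qualifying wave suffices, regardless of later
    denials. A missing doctor answer after symptom=yes counts as no doctor
    visit for that wave.
    """
    if rules is None:
        rules = CaseRules()
    df = responses.copy()
    df["symptom"] = _norm_yn(df["symptom"])
    df["doctor"] = _norm_yn(df["doctor"])
    if "severity" not in df.columns:
        df["severity"] = pd.NA
    df["severity"] = df["severity"].astype("string").str.strip().str.lower()

    # integrity: a doctor visit can only be reported alongside the symptom
    bad = df[(df["doctor"] == "yes") & (df["symptom"] != "yes")]
    if len(bad):
        samples = sorted(bad["sample"].astype(str).unique())
        raise ValueError(f"doctor=yes without symptom=yes for samples: {samples[:10]}")

    out_rows = []
    for sample, g in df.groupby("sample", sort=True):
        non_missing = g["symptom"].notna()
        row = {"sample": sample, "first_report_wave": np.nan, "reason": ""}
        if not non_missing.any():
            row.update(status="excluded", reason="all responses missing")
            out_rows.append(row)
            continue

        symptom_yes = g["symptom"] == "yes"
        # the mild-at-15 concession: a "mild" report at the age-15 wave does
        # not count as a symptom report when the flag is on
        if rules.mild_age15_as_control:
            mild15 = (
                symptom_yes
                & (g["wave"].astype(float) == rules.mild_wave)
                & (g["severity"] == "mild")
                & (g["doctor"] != "yes")
            )
            symptom_yes = symptom_yes & ~mild15

        doctor_yes = symptom_yes & (g["doctor"] == "yes")
        if symptom_yes.any():
            row["first_report_wave"] = float(g.loc[symptom_yes, "wave"].astype(float).min())

        if str(sample) in rules.comorbidity_exclusions:
            row.update(status="excluded", reason="comorbidity exclusion")
            out_rows.append(row)
            continue
        if (
            rules.exclude_post_measurement
            and symptom_yes.any()
            and str(sample) in rules.measurement_wave
            and row["first_report_wave"] > rules.measurement_wave[str(sample)]
        ):
            row.update(status="excluded", reason="first report after methylation measurement")
            out_rows.append(row)
            continue

        if doctor_yes.any() or (symptom_yes.any() and not rules.require_doctor):
            row["status"] = "case"
        elif symptom_yes.any():
            row["status"] = "less_severe"
        else:
            row["status"] = "control"
        out_rows.append(row)

    out = pd.DataFrame(out_rows).set_index("sample")
    out["status"] = pd.Categorical(out["status"], categories=_STATUS_ORDER)
    return out[["status", "first_report_wave", "reason"]]


def write_status(status: pd.DataFrame, path: str | Path) -> None:
    status.to_csv(path)
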