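"""Fixtures encoding published summary tables for the two worked conditions.

The underlying individual-level cohort (ALSPAC/ARIES) is managed-access, so
these fixtures reconstruct only what the publication prints:

* ``table1_fixture`` — a synthetic sample-level phenotype table whose group
  sizes and per-variable positive/missing counts (binary) and mean/SD/missing
  (continuous) reproduce every printed cell of the cohort characteristics
  table for dysmenorrhea and heavy menstrual bleeding (HMB).
* ``dysmenorrhea_catalog_fixture`` / ``hmb_catalog_fixture`` — offline
  EWAS-catalog stores encoding the published hit CpGs, their resident genes
  and the trait lists reported for each.

Everything here is synthetic scaffolding around printed margins: individual
rows are NOT real participants, and the overlap between the two conditions'
classified samples is deliberately empty (each synthetic sample carries a
status for exactly one condition), because only per-condition group margins
were published.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "table1_fixture",
    "table1_variable_metadata",
    "CatalogFixture",
    "dysmenorrhea_catalog_fixture",
    "hmb_catalog_fixture",
]

# Group sizes: (cases, controls) per condition.
_GROUP_N = {"dysmenorrhea": (641, 1254), "hmb": (527, 2083)}

# Binary variables: (positive, missing) per
# (dys cases, dys controls, hmb cases, hmb controls).
# The one cell printed only as "<5" (oral contraception, cases, missing) is
# encoded as 2.
_BINARY = {
    "maternal_university_degree": ((70, 72), (208, 137), (46, 65), (361, 188)),
    "prenatal_alcohol": ((394, 151), (785, 258), (317, 129), (1336, 397)),
    "prenatal_smoking": ((142, 95), (222, 184), (132, 86), (364, 282)),
    "prenatal_hdp": ((113, 44), (201, 67), (97, 41), (310, 104)),
    "prenatal_preeclampsia": ((9, 44), (26, 67), (11, 41), (42, 104)),
    "alcohol_by_13": ((165, 311), (242, 649), (137, 240), (430, 1013)),
    "smoked_by_13": ((99, 160), (92, 383), (91, 130), (160, 544)),
    "oral_contraception": ((445, 2), (271, 7), (390, 2), (511, 11)),
    "comorbidity": ((39, 363), (30, 837), (36, 301), (58, 1292)),
}

# Continuous variables: (mean, sd, missing) per group, same group order.
_CONTINUOUS = {
    "maternal_bmi": ((23.1, 3.9, 94), (22.9, 3.9, 201), (23.1, 4.0, 80), (22.8, 3.7, 301)),
    "gestational_age_weeks": ((39.6, 1.7, 39), (39.4, 1.8, 64), (39.5, 1.8, 35), (39.6, 1.8, 100)),
    "bmi_age7": ((16.8, 2.6, 137), (16.3, 2.1, 318), (16.8, 2.5, 114), (16.3, 2.1, 450)),
    "cholesterol_age7": ((4.5, 0.7, 309), (4.5, 0.7, 636), (4.5, 0.7, 253), (4.5, 0.7, 1008)),
    "cotinine_age7": ((1.5, 1.4, 302), (1.2, 1.2, 617), (1.5, 1.5, 254), (1.2, 1.1, 978)),
    "nonword_repetition_age8": ((7.2, 2.5, 62), (7.3, 2.6, 368), (7.1, 2.4, 145), (7.4, 2.5, 527)),
    "crp_age9": ((1.2, 3.7, 322), (0.7, 1.4, 625), (1.2, 3.2, 279), (0.8, 2.7, 981)),
    "aam_months": ((146.0, 12.8, 123), (151.5, 12.6, 331), (146.4, 13.3, 91), (150.4, 12.3, 478)),
    "ace_score_16": ((2.0, 1.5, 419), (1.6, 1.7, 892), (2.1, 1.9, 362), (1.5, 1.5, 1433)),
}

_EPOCH = {
    "maternal_university_degree": "prenatal",
    "prenatal_alcohol": "prenatal",
    "prenatal_smoking": "prenatal",
    "prenatal_hdp": "prenatal",
    "prenatal_preeclampsia": "prenatal",
    "maternal_bmi": "prenatal",
    "gestational_age_weeks": "prenatal",
    "alcohol_by_13": "childhood",
    "smoked_by_13": "childhood",
    "bmi_age7": "childhood",
    "cholesterol_age7": "childhood",
    "cotinine_age7": "childhood",
    "nonword_repetition_age8": "childhood",
    "crp_age9": "childhood",
    "oral_contraception": "puberty",
    "comorbidity": "puberty",
    "aam_months": "puberty",
    "ace_score_16": "puberty",
}


def _binary_column(n: int, positive: int, missing: int) -> np.ndarray:
    col = np.zeros(n)
    col[:positive] = 1.0
    if missing:
        col[n - missing:] = np.nan
    return col


def _continuous_column(n: int, mean: float, sd: float, missing: int) -> np.ndarray:
    # deterministic values with the exact sample mean and SD (ddof=1)
    k = n - missing
    base = np.linspace(-1.0, 1.0, k)
    z = (base - base.mean()) / base.std(ddof=1)
    col = np.full(n, np.nan)
    col[:k] = mean + sd * z
    return col


def table1_fixture() -> pd.DataFrame:
    """Synthetic sample-level table reproducing the printed cohort summary.

    Returns a DataFrame indexed by synthetic sample id with ``dysmenorrhea``
    and ``hmb`` status columns (1 = case, 0 = control, NaN = not classified
    for that condition) plus every summarised candidate variable. Group
    sizes, binary positive/missing counts and continuous mean/SD/missing all
    match the printed cells exactly.
    """
    blocks = []
    group_index = 0
    for condition in ("dysmenorrhea", "hmb"):
        for status in (1, 0):
            n = _GROUP_N[condition][0] if status == 1 else _GROUP_N[condition][1]
            data = {"dysmenorrhea": np.nan, "hmb": np.nan}
            block = pd.DataFrame(data, index=range(n))
            block[condition] = float(status)
            for var, cells in _BINARY.items():
                pos, miss = cells[group_index]
                block[var] = _binary_column(n, pos, miss)
            for var, cells in _CONTINUOUS.items():
                mean, sd, miss = cells[group_index]
                block[var] = _continuous_column(n, mean, sd, miss)
            blocks.append(block)
            group_index += 1
    out = pd.concat(blocks, ignore_index=True)
    out.index = pd.Index([f"T{i:05d}" for i in range(len(out))], name="sample_id")
    return out


def table1_variable_metadata() -> pd.DataFrame:
    """Declared type and measurement epoch for every fixture variable."""
    rows = [
        {"variable": v, "type": "binary", "epoch": _EPOCH[v]} for v in _BINARY
    ] + [
        {"variable": v, "type": "continuous", "epoch": _EPOCH[v]} for v in _CONTINUOUS
    ]
    return pd.DataFrame(rows).set_index("variable")


@dataclass(frozen=True)
class CatalogFixture:
    """One condition's published scan hits plus a matching offline store.

    ``hits`` are the published hit CpG ids, ``annotation`` the manifest rows
    for those probes (position and resident gene as printed, effect estimate
    columns carried along), and ``store`` the catalog records: CpG-level
    trait reports carry the CpG id (gene blank), gene-level aggregated
    reports carry the gene symbol (CpG blank).
    """

    condition: str
    hits: tuple[str, ...]
    annotation: pd.DataFrame
    store: pd.DataFrame


def _make_fixture(condition, rows, cpg_traits, gene_traits) -> CatalogFixture:
    annotation = pd.DataFrame(
        rows,
        columns=["probe_id", "chr", "pos", "gene", "beta", "ci_low", "ci_high", "p"],
    ).set_index("probe_id")
    annotation["probe_class"] = "cpg"
    annotation["detection_fail"] = 0
    annotation["chen_flag"] = 0
    records = []
    for cpg, traits in cpg_traits.items():
        for t in traits:
            records.append({"cpg": cpg, "gene": "", "trait": t, "study_id": "pub-cpg", "p": 1e-8})
    for gene, traits in gene_traits.items():
        for t in traits:
            records.append({"cpg": "", "gene": gene, "trait": t, "study_id": "pub-gene", "p": 1e-8})
    store = pd.DataFrame(records, columns=["cpg", "gene", "trait", "study_id", "p"])
    return CatalogFixture(
        condition=condition,
        hits=tuple(r[0] for r in rows),
        annotation=annotation,
        store=store,
    )


def dysmenorrhea_catalog_fixture() -> CatalogFixture:
    """Published dysmenorrhea hit CpGs and their catalog trait lists.

    Trait strings follow the printed lists, split on commas, with one
    reading decision: the resident-gene list for BANP separates "total
    cholesterol" (independently a standalone catalog trait) from
    "chylomicrons and extremely large VLDLs", while the NFIC run-on
    "pre-eclampsia HDPs" is kept as the single printed token.
    """
    rows = [
        ("cg08142094", "16", 85731256, "", -0.036, -0.050, -0.022, 1.02e-6),
        ("cg23012731", "1", 33438978, "", -0.008, -0.011, -0.005, 3.53e-6),
        ("cg21802726", "20", 33735257, "EDEM2", -0.002, -0.003, -0.004, 3.74e-4),
        ("cg04583842", "16", 88103117, "BANP", -0.034, -0.053, -0.016, 4.17e-4),
        ("cg22603569", "19", 3388047, "NFIC", -0.017, -0.029, -0.005, 6.14e-3),
        ("cg04737758", "14", 74824136, "", 0.042, 0.025, 0.058, 1.13e-6),
        ("cg15017604", "11", 1361518, "", 0.026, 0.015, 0.037, 9.39e-6),
    ]
    cpg_traits = {
        "cg21802726": ["Rheumatoid arthritis"],
        "cg04583842": ["Smoking", "gestational age", "BMI", "CRP", "mortality"],
        "cg22603569": [
            "Fetal vs adult liver",
            "gestational age",
            "alcohol consumption",
            "hypertensive disorders of pregnancy (HDPs)",
        ],
    }
    gene_traits = {
        "EDEM2": [
            "Rheumatoid arthritis",
            "ischaemic stroke",
            "primary Sjögren's syndrome",
            "HIV infection",
        ],
        "BANP": [
            "Clear cell renal carcinoma",
            "fetal vs adult liver",
            "HIV infection",
            "smoking",
            "age",
            "gestational age",
            "rheumatoid arthritis",
            "BMI",
            "primary Sjögren's syndrome",
            "chronic kidney disease",
            "CRP",
            "sex",
            "mortality",
            "child abuse",
            "melanoma",
            "alcohol consumption",
            "Crohn's disease",
            "pre-eclampsia",
            "air pollution exposure",
            "maternal urinary arsenic",
            "cognitive ability",
            "total cholesterol",
            "chylomicrons and extremely large VLDLs",
            "FASD",
        ],
        "NFIC": [
            "Fetal vs adult liver",
            "gestational age",
            "smoking",
            "pancreatic ductal adenocarcinoma",
            "aging",
            "rheumatoid arthritis",
            "cleft lip vs palate",
            "age",
            "HIV infection",
            "alcohol consumption",
            "primary Sjögren's syndrome",
            "sex",
            "time spent sitting",
            "pre-eclampsia HDPs",
            "Crohn's disease",
        ],
    }
    return _make_fixture("dysmenorrhea", rows, cpg_traits, gene_traits)


def hmb_catalog_fixture() -> CatalogFixture:
    """Published heavy-menstrual-bleeding hit CpGs and their trait lists."""
    rows = [
        ("cg24196053", "4", 1736433, "TACC3", -0.010, -0.014, -0.006, 1.50e-5),
        ("cg11465939", "22", 23923462, "IGLL1", -0.029, -0.042, -0.015, 6.04e-5),
    ]
    cpg_traits = {
        "cg11465939": ["Fetal vs adult liver", "smoking", "gestational age"],
    }
    gene_traits = {
        "TACC3": [
            "Clear cell renal carcinoma",
            "gestational age",
            "HIV infection",
            "Crohn's disease",
            "Alzheimer's disease",
            "pre-eclampsia",
            "total cholesterol",
        ],
        "IGLL1": [
            "Clear cell renal carcinoma",
            "fetal vs adult liver",
            "gestational age",
            "HIV infection",
            "primary Sjögren's syndrome",
            "smoking",
        ],
    }
    return _make_fixture("hmb", rows, cpg_traits, gene_traits)
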