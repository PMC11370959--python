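"""Probe-level filtering and per-probe outlier removal.

Mirrors standard 450K-array practice: drop sex-chromosome probes, SNP and
control probes, and probes failing detection; then, per retained probe, set
beta-values outside Tukey fences (quartiles +/- 3 x IQR) to missing. Probes
on the published cross-reactive/polymorphic list are never removed — hits
are flagged against the list afterwards so spurious signals can be
recognised without shrinking the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QcReport",
    "filter_probes",
    "tukey_fences",
    "remove_outliers",
    "flag_chen",
    "read_annotation",
]

_SEX_CHROMS = {"X", "Y", "chrX", "chrY", "x", "y", "23", "24"}


@dataclass
class QcReport:
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    outlier_cells: dict[str, int] = field(default_factory=dict)
    flagged_probes: list[str] = field(default_factory=list)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the manifest TSV: probe_id, chr, pos, gene, class, flags."""
    ann = pd.read_csv(path, sep="\t", dtype={"chr": str, "gene": str})
    ann = ann.set_index("probe_id")
    if "class" in ann.columns and "probe_class" not in ann.columns:
        ann = ann.rename(columns={"class": "probe_class"})
    return ann


def filter_probes(
    matrix: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, QcReport]:
    """Remove sex-chromosome, SNP/control and detection-failed probes.

    Filters apply in a fixed order (sex -> snp/control -> detection) so that
    a probe matching several categories is counted exactly once, under the
    first category it matches.
    """
    unannotated = matrix.index.difference(annotation.index)
    if len(unannotated):
        raise KeyError(
            f"{len(unannotated)} probes missing from annotation, e.g. "
            f"{list(unannotated[:5])}"
        )
    ann = annotation.loc[matrix.index]
    chrom = ann["chr"].astype(str)
    is_sex = chrom.isin(_SEX_CHROMS)
    is_snp_control = ann["probe_class"].isin(["snp", "control"]) & ~is_sex
    is_detection = (ann["detection_fail"].astype(int) == 1) & ~is_sex & ~is_snp_control

    report = QcReport(
        removed={
            "sex": int(is_sex.sum()),
            "snp_control": int(is_snp_control.sum()),
            "detection": int(is_detection.sum()),
        }
    )
    keep = ~(is_sex | is_snp_control | is_detection)
    filtered = matrix.loc[keep.values]
    report.retained = filtered.shape[0]
    return filtered, report


def tukey_fences(values: np.ndarray | pd.Series, k: float = 3.0) -> tuple[float, float]:
    """Outlier fences Q1 - k*IQR and Q3 + k*IQR.

    Quartiles use linear interpolation (the type-7 convention). Requires at
    least four non-missing values; fewer raise so the caller can flag the
    probe instead of silently skipping outlier removal.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 4:
        raise ValueError(f"need >= 4 non-missing values for fences, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation by default
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def remove_outliers(
    matrix: pd.DataFrame, k: float = 3.0
) -> tuple[pd.DataFrame, QcReport]:
    """Per probe, set values strictly outside the Tukey fences to missing.

    The boundary is inclusive: a value exactly on a fence is retained.
    Probes with fewer than four non-missing values are left untouched and
    listed in the report.
    """
    values = matrix.to_numpy(dtype=float, copy=True)
    report = QcReport(retained=matrix.shape[0])
    n_ok = (~np.isnan(values)).sum(axis=1)
    for i, probe in enumerate(matrix.index):
        if n_ok[i] < 4:
            report.flagged_probes.append(str(probe))
            continue
        row = values[i]
        q1, q3 = np.nanpercentile(row, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        out = (row < lo) | (row > hi)
        n_out = int(np.nansum(out))
        if n_out:
            row[out] = np.nan
            report.outlier_cells[str(probe)] = n_out
    cleaned = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    return cleaned, report


def flag_chen(results: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Annotate scan results with the cross-reactive/polymorphic-probe flag.

    No probe is removed; the flag travels with the result row so hits on the
    list can be read with caution.
    """
    out = results.copy()
    flags = annotation["chen_flag"].astype(int).reindex(out.index).fillna(0).astype(bool)
    out["chen_flag"] = flags
    return out
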