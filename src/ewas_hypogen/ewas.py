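"""Mass-univariate linear-regression EWAS.

Case/control status is the *exposure* and methylation the *outcome*: the
scan asks which CpGs differ between groups, not which CpGs cause the
condition, so a hit may equally reflect causation in either direction or a
shared upstream exposure — which is exactly what the downstream catalog
look-up exploits.

Per probe: ordinary least squares of beta-value on (intercept, case status,
age at measurement, surrogate variables), complete-case, with two-sided
t-distribution p-values and Wald confidence intervals. Scan-level
diagnostics: genomic inflation lambda and QQ data.

The module follows the Model/Results convention: build an
:class:`EWASScan` from data, call :meth:`EWASScan.fit`, and read estimates
off the returned :class:`EWASResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sva import SurrogateVariableSet

__all__ = [
    "ProbeFit",
    "EWASScan",
    "EWASResults",
    "build_design",
    "fit_probe",
    "run_ewas",
    "genomic_lambda",
    "select_hits",
    "qq_data",
]

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class ProbeFit:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    degenerate: bool = False


def build_design(
    pheno: pd.DataFrame,
    case: pd.Series,
    age_col: str = "age",
    svs: SurrogateVariableSet | None = None,
) -> pd.DataFrame:
    """Assemble the scan design: intercept + case + age (+ surrogate vars)."""
    design = pd.DataFrame(
        {"intercept": 1.0, "case": case.astype(float), "age": pheno[age_col].astype(float)},
        index=pheno.index,
    )
    if svs is not None and svs.n_sv > 0:
        design = design.join(svs.data)
    return design


def fit_probe(
    y: np.ndarray | pd.Series,
    design: np.ndarray | pd.DataFrame,
    exposure_index: int = 1,
) -> ProbeFit:
    """OLS fit of one probe's beta-values on the design.

    Complete-case: samples with a missing outcome are dropped. The reported
    coefficient is the exposure (case-status) column. A probe whose
    residual variance is (numerically) zero is flagged degenerate with a
    missing p-value.

    Raises
    ------
    ValueError if the complete-case design is rank deficient or has no
    residual degrees of freedom.
    """
    yv = np.asarray(y, dtype=float)
    x = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    ok = ~np.isnan(yv)
    yv, x = yv[ok], x[ok]
    n, k = x.shape
    if n <= k:
        raise ValueError(f"complete-case n={n} <= design columns k={k}")
    q, r = np.linalg.qr(x)
    if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(np.diag(r)))):
        raise ValueError("design rank deficient on the complete-case subset")
    coef = np.linalg.solve(r, q.T @ yv)
    resid = yv - x @ coef
    rss = float(resid @ resid)
    dof = n - k
    sigma2 = rss / dof
    r_inv = np.linalg.solve(r, np.eye(k))
    xtx_inv_diag = (r_inv ** 2).sum(axis=1)
    beta = float(coef[exposure_index])
    scale = float(np.mean(yv ** 2)) if n else 1.0
    if sigma2 <= _DEGENERATE_TOL * max(1.0, scale):
        return ProbeFit(beta, 0.0, beta, beta, np.nan, n, degenerate=True)
    se = float(np.sqrt(sigma2 * xtx_inv_diag[exposure_index]))
    tval = beta / se
    p = float(2.0 * stats.t.sf(abs(tval), dof))
    tcrit = float(stats.t.ppf(0.975, dof))
    return ProbeFit(beta, se, beta - tcrit * se, beta + tcrit * se, p, n, degenerate=False)


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median chi-square(1 df) quantile of the
    observed p-values over the null median (~0.455)."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValueError(f"need >= 100 p-values for lambda, got {p.size}")
    return float(np.median(stats.chi2.isf(p, 1)) / _CHI2_MEDIAN_1DF)


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    Observed p sorted ascending; expected quantiles are rank/(m+1).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 1:
        raise ValueError("need at least one p-value")
    obs = np.sort(p)
    exp = np.arange(1, p.size + 1) / (p.size + 1)
    return pd.DataFrame(
        {"expected": -np.log10(exp), "observed": -np.log10(obs)}
    )


def select_hits(results: pd.DataFrame, threshold: float = 1e-5) -> list[str]:
    """Probe ids with p strictly below the suggestive threshold, best first.

    The boundary is exclusive — a probe at exactly the threshold is not a
    hit. Ties in p break by probe id for determinism.
    """
    df = results[results["p"] < threshold]
    df = df.sort_values(["p"], kind="mergesort")
    order = sorted(df.index, key=lambda pid: (df.loc[pid, "p"], str(pid)))
    return [str(i) for i in order]


class EWASScan:
    """Mass-univariate scan model: methylation matrix + design.

    Parameters
    ----------
    beta : DataFrame, probes x samples, values in [0, 1], missing allowed.
    design : DataFrame, samples x k, containing the exposure column.
    exposure : name of the design column whose coefficient is reported.
    """

    def __init__(self, beta: pd.DataFrame, design: pd.DataFrame, exposure: str = "case"):
        if list(beta.columns) != list(design.index):
            design = design.loc[beta.columns]
        if exposure not in design.columns:
            raise ValueError(f"exposure column {exposure!r} not in design")
        self.beta = beta
        self.design = design
        self.exposure = exposure

    @classmethod
    def from_phenotypes(
        cls,
        beta: pd.DataFrame,
        pheno: pd.DataFrame,
        status: pd.DataFrame,
        svs: SurrogateVariableSet | None = None,
        age_col: str = "age",
    ) -> "EWASScan":
        """Build the scan from a phenotype table and derived case status.

        Only case and control samples enter; less-severe and excluded
        samples are dropped.
        """
        keep = status[status["status"].isin(["case", "control"])].index
        keep = [s for s in beta.columns if s in set(keep)]
        if len(keep) < 10:
            raise ValueError(f"only {len(keep)} usable case/control samples (< 10)")
        case = (status.loc[keep, "status"] == "case").astype(float)
        sub_svs = svs
        if svs is not None and svs.n_sv > 0:
            sub_svs = SurrogateVariableSet(
                n_sv=svs.n_sv, data=svs.data.loc[keep], method=svs.method, seed=svs.seed
            )
        design = build_design(pheno.loc[keep], case, age_col=age_col, svs=sub_svs)
        return cls(beta[keep], design)

    def fit(self, threshold: float = 1e-5) -> "EWASResults":
        y = self.beta.to_numpy(dtype=float)
        x = self.design.to_numpy(dtype=float)
        exposure_index = list(self.design.columns).index(self.exposure)
        n_probes = y.shape[0]
        cols = np.empty((n_probes, 7))
        skipped: list[str] = []

        has_missing = np.isnan(y).any(axis=1)
        if (~has_missing).any():
            idx = np.where(~has_missing)[0]
            res = _fit_block(y[idx], x, exposure_index)
            cols[idx] = res
        for i in np.where(has_missing)[0]:
            try:
                f = fit_probe(y[i], x, exposure_index)
            except ValueError:
                cols[i] = np.nan
                skipped.append(str(self.beta.index[i]))
                continue
            cols[i] = [f.beta, f.se, f.ci_low, f.ci_high, f.p, f.n, float(f.degenerate)]

        df = pd.DataFrame(
            cols,
            index=self.beta.index,
            columns=["beta", "se", "ci_low", "ci_high", "p", "n", "degenerate"],
        )
        df["n"] = df["n"].astype("Int64")
        df["degenerate"] = df["degenerate"] == 1.0
        df = df.iloc[np.lexsort((df.index.astype(str), df["p"].fillna(np.inf)))]
        try:
            lam = genomic_lambda(df["p"])
        except ValueError:
            lam = np.nan
        return EWASResults(
            table=df,
            lambda_=lam,
            threshold=threshold,
            covariates=list(self.design.columns),
            n_sv=sum(c.startswith("sv") for c in self.design.columns),
            skipped=skipped,
        )


def _fit_block(y: np.ndarray, x: np.ndarray, exposure_index: int) -> np.ndarray:
    """Vectorised OLS for probes with no missing cells."""
    n, k = x.shape
    q, r = np.linalg.qr(x)
    coef = np.linalg.solve(r, q.T @ y.T)  # k x p
    resid = y.T - x @ coef
    rss = (resid ** 2).sum(axis=0)
    dof = n - k
    sigma2 = rss / dof
    r_inv = np.linalg.solve(r, np.eye(k))
    d = (r_inv ** 2).sum(axis=1)[exposure_index]
    beta = coef[exposure_index]
    scale = np.maximum(1.0, (y ** 2).mean(axis=1))
    degenerate = sigma2 <= _DEGENERATE_TOL * scale
    se = np.sqrt(np.where(degenerate, 0.0, sigma2) * d)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    p = np.where(degenerate, np.nan, 2.0 * stats.t.sf(np.abs(tval), dof))
    tcrit = stats.t.ppf(0.975, dof)
    ci_low = np.where(degenerate, beta, beta - tcrit * se)
    ci_high = np.where(degenerate, beta, beta + tcrit * se)
    out = np.column_stack(
        [beta, np.where(degenerate, 0.0, se), ci_low, ci_high, p,
         np.full_like(beta, n), degenerate.astype(float)]
    )
    return out


@dataclass
class EWASResults:
    """Fitted scan: per-probe estimates plus scan-level diagnostics."""

    table: pd.DataFrame
    lambda_: float
    threshold: float
    covariates: list[str]
    n_sv: int
    skipped: list[str]

    def select_hits(self, threshold: float | None = None) -> list[str]:
        return select_hits(self.table, self.threshold if threshold is None else threshold)

    def qq_data(self) -> pd.DataFrame:
        return qq_data(self.table["p"])

    def summary(self, top: int = 10) -> str:
        lines = [
            "EWAS scan results",
            f"  probes analysed : {len(self.table)}",
            f"  covariates      : {', '.join(self.covariates)}",
            f"  surrogate vars  : {self.n_sv}",
            f"  inflation lambda: {self.lambda_:.3f}" if np.isfinite(self.lambda_) else
            "  inflation lambda: n/a (too few probes)",
            f"  hits (p < {self.threshold:g}): {len(self.select_hits())}",
            "",
            self.table.head(top).to_string(),
        ]
        return "\n".join(lines)

    def to_tsv(self, path, annotation: pd.DataFrame | None = None) -> None:
        out = self.table.copy()
        if annotation is not None:
            for col in ("chr", "pos", "gene", "chen_flag"):
                if col in annotation.columns:
                    out[col] = annotation[col].reindex(out.index)
        out.to_csv(path, sep="\t", index_label="probe_id")


def run_ewas(
    matrix: pd.DataFrame,
    pheno: pd.DataFrame,
    status: pd.DataFrame,
    svs: SurrogateVariableSet | None = None,
    threshold: float = 1e-5,
) -> EWASResults:
    """Convenience wrapper: build the scan from phenotypes and fit it."""
    return EWASScan.from_phenotypes(matrix, pheno, status, svs=svs).fit(threshold=threshold)
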