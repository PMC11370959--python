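"""Synthetic methylation + phenotype datasets with known planted structure.

The generator emulates the data layout the scan operates on: a sample x probe
beta-value matrix, a phenotype table with a binary condition, age at
measurement, a technical batch label and a continuous confounder exposure,
and a probe annotation manifest. Probes are assigned exactly one role:

* ``direct`` — methylation shifted by the condition itself,
* ``confounded`` — methylation shifted by the confounder exposure, which also
  raises the log-odds of the condition (a common cause, never a mediator:
  this is the structure the minimally adjusted scan is designed to exploit),
* ``batch`` — methylation shifted by the technical batch label,
* ``null`` — baseline plus noise only.

All randomness flows from a single seed; per-component substreams are
derived deterministically so identical configs give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "generate_dataset",
    "generate_catalog_fixture",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Effect sizes are on the beta-value (methylation fraction) scale except
    ``confounder_effect_logodds``, which is the log-odds increment of the
    condition per unit of the (standard-normal) confounder exposure.
    """

    n_samples: int = 500
    n_probes: int = 2000
    n_direct_probes: int = 10
    n_confounded_probes: int = 20
    n_batch_probes: int = 100
    direct_effect: float = 0.05
    confounder_effect_meth: float = 0.05
    confounder_effect_logodds: float = 1.0
    batch_effect: float = 0.05
    batch_effect_logodds: float = 0.0
    baseline_prevalence: float = 0.3
    noise_sd: float = 0.02
    seed: int = 0
    confounder_name: str = "smoking"
    batch_name: str = "batch"

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_probes": self.n_probes,
            "n_direct_probes": self.n_direct_probes,
            "n_confounded_probes": self.n_confounded_probes,
            "n_batch_probes": self.n_batch_probes,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        planted = self.n_direct_probes + self.n_confounded_probes + self.n_batch_probes
        if planted > self.n_probes:
            raise ValueError(
                f"planted probe counts sum to {planted} > n_probes={self.n_probes}"
            )
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Which probe carries which planted role, and the planted variable names."""

    roles: dict[str, str]
    confounder_name: str
    batch_name: str

    def probes_with_role(self, role: str) -> list[str]:
        return [p for p, r in self.roles.items() if r == role]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


def _rng(seed: int, stream: int) -> np.random.Generator:
    # deterministic per-component substream from one master seed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate one dataset.

    Returns
    -------
    beta : DataFrame, probes x samples
        Methylation beta-values, clipped to [0, 1].
    pheno : DataFrame indexed by sample id
        Columns: condition (0/1), age (years, 15 or 17), batch label,
        the confounder exposure, plus independent ``sep`` and
        ``aam_months`` adjuster columns for the testing phase.
    annotation : DataFrame indexed by probe id
        Manifest columns: chr, pos, gene, probe_class, detection_fail,
        chen_flag.
    truth : TruthRecord
    """
    c = config
    probe_ids = [f"cg{i:08d}" for i in range(c.n_probes)]
    sample_ids = [f"S{i:05d}" for i in range(c.n_samples)]

    roles = {}
    i = 0
    for role, n in (
        ("direct", c.n_direct_probes),
        ("confounded", c.n_confounded_probes),
        ("batch", c.n_batch_probes),
    ):
        for _ in range(n):
            roles[probe_ids[i]] = role
            i += 1
    for pid in probe_ids[i:]:
        roles[pid] = "null"
    truth = TruthRecord(roles=roles, confounder_name=c.confounder_name, batch_name=c.batch_name)

    annotation = pd.DataFrame(
        {
            "chr": [str(1 + (k % 22)) for k in range(c.n_probes)],
            "pos": [1000 + 137 * k for k in range(c.n_probes)],
            "gene": [f"GENE{k}" for k in range(c.n_probes)],
            "probe_class": "cpg",
            "detection_fail": 0,
            "chen_flag": 0,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    rng_pheno = _rng(c.seed, 1)
    confounder = rng_pheno.standard_normal(c.n_samples)
    batch = rng_pheno.integers(0, 2, size=c.n_samples)
    age = rng_pheno.choice([15.0, 17.0], size=c.n_samples)
    base_logodds = np.log(c.baseline_prevalence / (1.0 - c.baseline_prevalence))
    # batch_effect_logodds models uneven case sampling across plates, the
    # classic situation where technical batch confounds the scan
    logodds = (
        base_logodds
        + c.confounder_effect_logodds * confounder
        + c.batch_effect_logodds * batch
    )
    p_case = 1.0 / (1.0 + np.exp(-logodds))
    condition = (rng_pheno.random(c.n_samples) < p_case).astype(int)
    sep = rng_pheno.integers(0, 2, size=c.n_samples)
    aam = np.round(rng_pheno.normal(150.0, 13.0, size=c.n_samples))

    pheno = pd.DataFrame(
        {
            "condition": condition,
            "age": age,
            c.batch_name: batch,
            c.confounder_name: confounder,
            "sep": sep,
            "aam_months": aam,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    rng_meth = _rng(c.seed, 2)
    baseline = rng_meth.uniform(0.2, 0.8, size=c.n_probes)
    values = np.tile(baseline[:, None], (1, c.n_samples))
    role_arr = np.array([roles[p] for p in probe_ids])
    values[role_arr == "direct"] += c.direct_effect * condition[None, :]
    values[role_arr == "confounded"] += c.confounder_effect_meth * confounder[None, :]
    values[role_arr == "batch"] += c.batch_effect * batch[None, :]
    values += rng_meth.normal(0.0, c.noise_sd, size=values.shape)
    np.clip(values, 0.0, 1.0, out=values)

    beta = pd.DataFrame(values, index=annotation.index.copy(), columns=pheno.index.copy())
    return beta, pheno, annotation, truth


def generate_catalog_fixture(truth: TruthRecord, annotation: pd.DataFrame) -> pd.DataFrame:
    """Build an offline catalog store covering the planted confounder.

    Each confounded probe (and, through the manifest, its gene) carries one
    record naming the confounder's trait; probes with other roles carry no
    record, so any trait harvested from null hits is a genuine false positive
    of the scan, not of the store.
    """
    unknown = [p for p in truth.roles if p not in annotation.index]
    if unknown:
        raise KeyError(f"probes missing from annotation: {unknown[:5]}")
    records = []
    for pid in truth.probes_with_role("confounded"):
        records.append(
            {
                "cpg": pid,
                "gene": annotation.loc[pid, "gene"],
                "trait": truth.confounder_name,
                "study_id": "SIM1",
                "p": 1e-8,
            }
        )
    return pd.DataFrame(records, columns=["cpg", "gene", "trait", "study_id", "p"])


def write_dataset(
    outdir: str | Path,
    beta: pd.DataFrame,
    pheno: pd.DataFrame,
    annotation: pd.DataFrame,
    truth: TruthRecord,
) -> dict[str, Path]:
    """Write the four dataset pieces in their on-disk dialects.

    Beta matrix and annotation as TSV, phenotype table as CSV, truth as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "pheno": outdir / "pheno.csv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    beta.to_csv(paths["beta"], sep="\t")
    pheno.to_csv(paths["pheno"])
    annotation.to_csv(paths["annotation"], sep="\t")
    truth.to_json(paths["truth"])
    return paths
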