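"""EWAS-catalog trait harvesting for hit CpGs and their resident genes.

A catalog store holds published CpG-phenotype associations and answers two
queries — by CpG id and by gene symbol — through either an offline TSV dump
or a live REST endpoint (both return the same record schema, so downstream
code never cares which backend served them). :func:`harvest_traits` turns a
hit list into a deduplicated set of candidate phenotypes with provenance
(found at the CpG itself vs only via its resident gene), and
:func:`enrichment` offers the optional Fisher's-exact check of whether a
trait is over-represented among the hits relative to the analysed universe.
"""

from __future__ import annotations

import json
import re
import time
import urllib.error
import urllib.parse
import urllib.request
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = [
    "CatalogStore",
    "TSVCatalogStore",
    "RESTCatalogStore",
    "CatalogUnreachableError",
    "HypothesisSet",
    "normalize_trait",
    "harvest_traits",
    "enrichment",
]

_COLUMNS = ["cpg", "gene", "trait", "study_id", "p"]


class CatalogUnreachableError(IOError):
    """Live backend could not be reached; the call is retryable."""


def normalize_trait(trait: str) -> str:
    """Trim, collapse internal whitespace and case-fold a trait name."""
    return re.sub(r"\s+", " ", str(trait).strip()).casefold()


class CatalogStore(ABC):
    """Query interface shared by the offline and live backends."""

    @abstractmethod
    def query_cpg(self, cpg: str) -> pd.DataFrame:
        """All records whose CpG id matches exactly (empty frame if none)."""

    @abstractmethod
    def query_gene(self, gene: str) -> pd.DataFrame:
        """All records whose gene symbol matches case-insensitively."""


class TSVCatalogStore(CatalogStore):
    """Offline store backed by a TSV dump (cpg, gene, trait, study_id, p)."""

    def __init__(self, source: str | Path | pd.DataFrame, version: str = "offline"):
        if isinstance(source, pd.DataFrame):
            df = source.copy()
        else:
            df = pd.read_csv(source, sep="\t", dtype={"cpg": str, "gene": str, "trait": str})
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"catalog store missing columns: {sorted(missing)}")
        df["cpg"] = df["cpg"].fillna("").astype(str)
        df["gene"] = df["gene"].fillna("").astype(str)
        self.records = df[_COLUMNS].reset_index(drop=True)
        self.version = version

    def query_cpg(self, cpg: str) -> pd.DataFrame:
        return self.records[self.records["cpg"] == str(cpg)].reset_index(drop=True)

    def query_gene(self, gene: str) -> pd.DataFrame:
        g = str(gene).casefold()
        if not g:
            return self.records.iloc[0:0].reset_index(drop=True)
        return self.records[self.records["gene"].str.casefold() == g].reset_index(drop=True)


class RESTCatalogStore(CatalogStore):
    """Live backend: GET {base_url}?cpg=<id> or ?gene=<symbol>.

    Expects a JSON body with a ``results`` list of records carrying at least
    cpg, gene, trait, study_id and p fields. Transient failures raise
    :class:`CatalogUnreachableError` after ``retries`` attempts.
    """

    def __init__(self, base_url: str, retries: int = 3, timeout: float = 10.0, backoff: float = 1.0):
        self.base_url = base_url.rstrip("?&")
        self.retries = retries
        self.timeout = timeout
        self.backoff = backoff
        self.version = f"rest:{base_url}"

    def _get(self, **params: str) -> pd.DataFrame:
        url = f"{self.base_url}?{urllib.parse.urlencode(params)}"
        last_err: Exception | None = None
        for attempt in range(self.retries):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    payload = json.loads(resp.read().decode("utf-8"))
                break
            except (urllib.error.URLError, TimeoutError, json.JSONDecodeError) as err:
                last_err = err
                if attempt + 1 < self.retries:
                    time.sleep(self.backoff * (attempt + 1))
        else:
            raise CatalogUnreachableError(f"catalog API unreachable at {url}: {last_err}")
        records = payload.get("results", payload if isinstance(payload, list) else [])
        df = pd.DataFrame(records)
        for col in _COLUMNS:
            if col not in df.columns:
                df[col] = "" if col != "p" else float("nan")
        df["cpg"] = df["cpg"].fillna("").astype(str)
        df["gene"] = df["gene"].fillna("").astype(str)
        return df[_COLUMNS].reset_index(drop=True)

    def query_cpg(self, cpg: str) -> pd.DataFrame:
        df = self._get(cpg=str(cpg))
        return df[df["cpg"] == str(cpg)].reset_index(drop=True)

    def query_gene(self, gene: str) -> pd.DataFrame:
        df = self._get(gene=str(gene))
        g = str(gene).casefold()
        return df[df["gene"].str.casefold() == g].reset_index(drop=True)


@dataclass
class HypothesisSet:
    """Deduplicated candidate phenotypes harvested for one condition.

    ``entries`` columns: trait (first-seen display form), trait_key
    (normalized), provenance ("cpg" if any hit CpG reports the trait
    directly, else "gene"), sources (sorted CpG ids / gene symbols the trait
    was found through) and study_count (distinct supporting study ids).
    """

    condition: str = ""
    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["trait", "trait_key", "provenance", "sources", "study_count"]
        )
    )

    def __len__(self) -> int:
        return len(self.entries)

    def traits(self) -> set[str]:
        return set(self.entries["trait_key"])

    def cpg_level(self) -> set[str]:
        e = self.entries
        return set(e.loc[e["provenance"] == "cpg", "trait_key"])

    def gene_level(self) -> set[str]:
        e = self.entries
        return set(e.loc[e["provenance"] == "gene", "trait_key"])

    def to_tsv(self, path) -> None:
        out = self.entries.copy()
        out["sources"] = out["sources"].map(lambda s: ";".join(s))
        out.insert(0, "condition", self.condition)
        out.to_csv(path, sep="\t", index=False)


def _split_genes(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    return [g for g in str(value).split(";") if g.strip()]


def harvest_traits(
    hits,
    annotation: pd.DataFrame,
    store: CatalogStore,
    condition: str = "",
) -> HypothesisSet:
    """Union of CpG-level and gene-level catalog traits over the hit probes.

    Trait names are deduplicated case-insensitively (whitespace collapsed);
    a trait reported both for a hit CpG and for a resident gene keeps
    CpG-level provenance. Probes annotated with several gene symbols query
    each symbol. Output is invariant to hit ordering and duplicates.
    """
    hit_ids = sorted({str(h) for h in hits})
    missing = [h for h in hit_ids if h not in annotation.index]
    if missing:
        raise KeyError(f"hit probes missing from annotation: {missing[:5]}")

    collected: dict[str, dict] = {}

    def _add(records: pd.DataFrame, provenance: str, source: str) -> None:
        for _, rec in records.iterrows():
            key = normalize_trait(rec["trait"])
            if not key:
                continue
            entry = collected.setdefault(
                key,
                {"trait": re.sub(r"\s+", " ", str(rec["trait"]).strip()),
                 "trait_key": key, "provenance": provenance,
                 "sources": set(), "studies": set()},
            )
            if provenance == "cpg" and entry["provenance"] == "gene":
                entry["provenance"] = "cpg"
            entry["sources"].add(source)
            entry["studies"].add(str(rec["study_id"]))

    for hit in hit_ids:
        _add(store.query_cpg(hit), "cpg", hit)
    for hit in hit_ids:
        for gene in _split_genes(annotation.loc[hit, "gene"]):
            _add(store.query_gene(gene), "gene", gene)

    rows = [
        {
            "trait": e["trait"],
            "trait_key": key,
            "provenance": e["provenance"],
            "sources": tuple(sorted(e["sources"])),
            "study_count": len(e["studies"]),
        }
        for key, e in sorted(collected.items())
    ]
    entries = pd.DataFrame(rows, columns=["trait", "trait_key", "provenance", "sources", "study_count"])
    return HypothesisSet(condition=condition, entries=entries)


def enrichment(
    trait: str,
    hits,
    store: CatalogStore,
    universe,
) -> tuple[float, float]:
    """Fisher's exact test of trait over-representation among the hits.

    Builds the 2x2 table of (hit vs non-hit) x (trait-annotated vs not) over
    the analysed probe universe and returns (odds ratio, two-sided exact p).
    The odds ratio is the cross-product ratio, with a 0.5 continuity
    correction applied only when a cell is zero (display convention); the
    p-value is computed on the uncorrected table.
    """
    hit_set = {str(h) for h in hits}
    universe_set = {str(u) for u in universe}
    if not hit_set:
        raise ValueError("no hits: enrichment test is undefined")
    if not hit_set <= universe_set:
        raise ValueError("hits must be a subset of the analysed universe")

    key = normalize_trait(trait)
    if isinstance(store, TSVCatalogStore):
        records = store.records
    else:  # pragma: no cover - live backends expose no full dump; query per probe
        records = pd.concat([store.query_cpg(c) for c in sorted(universe_set)], ignore_index=True)
    trait_records = records[records["trait"].map(normalize_trait) == key]
    if trait_records.empty:
        raise KeyError(f"trait {trait!r} absent from catalog store")
    annotated = set(trait_records["cpg"]) & universe_set

    a = len(hit_set & annotated)
    b = len(hit_set - annotated)
    c = len(annotated - hit_set)
    d = len(universe_set) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)
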