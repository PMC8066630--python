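"""Stratified misdescription statistics and the packaged survey fixtures.

The three survey tables (Northern, Central, Southern Italy; 19 + 20 + 21
products) ship with the package as machine-readable TSVs transcribing every
printed column: product code, bracketed processed-sample count, retail type,
menu label, declared scientific name(s), barcode-identified species, matched
accessions, percent identity, and the bold misdescription mark.  Feeding the
declared and identified columns through the compliance engine reproduces the
bold/non-bold marking product-by-product, and the stratified rates derived
from it.

Rates are per product (one table row = one product): a stratum's rate is
100 x misdescribed / total over the products in it, with unresolved products
excluded from both numerator and denominator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .name_compliance import (
    CATEGORIES,
    REGIONS,
    RETAIL_TYPES,
    ComplianceCall,
    ProductRecord,
    RuleSet,
    call_compliance,
    categorize_label,
    default_rules,
    parse_declared_species,
)
from .species_assignment import SpeciesCall, round_half_up

logger = logging.getLogger(__name__)

_FIXTURE_FILES = {"north": "north.tsv", "central": "central.tsv", "south": "south.tsv"}

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class StratumStats:
    n_products: int
    n_misdescribed: int
    rate_pct: float
    rate_pct_rounded: int


@dataclass
class SurveySummary:
    """Stratified misdescription rates plus survey-level summaries.

    ``strata`` maps (region, retail_type, category) keys — each position
    either a concrete value or the wildcard ``"all"`` — to counts and rates.
    """

    strata: dict[tuple[str, str, str], StratumStats]
    species_inventory: dict[str, int] = field(default_factory=dict)
    identity_min: Optional[float] = None
    identity_max: Optional[float] = None
    identity_mean: Optional[float] = None
    n_sequences_processed: int = 0
    n_unresolved: int = 0

    def rate(self, region: str = "all", retail: str = "all", category: str = "all") -> StratumStats:
        return self.strata[(region, retail, category)]


@dataclass
class FixtureTable:
    """One or more packaged survey tables in analysis-ready form."""

    table: pd.DataFrame  # one row per product, all printed columns
    products: list[ProductRecord]

    def __len__(self) -> int:
        return len(self.products)

    @property
    def identified_species(self) -> dict[str, str]:
        return dict(zip(self.table["sample_code"], self.table["identified_species"]))

    @property
    def identity_pct(self) -> dict[str, float]:
        return dict(zip(self.table["sample_code"], self.table["identity_pct"]))

    @property
    def misdescribed_flag(self) -> dict[str, bool]:
        return dict(zip(self.table["sample_code"], self.table["misdescribed"].astype(bool)))


def _fixture_dir() -> Path:
    return Path(str(files("coiauth") / "fixtures"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_fixture(region: str = "all", rules: RuleSet | None = None) -> FixtureTable:
    """Load the packaged survey table(s) for one region or all three.

    File checksums are verified against the recorded manifest to guard
    against silent edits of the fixture transcription.
    """
    if region not in ("all", *REGIONS):
        raise ValueError(f"region must be one of {('all', *REGIONS)}, got {region!r}")
    rules = rules if rules is not None else default_rules()
    fdir = _fixture_dir()
    manifest_path = fdir / "checksums.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    frames = []
    wanted = REGIONS if region == "all" else (region,)
    for reg in wanted:
        path = fdir / _FIXTURE_FILES[reg]
        if manifest:
            digest = _sha256(path)
            if manifest.get(_FIXTURE_FILES[reg]) != digest:
                raise ValueError(
                    f"fixture checksum mismatch for {path.name}: file was modified"
                )
        df = pd.read_csv(path, sep="\t", dtype={"identity_pct": float})
        df.insert(1, "region", reg)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    products = [
        ProductRecord(
            sample_code=row.sample_code,
            region=row.region,
            retail_type=row.retail_type,
            menu_label=row.menu_label,
            declared_taxa=parse_declared_species(row.declared_species, rules),
            category=categorize_label(row.menu_label),
            processed_replicates=int(row.processed_replicates),
            declared_unlisted=bool(row.declared_unlisted),
        )
        for row in table.itertuples()
    ]
    return FixtureTable(table=table, products=products)


def fixture_species_calls(fixture: FixtureTable) -> dict[str, SpeciesCall]:
    """Per-product assigned species calls from the printed identified column."""
    calls = {}
    for row in fixture.table.itertuples():
        calls[row.sample_code] = SpeciesCall(
            sample_code=row.sample_code,
            status="assigned",
            species=row.identified_species,
            best_identity_pct=float(row.identity_pct),
            tied_species=(row.identified_species,),
            replicate_calls=[],
        )
    return calls


def fixture_verdicts(
    fixture: FixtureTable, rules: RuleSet | None = None
) -> list[ComplianceCall]:
    """Run the compliance engine over a fixture's declared/identified columns."""
    rules = rules if rules is not None else default_rules()
    calls = fixture_species_calls(fixture)
    return [
        call_compliance(product, calls[product.sample_code], rules=rules)
        for product in fixture.products
    ]


def stratified_rates(
    verdicts: Sequence[ComplianceCall],
    products: Sequence[ProductRecord],
    rounding: str = "none",
) -> SurveySummary:
    """Misdescription rates for every (region x retail x category) stratum.

    Every combination including ``"all"`` wildcards is materialized, so
    wildcard counts equal the sum of their refinements by construction.
    Unresolved verdicts are excluded from numerator and denominator, with
    their count logged and reported.
    """
    if rounding not in ("none", "nearest_integer"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    by_code = {v.sample_code: v for v in verdicts}
    missing = [p.sample_code for p in products if p.sample_code not in by_code]
    if missing:
        raise ValueError(f"products without a verdict: {missing}")
    n_unresolved = sum(1 for v in verdicts if v.verdict == "unresolved")
    if n_unresolved:
        logger.info("excluding %d unresolved products from rate denominators", n_unresolved)
    rows = [
        (p.region, p.retail_type, p.category, by_code[p.sample_code].verdict == "misdescribed")
        for p in products
        if by_code[p.sample_code].verdict != "unresolved"
    ]
    strata: dict[tuple[str, str, str], StratumStats] = {}
    for reg in ("all", *REGIONS):
        for ret in ("all", *RETAIL_TYPES):
            for cat in ("all", *CATEGORIES):
                sel = [
                    mis
                    for r, t, c, mis in rows
                    if (reg == "all" or r == reg)
                    and (ret == "all" or t == ret)
                    and (cat == "all" or c == cat)
                ]
                n = len(sel)
                m = sum(sel)
                rate = 100.0 * m / n if n else 0.0
                strata[(reg, ret, cat)] = StratumStats(
                    n_products=n,
                    n_misdescribed=m,
                    rate_pct=rate if rounding == "none" else round_half_up(rate, 1),
                    rate_pct_rounded=int(round_half_up(rate, 0)),
                )
    return SurveySummary(
        strata=strata,
        n_sequences_processed=sum(p.processed_replicates for p in products),
        n_unresolved=n_unresolved,
    )


def species_inventory(calls: Iterable[SpeciesCall]) -> dict[str, int]:
    """Distinct identified binomials with per-species product counts."""
    counts: dict[str, int] = {}
    for call in calls:
        if call.status == "assigned" and call.species:
            counts[call.species] = counts.get(call.species, 0) + 1
    return dict(sorted(counts.items()))


def identity_summary(identities: Sequence[float]) -> tuple[float, float, float]:
    """(min, max, mean) of top-hit identities, at 2-decimal reporting precision."""
    vals = list(identities)
    if not vals:
        raise ValueError("identity_summary requires a non-empty list")
    return (
        round_half_up(min(vals), 2),
        round_half_up(max(vals), 2),
        round_half_up(sum(vals) / len(vals), 2),
    )


def summarize_survey(
    verdicts: Sequence[ComplianceCall],
    products: Sequence[ProductRecord],
    species_calls: Mapping[str, SpeciesCall] | None = None,
    rounding: str = "none",
) -> SurveySummary:
    """Full survey summary: strata, species inventory and identity range."""
    summary = stratified_rates(verdicts, products, rounding)
    if species_calls:
        summary.species_inventory = species_inventory(species_calls.values())
        idents = [
            c.best_identity_pct
            for c in species_calls.values()
            if c.status == "assigned" and c.best_identity_pct is not None
        ]
        if idents:
            summary.identity_min, summary.identity_max, summary.identity_mean = (
                identity_summary(idents)
            )
    return summary


def _summary_to_dict(summary: SurveySummary) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "strata": {
            "|".join(key): {
                "n_products": s.n_products,
                "n_misdescribed": s.n_misdescribed,
                "rate_pct": s.rate_pct,
                "rate_pct_rounded": s.rate_pct_rounded,
            }
            for key, s in summary.strata.items()
        },
        "species_inventory": summary.species_inventory,
        "identity_min": summary.identity_min,
        "identity_max": summary.identity_max,
        "identity_mean": summary.identity_mean,
        "n_sequences_processed": summary.n_sequences_processed,
        "n_unresolved": summary.n_unresolved,
    }


def write_report(summary: SurveySummary, path: str | Path, format: str = "json") -> Path:
    """Write a survey summary as JSON (versioned schema) or TSV (one stratum/row)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_summary_to_dict(summary), indent=2) + "\n")
    elif format == "tsv":
        records = [
            {
                "region": key[0],
                "retail_type": key[1],
                "category": key[2],
                "n_products": s.n_products,
                "n_misdescribed": s.n_misdescribed,
                "rate_pct": s.rate_pct,
                "rate_pct_rounded": s.rate_pct_rounded,
            }
            for key, s in summary.strata.items()
            if s.n_products > 0
        ]
        pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def load_report(path: str | Path) -> SurveySummary:
    """Read back a JSON report written by :func:`write_report`."""
    data = json.loads(Path(path).read_text())
    strata = {
        tuple(key.split("|")): StratumStats(
            n_products=s["n_products"],
            n_misdescribed=s["n_misdescribed"],
            rate_pct=s["rate_pct"],
            rate_pct_rounded=s["rate_pct_rounded"],
        )
        for key, s in data["strata"].items()
    }
    return SurveySummary(
        strata=strata,
        species_inventory=data["species_inventory"],
        identity_min=data["identity_min"],
        identity_max=data["identity_max"],
        identity_mean=data["identity_mean"],
        n_sequences_processed=data["n_sequences_processed"],
        n_unresolved=data["n_unresolved"],
    )


def reproduce_survey(region: str = "all") -> dict:
    """One-shot reproduction of the packaged survey from its fixtures.

    Loads the requested fixture(s), recomputes every per-product verdict with
    the default rule configuration, checks them against the tables' bold
    marks, and returns the summary plus headline numbers.
    """
    fixture = load_fixture(region)
    rules = default_rules()
    verdicts = fixture_verdicts(fixture, rules)
    calls = fixture_species_calls(fixture)
    summary = summarize_survey(verdicts, fixture.products, calls)
    flags = fixture.misdescribed_flag
    mismatches = [
        v.sample_code
        for v in verdicts
        if (v.verdict == "misdescribed") != flags[v.sample_code]
    ]
    return {
        "summary": summary,
        "verdicts": verdicts,
        "n_products": len(fixture),
        "verdict_mismatches": mismatches,
        "n_species": len(summary.species_inventory),
        "identity_range": (summary.identity_min, summary.identity_max),
        "n_sequences_processed": summary.n_sequences_processed,
    }
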