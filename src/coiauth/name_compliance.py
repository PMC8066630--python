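"""Trade-name resolution and misdescription calling.

A product is sold under a menu/label name; a regulatory name list (for the
packaged survey, the Italian Ministerial Decree n.19105 of 22 September 2017)
maps each official trade name to the taxa it lawfully declares, at species,
genus or family rank.  A product is *misdescribed* when the species identified
by DNA barcoding matches none of the taxa declared by the menu name, nor any
scientific name explicitly declared alongside it.  Umbrella names ("tobiko",
"ikura") lawfully cover whole genera, so congeneric substitutions under such a
name are compliant while, e.g., capelin roe sold as tobiko is not.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

RANKS = ("species", "genus", "family")
REGIONS = ("north", "central", "south")
RETAIL_TYPES = ("restaurant", "takeaway")
CATEGORIES = ("white_fish", "tuna", "roe", "other")

#: Epithet tokens that denote an unresolved species, i.e. a genus-rank claim.
_GENUS_ONLY_TOKENS = {"sp", "sp.", "spp", "spp."}


def normalize_name(text: str) -> str:
    """Case-fold, strip diacritics and collapse whitespace for rule lookup."""
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    return " ".join(text.casefold().split())


@dataclass(frozen=True)
class TaxonConstraint:
    """One taxon a trade name may lawfully declare, at an explicit rank."""

    rank: str  # species | genus | family
    taxon: str

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}; expected one of {RANKS}")
        if not self.taxon:
            raise ValueError("empty taxon in constraint")


@dataclass(frozen=True)
class NameRule:
    trade_name: str  # normalized key
    allowed_taxa: tuple[TaxonConstraint, ...]
    source: str = ""
    listed: bool = True  # False for names footnoted as absent from the decree

    def __post_init__(self) -> None:
        if not self.allowed_taxa:
            raise ValueError(f"rule {self.trade_name!r} has no allowed taxa")


RuleSet = dict[str, NameRule]


def _merge_rule(rules: RuleSet, rule: NameRule) -> None:
    existing = rules.get(rule.trade_name)
    if existing is None:
        rules[rule.trade_name] = rule
    else:
        merged = tuple(dict.fromkeys(existing.allowed_taxa + rule.allowed_taxa))
        rules[rule.trade_name] = NameRule(
            trade_name=rule.trade_name,
            allowed_taxa=merged,
            source=existing.source or rule.source,
            listed=existing.listed and rule.listed,
        )


def load_name_rules(path: str | Path) -> RuleSet:
    """Load a trade-name rule table from TSV or YAML.

    Both formats carry rows of (trade_name, rank, taxon, listed, source);
    duplicate trade names merge by union of their allowed taxa.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        rows = yaml.safe_load(path.read_text()) or []
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        rows = df.to_dict("records")
    rules: RuleSet = {}
    for row in rows:
        listed = row.get("listed", True)
        if isinstance(listed, str):
            listed = listed.strip().lower() not in ("false", "0", "no", "")
        _merge_rule(
            rules,
            NameRule(
                trade_name=normalize_name(str(row["trade_name"])),
                allowed_taxa=(
                    TaxonConstraint(rank=str(row["rank"]).strip().lower(),
                                    taxon=str(row["taxon"]).strip()),
                ),
                source=str(row.get("source", "")),
                listed=bool(listed),
            ),
        )
    return rules


def default_rules() -> RuleSet:
    """The packaged rule configuration for the Italian-survey trade names."""
    from importlib.resources import files

    path = files("coiauth") / "fixtures" / "md_rules.yaml"
    return load_name_rules(Path(str(path)))


def _label_alternates(label: str) -> list[str]:
    """Split a compound label into candidate rule keys.

    Compound labels join alternatives with "or", "/" or commas, and may carry
    a parenthetical gloss ("maguro yaki (red tuna)"); each part is looked up
    independently and the results are unioned.
    """
    norm = normalize_name(label)
    for sep in ("(", ")", "/", ","):
        norm = norm.replace(sep, "|")
    parts = [p.strip() for p in norm.split("|")]
    out = []
    for part in parts:
        for alt in part.split(" or "):
            alt = alt.strip()
            if alt and alt not in out:
                out.append(alt)
    return out


def resolve_declared(
    menu_label: str, rules: RuleSet
) -> tuple[tuple[TaxonConstraint, ...], bool]:
    """Resolve a menu label to the taxa it declares under the rule set.

    Returns (constraints, listed): an exact normalized lookup is tried first,
    then each compound part; an unknown label returns no constraints with
    ``listed=False`` (an unlisted-name flag, not an exception).
    """
    norm = normalize_name(menu_label)
    if norm in rules:
        rule = rules[norm]
        return rule.allowed_taxa, rule.listed
    constraints: list[TaxonConstraint] = []
    listed = True
    matched = False
    for part in _label_alternates(menu_label):
        rule = rules.get(part)
        if rule is not None:
            matched = True
            listed = listed and rule.listed
            for c in rule.allowed_taxa:
                if c not in constraints:
                    constraints.append(c)
    if not matched:
        return (), False
    return tuple(constraints), listed


def parse_declared_species(text: str, rules: RuleSet | None = None) -> tuple[TaxonConstraint, ...]:
    """Parse a declared-species cell into taxon constraints.

    Handles "Genus epithet", slash-joined alternatives
    ("Sparus aurata/Dicentrarchus labrax"), genus-only claims ("Anguilla sp"),
    and vernacular cells ("salmon eggs") which fall back to rule resolution.
    """
    constraints: list[TaxonConstraint] = []
    for part in str(text).split("/"):
        part = " ".join(part.replace("*", "").split())
        if not part:
            continue
        tokens = part.split()
        if len(tokens) == 2 and tokens[0][0].isupper():
            if tokens[1].lower() in _GENUS_ONLY_TOKENS:
                c = TaxonConstraint("genus", tokens[0])
            else:
                c = TaxonConstraint("species", part)
            if c not in constraints:
                constraints.append(c)
        elif rules is not None:
            resolved, _ = resolve_declared(part, rules)
            for c in resolved:
                if c not in constraints:
                    constraints.append(c)
        else:
            logger.warning("declared-species cell %r not parseable as a taxon", part)
    return tuple(constraints)


def categorize_label(menu_label: str) -> str:
    """Map a menu label to the survey product category.

    Tuna labels (tuna/maguro) -> tuna; roe labels (tobiko, ikura, roe, egg)
    -> roe; white fish (sea bream / bass) -> white_fish; everything else
    (eel, swordfish rolls, ...) -> other.
    """
    norm = normalize_name(menu_label)
    if "tuna" in norm or "maguro" in norm:
        return "tuna"
    if any(k in norm for k in ("tobiko", "ikura", "roe", "egg")):
        return "roe"
    if "sea bream" in norm or "bass" in norm:
        return "white_fish"
    return "other"


@dataclass(frozen=True)
class ProductRecord:
    sample_code: str
    region: str  # north | central | south
    retail_type: str  # restaurant | takeaway
    menu_label: str
    declared_taxa: tuple[TaxonConstraint, ...] = ()
    category: str = "other"
    processed_replicates: int = 3
    declared_unlisted: bool = False  # declared name footnoted as absent from the decree

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"{self.sample_code}: unknown region {self.region!r}")
        if self.retail_type not in RETAIL_TYPES:
            raise ValueError(f"{self.sample_code}: unknown retail type {self.retail_type!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.sample_code}: unknown category {self.category!r}")
        if self.processed_replicates not in (1, 2, 3):
            raise ValueError(
                f"{self.sample_code}: processed_replicates must be 1..3, "
                f"got {self.processed_replicates}"
            )


@dataclass
class ComplianceCall:
    sample_code: str
    declared_taxa: tuple[TaxonConstraint, ...]
    identified_species: Optional[str]
    verdict: str  # compliant | misdescribed | unlisted_name | unresolved
    rationale: str = ""


def _satisfies(
    species: str,
    constraint: TaxonConstraint,
    taxonomy: Optional[object],
) -> bool:
    if constraint.rank == "species":
        return normalize_name(species) == normalize_name(constraint.taxon)
    if constraint.rank == "genus":
        return normalize_name(species.split()[0]) == normalize_name(constraint.taxon)
    # family rank needs an external species -> family lookup
    if taxonomy is None:
        raise ValueError(
            f"family-rank constraint on {constraint.taxon!r} requires a taxonomy, "
            f"but none was provided for species {species!r}"
        )
    if hasattr(taxonomy, "family_of"):
        try:
            family = taxonomy.family_of(species)
        except KeyError as exc:
            raise ValueError(f"species {species!r} absent from taxonomy") from exc
    else:
        try:
            family = taxonomy[species]
        except KeyError as exc:
            raise ValueError(f"species {species!r} absent from taxonomy") from exc
    return normalize_name(family) == normalize_name(constraint.taxon)


def call_compliance(
    product: ProductRecord,
    species_call,
    rules: RuleSet | None = None,
    taxonomy: Optional[object] = None,
) -> ComplianceCall:
    """Call misdescription for one product.

    The identified species is checked against the union of (i) the explicitly
    declared scientific names and (ii) the taxa the menu label resolves to
    under the rule set; a match with any constraint is compliant.  A product
    whose barcode call is not an assigned binomial is unresolved and excluded
    from survey denominators downstream.
    """
    if species_call.sample_code and species_call.sample_code != product.sample_code:
        raise ValueError(
            f"species call {species_call.sample_code!r} does not belong to "
            f"product {product.sample_code!r}"
        )
    if species_call.status != "assigned" or not species_call.species:
        return ComplianceCall(
            sample_code=product.sample_code,
            declared_taxa=product.declared_taxa,
            identified_species=None,
            verdict="unresolved",
            rationale=f"barcoding call status: {species_call.status}",
        )
    species = species_call.species
    constraints = list(product.declared_taxa)
    label_listed = True
    if rules is not None:
        label_taxa, label_listed = resolve_declared(product.menu_label, rules)
        for c in label_taxa:
            if c not in constraints:
                constraints.append(c)
    if not constraints:
        return ComplianceCall(
            sample_code=product.sample_code,
            declared_taxa=(),
            identified_species=species,
            verdict="unlisted_name",
            rationale=f"menu label {product.menu_label!r} has no rule and no "
            "declared scientific name",
        )
    satisfied = [c for c in constraints if _satisfies(species, c, taxonomy)]
    notes = []
    if rules is not None and not label_listed:
        notes.append(f"label {product.menu_label!r} not an official listed name")
    if satisfied:
        c = satisfied[0]
        notes.insert(0, f"{species} satisfies {c.rank} constraint {c.taxon}")
        verdict = "compliant"
    else:
        wanted = ", ".join(f"{c.taxon} ({c.rank})" for c in constraints)
        notes.insert(0, f"{species} matches none of: {wanted}")
        verdict = "misdescribed"
    return ComplianceCall(
        sample_code=product.sample_code,
        declared_taxa=tuple(constraints),
        identified_species=species,
        verdict=verdict,
        rationale="; ".join(notes),
    )
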