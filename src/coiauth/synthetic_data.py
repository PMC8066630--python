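"""Ground-truthed synthetic data for every pipeline stage.

Generates COI-like reference panels (stop-free coding sequences under the
vertebrate mitochondrial code), query amplicons mutated to a controlled
percent identity, NUMT decoys that must fail the QC screen, and whole labeled
surveys with a known mislabeling fraction — so assignment accuracy and
rate-recovery can be tested without any external database.

The mutation model is substitution-only (accepted survey sequences showed no
indels; indels belong to the decoys), with the replacement base drawn
uniformly from the admissible alternatives and no transition/transversion
bias.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .name_compliance import (
    CATEGORIES,
    REGIONS,
    RETAIL_TYPES,
    NameRule,
    ProductRecord,
    RuleSet,
    TaxonConstraint,
)
from .seq_qc import BarcodeRead, QCConfig, screen_numt, vertebrate_mito_stops, write_fasta
from .species_assignment import ReferencePanel, ReferenceRecord

_STOPS = vertebrate_mito_stops()
#: Codons that can appear in a clean vertebrate-mitochondrial coding frame.
NONSTOP_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)

#: 22-mer whose insertion puts a stop codon in all six frame/strand
#: combinations: "TAATTAATTAA" holds TAA at internal offsets 0, 4 and 8 —
#: one per phase, so every forward frame hits a stop wherever the block
#: lands — and its reverse complement does the same for the reverse frames.
_ALL_FRAME_STOP_BLOCK = "TAATTAATTAA" + "TTAATTAATTA"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated survey.

    Defaults target the regime of the packaged survey: ~650 nt amplicons
    (651 here, a whole number of codons), queries at 98.5% identity to their
    source species (the survey observed 98.17-99.85%), reference species
    diverged by at least 10%, and up to three replicate extractions per
    product.
    """

    seed: int
    n_species: int = 8
    sequence_length_nt: int = 651
    min_interspecies_divergence: float = 0.10
    query_identity: float = 0.985
    mislabel_rate: float = 0.0
    n_products: int = 60
    replicates_per_product: int = 3
    numt_fraction: float = 0.0
    n_umbrella_names: int = 0

    def __post_init__(self) -> None:
        for name in ("min_interspecies_divergence", "query_identity", "mislabel_rate", "numt_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sequence_length_nt % 3 != 0:
            raise ValueError("sequence_length_nt must be divisible by 3")
        if self.mislabel_rate > 0 and self.n_species < 2:
            raise ValueError("mislabel_rate > 0 requires at least 2 species")
        if self.replicates_per_product not in (1, 2, 3):
            raise ValueError("replicates_per_product must be 1..3")


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery checks."""

    species_sequences: dict[str, str] = field(default_factory=dict)
    products: dict[str, dict] = field(default_factory=dict)  # code -> truth record
    reads: dict[str, dict] = field(default_factory=dict)  # read_id -> truth record
    mislabel_rate_realized: float = 0.0

    def intended_rate_pct(self) -> float:
        """Realized misdescription rate (%) among products, per the generator."""
        verdicts = [p["intended_verdict"] for p in self.products.values()]
        mis = sum(1 for v in verdicts if v == "misdescribed")
        return 100.0 * mis / len(verdicts) if verdicts else 0.0


def _hamming_identity(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def _random_coding_sequence(rng: random.Random, length_nt: int) -> str:
    return "".join(rng.choice(NONSTOP_CODONS) for _ in range(length_nt // 3))


def _genus_name(i: int, n_umbrella: int) -> str:
    """Umbrella-covered species come in consecutive pairs sharing a genus."""
    pair = i // 2
    if pair < n_umbrella:
        return f"Umbra{pair:02d}"
    return f"Simulatus{i:03d}"


def _species_name(i: int, n_umbrella: int = 0) -> str:
    return f"{_genus_name(i, n_umbrella)} fictus{i:03d}"


def simulate_panel(config: SimulationConfig) -> tuple[ReferencePanel, GroundTruth]:
    """Generate a reference panel of diverged, stop-free coding sequences.

    Pairwise identity between any two species is at most
    ``1 - min_interspecies_divergence`` (verified directly after generation;
    a violating draw is regenerated, with a bounded retry budget).
    """
    rng = random.Random(config.seed)
    sequences: list[str] = []
    for i in range(config.n_species):
        for attempt in range(100):
            candidate = _random_coding_sequence(rng, config.sequence_length_nt)
            if all(
                _hamming_identity(candidate, prev) <= 1.0 - config.min_interspecies_divergence
                for prev in sequences
            ):
                sequences.append(candidate)
                break
        else:
            raise RuntimeError(
                f"could not generate species {i} at divergence "
                f">= {config.min_interspecies_divergence} within 100 attempts"
            )
    nu = config.n_umbrella_names
    records = [
        ReferenceRecord(
            accession=f"SIM{i:05d}",
            species=_species_name(i, nu),
            genus=_genus_name(i, nu),
            family="Simulatidae",
            sequence=seq,
        )
        for i, seq in enumerate(sequences)
    ]
    truth = GroundTruth(
        species_sequences={_species_name(i, nu): seq for i, seq in enumerate(sequences)}
    )
    return ReferencePanel(records=records), truth


def mutate_to_identity(
    reference: str,
    target_identity: float,
    seed: int,
    preserve_frame: bool = True,
) -> str:
    """Substitute exactly round(L x (1 - target_identity)) distinct positions.

    With ``preserve_frame``, a substitution that would create an in-frame
    (frame 0, forward) stop codon is resampled among the remaining bases —
    every codon position admits at least one non-stop alternative under the
    vertebrate mitochondrial code, so this always succeeds.  No indels are
    introduced.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError(f"target_identity must be in (0, 1], got {target_identity}")
    length = len(reference)
    n_mut = int(round(length * (1.0 - target_identity)))
    if n_mut > length:
        raise ValueError(f"{n_mut} mutations exceed sequence length {length}")
    if n_mut == 0:
        return reference
    rng = random.Random(seed)
    seq = list(reference)
    for pos in rng.sample(range(length), n_mut):
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        rng.shuffle(alternatives)
        for base in alternatives:
            old = seq[pos]
            seq[pos] = base
            if not preserve_frame:
                break
            codon_start = (pos // 3) * 3
            codon = "".join(seq[codon_start : codon_start + 3])
            if len(codon) < 3 or codon not in _STOPS:
                break
            seq[pos] = old
        else:  # pragma: no cover - unreachable: a non-stop alternative always exists
            raise RuntimeError(f"no admissible substitution at position {pos}")
    return "".join(seq)


DECOY_MODES = ("stop_insert", "frameshift", "truncate")


def make_numt_decoy(reference: str, seed: int, mode: str = "stop_insert") -> str:
    """Derive a NUMT-like decoy that must fail the QC screen.

    stop_insert places stop codons in all six frames; frameshift deletes one
    base mid-sequence (appending all-frame stops if the shifted sequence were
    still stop-free somewhere); truncate returns a sub-600 nt fragment, below
    the vertebrate NUMT size heuristic.
    """
    if mode not in DECOY_MODES:
        raise ValueError(f"unknown decoy mode {mode!r}; expected one of {DECOY_MODES}")
    rng = random.Random(seed)
    n = len(reference)
    if mode == "truncate":
        decoy = reference[: rng.randint(max(60, n // 3), min(599, n - 1))]
    elif mode == "stop_insert":
        pos = rng.randint(n // 4, 3 * n // 4)
        decoy = reference[:pos] + _ALL_FRAME_STOP_BLOCK + reference[pos:]
    else:  # frameshift
        pos = rng.randint(n // 3, 2 * n // 3)
        decoy = reference[:pos] + reference[pos + 1 :]
        result = screen_numt(BarcodeRead("decoy", decoy, "decoy"), QCConfig())
        if not result.numt_flag:  # shifted tail happened to stay stop-free
            mid = len(decoy) // 2
            decoy = decoy[:mid] + _ALL_FRAME_STOP_BLOCK + decoy[mid:]
    check = screen_numt(BarcodeRead("decoy", decoy, "decoy"), QCConfig())
    if not check.numt_flag:  # pragma: no cover - construction guarantees failure
        raise RuntimeError(f"decoy (mode={mode}) unexpectedly passed the NUMT screen")
    return decoy


@dataclass
class SurveyDataset:
    """Everything a simulated survey produces, in pipeline-ready form."""

    reads: list[BarcodeRead]
    products: list[ProductRecord]
    rules: RuleSet
    panel: ReferencePanel
    ground_truth: GroundTruth


def _trade_name(i: int) -> str:
    return f"simfish {i:03d}"


def _survey_rules(config: SimulationConfig, panel: ReferencePanel) -> RuleSet:
    rules: RuleSet = {}
    for i, rec in enumerate(panel.records):
        rules[_trade_name(i)] = NameRule(
            trade_name=_trade_name(i),
            allowed_taxa=(TaxonConstraint("species", rec.species),),
            source="simulated",
        )
    # umbrella names lawfully covering a whole simulated genus
    for pair in range(config.n_umbrella_names):
        members = [r for r in panel.records if r.genus == f"Umbra{pair:02d}"]
        if len(members) >= 2:
            name = f"umbrella {pair:02d}"
            rules[name] = NameRule(
                trade_name=name,
                allowed_taxa=(TaxonConstraint("genus", members[0].genus),),
                source="simulated umbrella",
            )
    return rules


def simulate_survey(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SurveyDataset:
    """Generate a full labeled survey with known ground truth.

    Each product draws a region, retail type and category uniformly, a true
    species uniformly from the panel, and — with probability
    ``mislabel_rate`` — a declared trade name swapped to a different species.
    Reads are mutated copies of the true species' reference at
    ``query_identity``; a ``numt_fraction`` of reads are replaced by decoys.
    With ``outdir`` set, all pipeline input files are written there.
    """
    panel, truth = simulate_panel(config)
    rules = _survey_rules(config, panel)
    rng = random.Random(config.seed + 1_000_003)
    species_names = [r.species for r in panel.records]
    reads: list[BarcodeRead] = []
    products: list[ProductRecord] = []
    decoy_cycle = itertools.cycle(DECOY_MODES)
    n_mislabels = 0
    for p in range(config.n_products):
        code = f"P{p:04d}"
        true_idx = rng.randrange(config.n_species)
        mislabeled = rng.random() < config.mislabel_rate
        if mislabeled:
            n_mislabels += 1
            declared_idx = rng.choice([i for i in range(config.n_species) if i != true_idx])
        else:
            declared_idx = true_idx
        label = _trade_name(declared_idx)
        declared_species = species_names[declared_idx]
        product = ProductRecord(
            sample_code=code,
            region=rng.choice(REGIONS),
            retail_type=rng.choice(RETAIL_TYPES),
            menu_label=label,
            declared_taxa=(TaxonConstraint("species", declared_species),),
            category=rng.choice(CATEGORIES),
            processed_replicates=config.replicates_per_product,
        )
        products.append(product)
        truth.products[code] = {
            "true_species": species_names[true_idx],
            "declared_label": label,
            "declared_species": declared_species,
            "intended_verdict": "misdescribed" if mislabeled else "compliant",
        }
        source = panel.records[true_idx].sequence
        for rep in range(1, config.replicates_per_product + 1):
            read_id = f"{code}|{rep}"
            mut_seed = rng.randrange(2**31)
            sequence = mutate_to_identity(
                source, config.query_identity, seed=mut_seed, preserve_frame=True
            )
            is_decoy = rng.random() < config.numt_fraction
            decoy_mode = None
            if is_decoy:
                decoy_mode = next(decoy_cycle)
                sequence = make_numt_decoy(sequence, seed=rng.randrange(2**31), mode=decoy_mode)
            reads.append(BarcodeRead(read_id, sequence, code, rep))
            truth.reads[read_id] = {
                "source_species": species_names[true_idx],
                "n_mutations": int(round(len(source) * (1 - config.query_identity))),
                "is_decoy": is_decoy,
                "decoy_mode": decoy_mode,
            }
    truth.mislabel_rate_realized = (
        n_mislabels / config.n_products if config.n_products else 0.0
    )
    dataset = SurveyDataset(
        reads=reads, products=products, rules=rules, panel=panel, ground_truth=truth
    )
    if outdir is not None:
        _write_survey(dataset, Path(outdir))
    return dataset


def _write_survey(dataset: SurveyDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.reads, outdir / "reads.fasta")
    with open(outdir / "panel.fasta", "w") as fh:
        for rec in dataset.panel.records:
            fh.write(f">{rec.accession}\n{rec.sequence}\n")
    with open(outdir / "taxonomy.tsv", "w") as fh:
        fh.write("accession\tspecies\tgenus\tfamily\n")
        for rec in dataset.panel.records:
            fh.write(f"{rec.accession}\t{rec.species}\t{rec.genus}\t{rec.family}\n")
    with open(outdir / "products.tsv", "w") as fh:
        fh.write(
            "sample_code\tregion\tretail_type\tmenu_label\tdeclared_species\t"
            "category\tprocessed_replicates\n"
        )
        for p in dataset.products:
            declared = "/".join(
                c.taxon if c.rank == "species" else f"{c.taxon} sp"
                for c in p.declared_taxa
            )
            fh.write(
                f"{p.sample_code}\t{p.region}\t{p.retail_type}\t{p.menu_label}\t"
                f"{declared}\t{p.category}\t{p.processed_replicates}\n"
            )
    rows = [
        {
            "trade_name": rule.trade_name,
            "rank": c.rank,
            "taxon": c.taxon,
            "listed": rule.listed,
            "source": rule.source,
        }
        for rule in dataset.rules.values()
        for c in rule.allowed_taxa
    ]
    (outdir / "rules.yaml").write_text(yaml.safe_dump(rows, sort_keys=False))
    (outdir / "ground_truth.json").write_text(
        json.dumps(asdict(dataset.ground_truth), indent=2) + "\n"
    )
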