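"""End-to-end authentication: QC -> assignment -> consensus -> compliance."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .name_compliance import ComplianceCall, ProductRecord, RuleSet, call_compliance
from .seq_qc import BarcodeRead, QCConfig, QCResult, run_qc
from .species_assignment import (
    AlignmentScoring,
    ReadAssignment,
    ReferencePanel,
    SpeciesCall,
    assign_reads,
    consensus_by_product,
)


@dataclass
class PipelineResult:
    qc: list[tuple[BarcodeRead, QCResult]]
    read_calls: list[ReadAssignment]
    product_calls: dict[str, SpeciesCall]
    verdicts: list[ComplianceCall]

    @property
    def n_qc_failed(self) -> int:
        return sum(1 for _, r in self.qc if not r.passed)


def authenticate(
    reads: Sequence[BarcodeRead],
    panel: ReferencePanel,
    products: Sequence[ProductRecord],
    rules: RuleSet | None = None,
    qc_config: QCConfig | None = None,
    min_identity_pct: float = 97.0,
    tie_tolerance: float = 0.0,
    scoring: AlignmentScoring | None = None,
) -> PipelineResult:
    """Run the full authentication pipeline over a batch of products.

    Reads failing QC (NUMT-flagged, too long, too ambiguous) never reach
    assignment; a product none of whose reads survive gets an unassigned
    consensus and hence an unresolved compliance verdict, excluding it from
    survey denominators.
    """
    qc_config = qc_config or QCConfig()
    qc = run_qc(reads, qc_config)
    passed = [read for read, result in qc if result.passed]
    read_calls = assign_reads(passed, panel, min_identity_pct, tie_tolerance, scoring)
    product_calls = consensus_by_product(read_calls)
    verdicts = []
    for product in products:
        call = product_calls.get(product.sample_code)
        if call is None:
            call = SpeciesCall(
                sample_code=product.sample_code,
                status="unassigned",
                species=None,
                best_identity_pct=None,
                tied_species=(),
                replicate_calls=[],
            )
            product_calls[product.sample_code] = call
        verdicts.append(call_compliance(product, call, rules=rules, taxonomy=panel))
    return PipelineResult(
        qc=qc, read_calls=read_calls, product_calls=product_calls, verdicts=verdicts
    )
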