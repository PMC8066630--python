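"""Species assignment by top percent identity against a local reference panel.

Replaces a live BLAST/BOLD search with optimal global (end-to-end) pairwise
alignment of each query amplicon against a curated, taxonomy-annotated COI
reference panel.  Queries and references are near-full-length amplicons of
similar length, so end-to-end alignment with 100% query coverage is the
natural criterion.  Assignment is the classic top-hit rule: keep the hit(s)
with the highest percent identity; if several tie, the call stands only when
all tied hits belong to one species, otherwise the read is flagged ambiguous.

The assignment step is exposed both as plain functions (:func:`rank_hits`,
:func:`call_species_for_read`) and as a scikit-learn style estimator,
:class:`PanelIdentityClassifier`, which behaves as a 1-nearest-neighbour
classifier under alignment percent identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from sklearn.base import BaseEstimator, ClassifierMixin

try:
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

from .seq_qc import VALID_BASES

logger = logging.getLogger(__name__)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed-table precision."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AlignmentScoring:
    """Match/mismatch/gap scores for global alignment (linear gap penalty).

    Near-identical COI sequences are insensitive to this choice; the defaults
    are a plain +1/-1/-2 scheme.  N scores 0 against everything and counts as
    neither match nor mismatch, but occupies an alignment column.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class ReferenceRecord:
    accession: str
    species: str
    genus: str
    family: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.species.split()) < 2:
            raise ValueError(
                f"{self.accession}: species {self.species!r} is not a binomial"
            )


@dataclass
class ReferencePanel:
    """Taxonomy-annotated COI reference sequences with a species index."""

    records: list[ReferenceRecord]
    species_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        accessions = [r.accession for r in self.records]
        if len(set(accessions)) != len(accessions):
            dupes = sorted({a for a in accessions if accessions.count(a) > 1})
            raise ValueError(f"duplicate accessions in panel: {dupes}")
        if not self.species_index:
            self.species_index = {}
            for rec in self.records:
                self.species_index.setdefault(rec.species, []).append(rec.accession)
        self._by_accession = {r.accession: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.species_index)

    def record(self, accession: str) -> ReferenceRecord:
        return self._by_accession[accession]

    def family_of(self, species: str) -> str:
        accs = self.species_index.get(species)
        if not accs:
            raise KeyError(f"species {species!r} not in panel taxonomy")
        return self._by_accession[accs[0]].family


@dataclass(frozen=True)
class PairwiseIdentity:
    """Identity statistics of one optimal global alignment."""

    matches: int
    aligned_columns: int
    identity_pct: float  # rounded half-up to 2 decimals
    coverage_pct: float
    score: float


@dataclass(frozen=True)
class AssignmentHit:
    accession: str
    species: str
    identity_pct: float
    coverage_pct: float
    aligned_columns: int
    matches: int


@dataclass(frozen=True)
class ReadAssignment:
    """Per-read species call (one replicate of one product)."""

    sample_code: str
    replicate_index: int
    status: str  # assigned | ambiguous | unassigned
    species: Optional[str]
    best_identity_pct: Optional[float]
    tied_species: tuple[str, ...] = ()


@dataclass
class SpeciesCall:
    """Per-product consensus across up to three replicate extractions."""

    sample_code: str
    status: str  # assigned | ambiguous | unassigned | multi_species
    species: Optional[str]
    best_identity_pct: Optional[float]
    tied_species: tuple[str, ...]
    replicate_calls: list[ReadAssignment]


def build_panel(fasta: str | Path, taxonomy: str | Path) -> ReferencePanel:
    """Load a reference panel from a FASTA file plus a taxonomy table.

    The taxonomy table is TSV with columns ``accession``, ``species``,
    ``genus``, ``family``; every FASTA accession must appear in it.
    """
    tax = pd.read_csv(taxonomy, sep="\t", dtype=str)
    required = {"accession", "species", "genus", "family"}
    missing = required - set(tax.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    if tax["accession"].duplicated().any():
        dupes = tax.loc[tax["accession"].duplicated(), "accession"].tolist()
        raise ValueError(f"duplicate accessions in taxonomy: {dupes}")
    tax_by_acc = tax.set_index("accession")
    records = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        acc = rec.id
        if acc not in tax_by_acc.index:
            raise ValueError(f"FASTA accession {acc!r} absent from taxonomy table")
        row = tax_by_acc.loc[acc]
        if len(rec.seq) < 400:
            logger.warning(
                "reference %s is only %d nt; barcode references are expected "
                "to be near-full-length (>= 400 nt)", acc, len(rec.seq),
            )
        records.append(
            ReferenceRecord(
                accession=acc,
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                sequence=str(rec.seq).upper().replace("U", "T"),
            )
        )
    panel = ReferencePanel(records=records)
    logger.info("reference panel: %d records, %d species", len(panel), len(panel.species))
    return panel


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            matrix[a, b] = scoring.match if a == b else scoring.mismatch
    # N is ambiguity, not evidence: contributes nothing to the score
    for a in "ACGTN":
        matrix["N", a] = 0.0
        matrix[a, "N"] = 0.0
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _validate_nt(name: str, sequence: str) -> None:
    bad = set(sequence) - VALID_BASES
    if bad:
        raise ValueError(f"{name} contains non-IUPAC symbols: {sorted(bad)}")


def global_identity(
    query: str,
    reference: str,
    scoring: AlignmentScoring | None = None,
) -> PairwiseIdentity:
    """Percent identity of the optimal global alignment of two sequences.

    identity_pct = 100 x matches / aligned_columns, where aligned_columns
    counts every column of the end-to-end alignment including gap columns.
    Columns involving N count in the denominator but never as matches.
    Coverage is 100% by construction for global alignment.
    """
    if not query or not reference:
        raise ValueError("global_identity requires two non-empty sequences")
    _validate_nt("query", query)
    _validate_nt("reference", reference)
    scoring = scoring or AlignmentScoring()
    aligner = _make_aligner(scoring)
    # canonical argument order: among co-optimal alignments the traceback
    # choice depends on which sequence comes first, so identity of the picked
    # alignment would not be symmetric; the scoring scheme is symmetric, so
    # ordering the inputs fixes one deterministic, symmetric answer
    first, second = (query, reference) if query <= reference else (reference, query)
    alignment = aligner.align(first, second)[0]
    gapped_q, gapped_r = str(alignment[0]), str(alignment[1])
    matches = sum(
        1
        for a, b in zip(gapped_q, gapped_r)
        if a == b and a not in ("-", "N")
    )
    columns = len(gapped_q)
    identity = round_half_up(100.0 * matches / columns, 2)
    return PairwiseIdentity(
        matches=matches,
        aligned_columns=columns,
        identity_pct=identity,
        coverage_pct=100.0,
        score=float(alignment.score),
    )


def _identity_upper_bound(query: str, reference: str) -> float:
    """Cheap provable upper bound on global-alignment percent identity.

    For any alignment, mismatch + gap columns >= the Levenshtein distance d,
    and aligned_columns <= len(q) + len(r), so
    identity <= 100 * (len(q) + len(r) - d) / (len(q) + len(r)).
    Used only to skip references that cannot reach the identity threshold.
    """
    d = edlib.align(query, reference, mode="NW")["editDistance"]
    total = len(query) + len(reference)
    return 100.0 * (total - d) / total


def rank_hits(
    query: str,
    panel: ReferencePanel,
    min_identity_pct: float = 97.0,
    scoring: AlignmentScoring | None = None,
) -> list[AssignmentHit]:
    """All panel hits at or above the identity threshold, best first.

    Sorted by identity (2-decimal reporting precision) descending, ties kept
    adjacent with deterministic secondary order by accession.
    """
    scoring = scoring or AlignmentScoring()
    hits = []
    for rec in panel.records:
        if _HAVE_EDLIB and min_identity_pct > 0:
            # safe prune: skip references provably below threshold
            if _identity_upper_bound(query, rec.sequence) < min_identity_pct - 0.005:
                continue
        stats = global_identity(query, rec.sequence, scoring)
        if stats.identity_pct >= min_identity_pct:
            hits.append(
                AssignmentHit(
                    accession=rec.accession,
                    species=rec.species,
                    identity_pct=stats.identity_pct,
                    coverage_pct=stats.coverage_pct,
                    aligned_columns=stats.aligned_columns,
                    matches=stats.matches,
                )
            )
    hits.sort(key=lambda h: (-h.identity_pct, h.accession))
    return hits


def call_species_for_read(
    hits: Sequence[AssignmentHit],
    tie_tolerance: float = 0.0,
    sample_code: str = "",
    replicate_index: int = 1,
) -> ReadAssignment:
    """Apply the top-hit tie rule to a ranked hit list.

    Hits within ``tie_tolerance`` identity points of the best hit are the tied
    set; a call is made only when they all name one species.
    """
    if not hits:
        return ReadAssignment(sample_code, replicate_index, "unassigned", None, None)
    best = hits[0].identity_pct
    tied = [h for h in hits if h.identity_pct >= best - tie_tolerance]
    tied_species = tuple(sorted({h.species for h in tied}))
    if len(tied_species) == 1:
        return ReadAssignment(
            sample_code, replicate_index, "assigned", tied_species[0], best, tied_species
        )
    return ReadAssignment(
        sample_code, replicate_index, "ambiguous", None, best, tied_species
    )


def consensus_product_call(replicate_calls: Sequence[ReadAssignment]) -> SpeciesCall:
    """Combine 1-3 replicate read calls for one product into a consensus.

    Unanimous assigned replicates give an assigned product; replicates naming
    different species flag a multi-species product; ambiguous replicates are
    recorded but do not overrule an otherwise unanimous species.
    """
    if not replicate_calls:
        raise ValueError("consensus_product_call requires at least one replicate call")
    codes = {c.sample_code for c in replicate_calls}
    if len(codes) != 1:
        raise ValueError(f"replicate calls span multiple sample codes: {sorted(codes)}")
    code = codes.pop()
    assigned = [c for c in replicate_calls if c.status == "assigned"]
    species_seen = sorted({c.species for c in assigned})
    tied = tuple(
        sorted({s for c in replicate_calls for s in c.tied_species})
    )
    if len(species_seen) >= 2:
        return SpeciesCall(code, "multi_species", None, None, tied, list(replicate_calls))
    if len(species_seen) == 1:
        best = max(c.best_identity_pct for c in assigned)
        return SpeciesCall(
            code, "assigned", species_seen[0], best, (species_seen[0],), list(replicate_calls)
        )
    if any(c.status == "ambiguous" for c in replicate_calls):
        return SpeciesCall(code, "ambiguous", None, None, tied, list(replicate_calls))
    return SpeciesCall(code, "unassigned", None, None, (), list(replicate_calls))


class PanelIdentityClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-reference species classifier under global-alignment identity.

    ``fit`` takes reference sequences ``X`` and species labels ``y`` (or a
    prebuilt :class:`ReferencePanel` as ``X``); ``predict`` assigns each query
    to the species of its top-identity reference, applying the tie rule.
    Queries with no hit at ``min_identity_pct`` predict ``"unassigned"``;
    cross-species ties predict ``"ambiguous"``.

    Parameters
    ----------
    min_identity_pct : float
        Identity threshold below which a query is unassigned.
    tie_tolerance : float
        Identity margin (percentage points, on 2-decimal identities) within
        which top hits are considered tied.
    match_score, mismatch_score, gap_score : float
        Alignment scoring (linear gap penalty).
    """

    def __init__(
        self,
        min_identity_pct: float = 97.0,
        tie_tolerance: float = 0.0,
        match_score: float = 1.0,
        mismatch_score: float = -1.0,
        gap_score: float = -2.0,
    ):
        self.min_identity_pct = min_identity_pct
        self.tie_tolerance = tie_tolerance
        self.match_score = match_score
        self.mismatch_score = mismatch_score
        self.gap_score = gap_score

    def _scoring(self) -> AlignmentScoring:
        return AlignmentScoring(
            match=self.match_score,
            mismatch=self.mismatch_score,
            gap_open=self.gap_score,
            gap_extend=self.gap_score,
        )

    def fit(self, X, y=None):
        """Build the reference panel from sequences X and species labels y."""
        if isinstance(X, ReferencePanel):
            self.panel_ = X
        else:
            X = list(X)
            if y is None or len(y) != len(X):
                raise ValueError("y (species labels) must match X in length")
            records = [
                ReferenceRecord(
                    accession=f"REF{i:05d}",
                    species=sp,
                    genus=sp.split()[0],
                    family="",
                    sequence=seq,
                )
                for i, (seq, sp) in enumerate(zip(X, y))
            ]
            self.panel_ = ReferencePanel(records=records)
        self.classes_ = np.array(self.panel_.species)
        self.n_features_in_ = 1
        return self

    def predict_detail(self, X) -> list[ReadAssignment]:
        """Full per-query call objects (status, species, identity, ties)."""
        if not hasattr(self, "panel_"):
            raise ValueError("classifier is not fitted; call fit first")
        scoring = self._scoring()
        calls = []
        for i, query in enumerate(X):
            hits = rank_hits(query, self.panel_, self.min_identity_pct, scoring)
            calls.append(
                call_species_for_read(hits, self.tie_tolerance, sample_code=str(i))
            )
        return calls

    def predict(self, X) -> np.ndarray:
        """Species label per query; 'unassigned'/'ambiguous' where no call stands."""
        return np.array(
            [c.species if c.status == "assigned" else c.status for c in self.predict_detail(X)],
            dtype=object,
        )


def assign_reads(
    reads: Iterable,
    panel: ReferencePanel,
    min_identity_pct: float = 97.0,
    tie_tolerance: float = 0.0,
    scoring: AlignmentScoring | None = None,
) -> list[ReadAssignment]:
    """Assign a batch of QC-passed BarcodeReads; thin wrapper over rank/call."""
    out = []
    for read in reads:
        hits = rank_hits(read.sequence, panel, min_identity_pct, scoring)
        out.append(
            call_species_for_read(
                hits,
                tie_tolerance,
                sample_code=read.sample_code,
                replicate_index=read.replicate_index,
            )
        )
    return out


def consensus_by_product(read_calls: Sequence[ReadAssignment]) -> dict[str, SpeciesCall]:
    """Group read calls by sample code and form per-product consensus calls."""
    grouped: dict[str, list[ReadAssignment]] = {}
    for call in read_calls:
        grouped.setdefault(call.sample_code, []).append(call)
    return {code: consensus_product_call(calls) for code, calls in sorted(grouped.items())}
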