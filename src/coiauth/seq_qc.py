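"""Amplicon quality control for COI barcodes.

Sanger-length COI amplicons (~650 nt) are ingested from FASTA, primer-trimmed,
translated in all six frame/strand combinations under the vertebrate
mitochondrial genetic code, and screened for nuclear mitochondrial pseudogenes
(NUMTs).  A genuine mitochondrial COI fragment is protein-coding and stop-free
in one reading frame; NUMTs betray themselves through premature stop codons,
frameshifts, or short length (vertebrate NUMTs are generally < 600 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: NCBI translation table ids accepted by :func:`translate`.
SUPPORTED_CODES = (1, 2)

STOP_SYMBOL = "*"


class FastaFormatError(ValueError):
    """Raised when a FASTA file or record violates the input contract."""


@dataclass(frozen=True)
class BarcodeRead:
    """One amplicon sequence with its provenance.

    ``read_id`` encodes ``sampleCode|replicateIndex`` per the documented FASTA
    header convention; ``replicate_index`` is 1..3 (each product was extracted
    up to three times to detect species mixtures).
    """

    read_id: str
    sequence: str
    sample_code: str
    replicate_index: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FastaFormatError(
                f"read {self.read_id!r}: non-ACGTN characters {sorted(bad)}"
            )
        if self.replicate_index not in (1, 2, 3):
            raise ValueError(
                f"read {self.read_id!r}: replicate_index must be 1..3, "
                f"got {self.replicate_index}"
            )


@dataclass(frozen=True)
class QCConfig:
    """Quality-control thresholds.

    Primers are a configuration item with no default: the survey's primer pair
    is not part of the packaged data, and trimming is skipped when unset.
    Length thresholds separate the hard NUMT-size filter (< 600 nt) from the
    merely-unusual window (outside 636-655 nt observed for clean amplicons,
    logged as a warning).
    """

    primer_forward: str = ""
    primer_reverse: str = ""
    max_primer_mismatch: int = 0
    genetic_code_id: int = 2  # vertebrate mitochondrial
    min_length_nt: int = 600
    max_length_nt: int = 700
    expected_window: tuple[int, int] = (636, 655)
    max_n_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.min_length_nt >= self.max_length_nt:
            raise ValueError("min_length_nt must be < max_length_nt")
        lo, hi = self.expected_window
        if not (self.min_length_nt <= lo <= hi <= self.max_length_nt):
            logger.warning(
                "expected_window %s not nested in [%d, %d]",
                self.expected_window, self.min_length_nt, self.max_length_nt,
            )


@dataclass
class QCResult:
    read_id: str
    trimmed_sequence: str
    strand: str  # "forward" | "reverse"
    frame_offset: int  # 0..2, leading bases skipped
    internal_stop_count: int
    length_nt: int
    numt_flag: bool
    fail_reason: Optional[str] = None  # stops_in_all_frames | too_short | too_long | ambiguous_bases

    @property
    def passed(self) -> bool:
        return self.fail_reason is None


def _parse_header(header: str) -> tuple[str, int]:
    """Split ``sampleCode|replicateIndex`` headers; bare ids map to replicate 1."""
    token = header.split()[0]
    if "|" in token:
        code, _, rep = token.partition("|")
        try:
            return code, int(rep)
        except ValueError as exc:
            raise FastaFormatError(
                f"record {header!r}: replicate index {rep!r} is not an integer"
            ) from exc
    return token, 1


def read_fasta(path: str | Path) -> list[BarcodeRead]:
    """Read amplicons from a FASTA file into :class:`BarcodeRead` records.

    Sequences are upper-cased and RNA ``U`` converted to ``T``; any other
    non-ACGTN character is a record-level error naming the offending id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text_head = path.read_text()[:1].strip()
    if text_head and text_head != ">":
        raise FastaFormatError(f"{path}: not FASTA (first line does not start with '>')")
    reads: list[BarcodeRead] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        sample_code, replicate = _parse_header(record.id)
        reads.append(
            BarcodeRead(
                read_id=record.id,
                sequence=seq,
                sample_code=sample_code,
                replicate_index=replicate,
            )
        )
    return reads


def write_fasta(reads: Iterable[BarcodeRead], path: str | Path) -> None:
    """Write reads back out, one wrapped FASTA record per read."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n")
            for i in range(0, len(read.sequence), 70):
                fh.write(read.sequence[i : i + 70] + "\n")


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def _mismatches_at(sequence: str, primer: str, offset: int) -> int:
    window = sequence[offset : offset + len(primer)]
    return sum(1 for a, b in zip(window, primer) if a != b and a != "N")


def _find_primer(sequence: str, primer: str, max_mismatch: int) -> Optional[int]:
    """Leftmost offset where ``primer`` matches within ``max_mismatch`` substitutions."""
    for offset in range(len(sequence) - len(primer) + 1):
        if _mismatches_at(sequence, primer, offset) <= max_mismatch:
            return offset
    return None


def trim_primers(read: BarcodeRead, config: QCConfig) -> BarcodeRead:
    """Remove primer sequences (and anything upstream/downstream of them).

    The forward primer is sought at the 5' end on either strand; when it is
    found on the reverse strand the read is reverse-complemented first, so the
    returned read is forward-oriented.  The reverse primer is removed at the
    3' end as its reverse complement.  With no configured primers, or no
    occurrence, the read is returned unchanged.
    """
    if not config.primer_forward and not config.primer_reverse:
        return read
    seq = read.sequence
    if config.primer_forward:
        offset = _find_primer(seq, config.primer_forward, config.max_primer_mismatch)
        if offset is None:
            rc = reverse_complement(seq)
            rc_offset = _find_primer(rc, config.primer_forward, config.max_primer_mismatch)
            if rc_offset is not None:
                seq = rc
                offset = rc_offset
        if offset is not None:
            seq = seq[offset + len(config.primer_forward):]
        else:
            logger.info("read %s: forward primer not found; left untrimmed", read.read_id)
    if config.primer_reverse:
        probe = reverse_complement(config.primer_reverse)
        # rightmost occurrence: scan from the right
        hit = None
        for offset in range(len(seq) - len(probe), -1, -1):
            if _mismatches_at(seq, probe, offset) <= config.max_primer_mismatch:
                hit = offset
                break
        if hit is not None:
            seq = seq[:hit]
        else:
            logger.info("read %s: reverse primer not found; right end untrimmed", read.read_id)
    if len(seq) < 50:
        raise ValueError(
            f"read {read.read_id!r}: primer trimming left {len(seq)} nt (< 50); "
            "sequence effectively destroyed"
        )
    return BarcodeRead(
        read_id=read.read_id,
        sequence=seq,
        sample_code=read.sample_code,
        replicate_index=read.replicate_index,
    )


def translate(
    sequence: str,
    frame_offset: int = 0,
    strand: str = "forward",
    genetic_code_id: int = 2,
) -> str:
    """Translate a nucleotide sequence in one frame/strand combination.

    ``genetic_code_id`` is an NCBI translation table id (1 = standard,
    2 = vertebrate mitochondrial, in which AGA/AGG are stops, ATA is Met and
    TGA is Trp).  Stops render as ``*``; codons containing N render as ``X``
    unless the table resolves them unambiguously.  The trailing incomplete
    codon is dropped.
    """
    if genetic_code_id not in SUPPORTED_CODES:
        raise ValueError(
            f"unsupported genetic_code_id {genetic_code_id}; supported: {SUPPORTED_CODES}"
        )
    if strand not in ("forward", "reverse"):
        raise ValueError(f"strand must be 'forward' or 'reverse', got {strand!r}")
    if not 0 <= frame_offset <= 2:
        raise ValueError(f"frame_offset must be 0..2, got {frame_offset}")
    seq = sequence if strand == "forward" else reverse_complement(sequence)
    seq = seq[frame_offset:]
    seq = seq[: len(seq) - len(seq) % 3]
    if not seq:
        return ""
    return str(Seq(seq).translate(table=genetic_code_id))


def _internal_stops(protein: str) -> int:
    """Stops anywhere but the final codon position (a trailing stop is not internal)."""
    if not protein:
        return 0
    return protein[:-1].count(STOP_SYMBOL)


def six_frame_stop_counts(
    sequence: str, genetic_code_id: int = 2
) -> list[tuple[str, int, int]]:
    """Internal-stop counts for all six (strand, frame) combinations.

    Returned in deterministic tie-break order: forward before reverse,
    frame 0 before 1 before 2.
    """
    combos = []
    for strand in ("forward", "reverse"):
        for frame in (0, 1, 2):
            protein = translate(sequence, frame, strand, genetic_code_id)
            combos.append((strand, frame, _internal_stops(protein)))
    return combos


def screen_numt(read: BarcodeRead, config: QCConfig | None = None) -> QCResult:
    """Screen a primer-trimmed read for NUMT signatures.

    All six frame/strand translations are computed; the combination with the
    fewest internal stops wins (forward strand first, then lowest frame).
    The read is NUMT-flagged when even the best frame retains a stop, or when
    it is shorter than the NUMT-size heuristic (600 nt).  Over-long reads and
    excessive ambiguity fail QC without the NUMT flag.
    """
    config = config or QCConfig()
    combos = six_frame_stop_counts(read.sequence, config.genetic_code_id)
    strand, frame, stops = min(combos, key=lambda c: c[2])
    length = len(read.sequence)

    numt_flag = False
    fail_reason: Optional[str] = None
    if length < config.min_length_nt:
        numt_flag, fail_reason = True, "too_short"
    elif stops >= 1:
        numt_flag, fail_reason = True, "stops_in_all_frames"
    elif length > config.max_length_nt:
        fail_reason = "too_long"
    elif read.sequence.count("N") > config.max_n_fraction * length:
        fail_reason = "ambiguous_bases"
    else:
        lo, hi = config.expected_window
        if not lo <= length <= hi:
            logger.warning(
                "read %s: length %d nt outside expected window [%d, %d]",
                read.read_id, length, lo, hi,
            )
    return QCResult(
        read_id=read.read_id,
        trimmed_sequence=read.sequence,
        strand=strand,
        frame_offset=frame,
        internal_stop_count=stops,
        length_nt=length,
        numt_flag=numt_flag,
        fail_reason=fail_reason,
    )


def run_qc(
    reads: Iterable[BarcodeRead], config: QCConfig | None = None
) -> list[tuple[BarcodeRead, QCResult]]:
    """Trim and screen a batch of reads; returns (trimmed read, result) pairs."""
    config = config or QCConfig()
    out = []
    for read in reads:
        trimmed = trim_primers(read, config)
        out.append((trimmed, screen_numt(trimmed, config)))
    return out


def vertebrate_mito_stops() -> frozenset[str]:
    """Stop codons of NCBI translation table 2 (TAA, TAG, AGA, AGG)."""
    return frozenset(CodonTable.unambiguous_dna_by_id[2].stop_codons)
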