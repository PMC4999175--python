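"""Six-frame ORF discovery and translation.

An ORF runs from an ATG to the next in-frame stop codon (complete), or to the
end of the sequence (3'-truncated), and the frame-initial segment that reaches
a stop without beginning at an ATG is reported as a 5'-truncated ORF.  A
"complete" ORF has both a start and a stop; that is the sense in which some
transcriptome unigenes (e.g. ones truncated by assembly) lack complete ORFs.

Coordinates are 0-based half-open on the forward strand regardless of the
ORF's strand; conversion to 1-based display happens only in reports.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import NoOrfError, ValidationError
from .seq_io import Transcript

__all__ = [
    "OrfRecord",
    "ProteinRecord",
    "reverse_complement",
    "translate",
    "find_orfs",
    "longest_orf_protein",
]

_STANDARD = unambiguous_dna_by_id[1]
_CODON_TABLE = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:  # TAA, TAG, TGA
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MIN_AA = 80  # smallest deposited precursor is 112 aa; 80 leaves margin


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt_seq: str, offset: int = 0) -> str:
    """Translate successive codons from ``offset`` with the standard code.

    Stop codons render as ``*``; any codon containing ``N`` renders as ``X``;
    a trailing partial codon is dropped.
    """
    if offset not in (0, 1, 2):
        raise ValidationError(f"offset must be 0, 1 or 2, got {offset}")
    bad = set(nt_seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"non-nucleotide characters {sorted(bad)}")
    aa = []
    for i in range(offset, len(nt_seq) - 2, 3):
        codon = nt_seq[i : i + 3]
        aa.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(aa)


@dataclass(frozen=True)
class OrfRecord:
    """One open reading frame located on a transcript.

    ``nt_start``/``nt_end`` are forward-strand 0-based half-open coordinates
    covering whole codons only (the stop codon included when present).
    """

    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2 on the reading strand
    nt_start: int
    nt_end: int
    has_start: bool
    has_stop: bool
    aa_seq: str

    def __post_init__(self) -> None:
        if (self.nt_end - self.nt_start) % 3 != 0:
            raise ValidationError("ORF span must cover whole codons")
        if "*" in self.aa_seq:
            raise ValidationError("aa_seq must not contain stop symbols")

    @property
    def is_complete(self) -> bool:
        return self.has_start and self.has_stop

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


@dataclass(frozen=True)
class ProteinRecord:
    """The representative translated protein of one transcript."""

    id: str
    aa_seq: str
    orf: OrfRecord

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


def _orfs_on_reading_strand(seq: str, transcript_id: str, strand: str, min_aa: int):
    """Enumerate ORFs in all 3 frames of one reading-strand sequence.

    Yields tuples (frame, start, end, has_start, has_stop, aa) with
    coordinates on the *reading* strand; the caller maps minus-strand
    coordinates back to the forward strand.
    """
    n = len(seq)
    for frame in range(3):
        aa_frame = translate(seq, frame)
        # codon index k covers reading-strand [frame+3k, frame+3k+3)
        stops = [k for k, a in enumerate(aa_frame) if a == "*"]
        starts = [
            k
            for k in range(len(aa_frame))
            if seq[frame + 3 * k : frame + 3 * k + 3] == "ATG"
        ]
        for s in starts:
            j = bisect.bisect_left(stops, s)
            if j < len(stops):
                k_stop = stops[j]
                aa = aa_frame[s:k_stop]
                if len(aa) >= min_aa:
                    yield (frame, frame + 3 * s, frame + 3 * (k_stop + 1), True, True, aa)
            else:
                aa = aa_frame[s:]
                if len(aa) >= min_aa:
                    yield (frame, frame + 3 * s, frame + 3 * len(aa_frame), True, False, aa)
        # 5'-truncated: frame-initial segment reaching a stop without an ATG start
        if stops:
            k_stop = stops[0]
            begins_with_atg = seq[frame : frame + 3] == "ATG"
            if not begins_with_atg and k_stop >= 1:
                aa = aa_frame[:k_stop]
                if len(aa) >= min_aa:
                    yield (frame, frame, frame + 3 * (k_stop + 1), False, True, aa)


def find_orfs(transcript: Transcript, min_aa: int = DEFAULT_MIN_AA) -> list[OrfRecord]:
    """All ORFs of length >= ``min_aa`` on both strands and all three frames.

    Every ATG opens its own ORF (nested ORFs sharing a stop are all reported);
    the pipeline's tie-break in :func:`longest_orf_protein` selects among them.
    """
    if min_aa < 1:
        raise ValidationError("min_aa must be >= 1")
    n = len(transcript.seq)
    records: list[OrfRecord] = []
    for strand in "+-":
        seq = transcript.seq if strand == "+" else reverse_complement(transcript.seq)
        for frame, start, end, has_start, has_stop, aa in _orfs_on_reading_strand(
            seq, transcript.id, strand, min_aa
        ):
            if strand == "+":
                nt_start, nt_end = start, end
            else:
                nt_start, nt_end = n - end, n - start
            records.append(
                OrfRecord(
                    transcript_id=transcript.id,
                    strand=strand,
                    frame=frame,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    has_start=has_start,
                    has_stop=has_stop,
                    aa_seq=aa,
                )
            )
    records.sort(key=lambda o: (o.strand, o.frame, o.nt_start))
    return records


def longest_orf_protein(transcript: Transcript, min_aa: int = DEFAULT_MIN_AA) -> ProteinRecord:
    """The transcript's representative protein: its longest qualifying ORF.

    Ties break complete-before-incomplete, then '+' strand before '-', then
    smallest forward-strand start.
    """
    orfs = find_orfs(transcript, min_aa)
    if not orfs:
        raise NoOrfError(
            f"transcript {transcript.id!r}: no ORF of >= {min_aa} aa"
        )
    best = min(
        orfs,
        key=lambda o: (-o.length_aa, not o.is_complete, o.strand != "+", o.nt_start),
    )
    return ProteinRecord(id=transcript.id, aa_seq=best.aa_seq, orf=best)
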