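"""Synthetic stand-ins for the deposited SaveOBP/SaveCSP records.

The 18 deposited sequences (GenBank KU140605–KU140622) are not bundled with
the package; ``scripts/fetch_accessions.py`` retrieves them where a network
is available.  This module instead constructs SYNTHETIC stand-in transcripts
that reproduce the documented structure of each record:

* the precursor length in amino acids (e.g. SaveOBP1 152 aa, SaveCSP5 231 aa);
* ORF completeness (SaveOBP13 and SaveCSP1 are 5'-truncated, all others have
  a start and an in-frame stop);
* cysteine-spacing class: nine OBPs carry the classic hemipteran six-cysteine
  motif, SaveOBP1 has 47 residues between its third and fourth cysteines,
  SaveOBP4 has 49 between its first and second and 21 between its fourth and
  fifth (so neither fits the classic or the general spacing), SaveOBP5/6
  follow the Plus-C pattern, and all five CSPs fit the tight hemipteran CSP
  spacing.

These stand-ins exercise the ORF-finding and motif-scanning pipeline end to
end; they are not the deposited sequences and carry ``_synthetic`` ids to say
so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .motif_engine import builtin_motifs, scan_motif
from .orf_finder import longest_orf_protein
from .seq_io import Transcript
from .synthetic_data import _STOP_CODONS, plant_motif, reverse_translate

__all__ = ["STANDIN_TABLE", "standin_accession_set"]


@dataclass(frozen=True)
class _StandinRow:
    gene: str
    accession: str
    length_aa: int
    spec_name: str  # motif planted in the stand-in
    gap_vector: tuple[int, ...]
    lead_flank: int  # residues before the first anchor (after M when complete)
    complete: bool
    classic: bool  # expected classic-hemipteran motif membership


# Gap vectors sit inside the planted spec's ranges; the two deviant OBPs use
# the spacings reported for them (OBP1: C3–C4 = 47; OBP4: C1–C2 = 49 and
# C4–C5 = 21), planted via a widened private variant of the classic pattern.
STANDIN_TABLE: tuple[_StandinRow, ...] = (
    _StandinRow("SaveOBP1", "KU140605", 152, "OBP_DEVIANT", (25, 3, 47, 10, 8), 18, True, False),
    _StandinRow("SaveOBP2", "KU140606", 243, "OBP_CLASSIC", (30, 3, 44, 12, 8), 18, True, True),
    _StandinRow("SaveOBP3", "KU140607", 141, "OBP_CLASSIC", (24, 3, 38, 9, 8), 22, True, True),
    _StandinRow("SaveOBP4", "KU140608", 199, "OBP_DEVIANT", (49, 3, 40, 21, 8), 21, True, False),
    _StandinRow("SaveOBP5", "KU140609", 221, "OBP_PLUSC", (30, 3, 43, 25, 9, 8, 0, 10), 24, True, False),
    _StandinRow("SaveOBP6", "KU140610", 215, "OBP_PLUSC", (21, 3, 41, 20, 9, 8, 0, 9), 18, True, False),
    _StandinRow("SaveOBP7", "KU140611", 149, "OBP_CLASSIC", (23, 3, 39, 10, 8), 23, True, True),
    _StandinRow("SaveOBP8", "KU140612", 162, "OBP_CLASSIC", (28, 3, 42, 11, 8), 17, True, True),
    _StandinRow("SaveOBP9", "KU140613", 166, "OBP_CLASSIC", (25, 3, 40, 13, 8), 23, True, True),
    _StandinRow("SaveOBP10", "KU140614", 143, "OBP_CLASSIC", (22, 3, 37, 8, 8), 23, True, True),
    _StandinRow("SaveOBP13", "KU140615", 112, "OBP_CLASSIC", (22, 3, 36, 8, 8), 15, False, True),
    _StandinRow("SaveOBP14", "KU140616", 167, "OBP_CLASSIC", (31, 3, 45, 14, 8), 20, True, True),
    _StandinRow("SaveOBP15", "KU140617", 175, "OBP_CLASSIC", (26, 3, 43, 9, 8), 21, True, True),
    _StandinRow("SaveCSP1", "KU140618", 118, "CSP_RESULTS", (5, 18, 2), 20, False, False),
    _StandinRow("SaveCSP2", "KU140619", 147, "CSP_RESULTS", (6, 19, 2), 21, True, False),
    _StandinRow("SaveCSP3", "KU140620", 138, "CSP_RESULTS", (5, 19, 2), 18, True, False),
    _StandinRow("SaveCSP4", "KU140621", 157, "CSP_RESULTS", (6, 18, 2), 24, True, False),
    _StandinRow("SaveCSP5", "KU140622", 231, "CSP_RESULTS", (5, 18, 2), 15, True, False),
)

# The deviant OBPs are planted with this relaxed six-cysteine envelope so the
# reported spacings (49, 21, 47) are representable; it is a construction aid,
# not a biological class.
_DEVIANT_PATTERN = "C-x(15,60)-C-x(3)-C-x(21,60)-C-x(7,30)-C-x(8)-C"


def _plan_protein(row: _StandinRow, seed: int) -> str:
    from .motif_engine import parse_motif

    lib = builtin_motifs()
    spec = (
        parse_motif(_DEVIANT_PATTERN, name="OBP_DEVIANT")
        if row.spec_name == "OBP_DEVIANT"
        else lib[row.spec_name]
    )
    span = len(spec.anchors) + sum(row.gap_vector)
    m_prefix = 1 if row.complete else 0
    tail = row.length_aa - m_prefix - row.lead_flank - span
    if tail < spec.min_tail or tail < 0:
        raise ValidationError(f"stand-in plan for {row.gene} does not fit its length")
    planted, _ = plant_motif(spec, row.gap_vector, (row.lead_flank, tail), seed=seed)
    protein = ("M" + planted) if row.complete else planted
    if not row.complete and protein[0] == "M":
        protein = "Q" + protein[1:]  # a 5'-truncated record must not begin at ATG
    if len(protein) != row.length_aa:
        raise AssertionError(f"stand-in for {row.gene} has the wrong length")
    return protein


def standin_accession_set(seed: int = 0) -> tuple[list[Transcript], pd.DataFrame]:
    """Build the 18 synthetic stand-in transcripts and their metadata table.

    Returns (transcripts, table); the table holds gene, accession, stand-in
    transcript id, expected precursor length, completeness and expected
    classic-motif membership.  Each stand-in is verified during construction:
    the longest-ORF rule recovers exactly the planned protein, and its motif
    membership (classic / Plus-C / CSP) is re-measured with the scanner, not
    assumed.
    """
    lib = builtin_motifs()
    rng = np.random.default_rng(seed + 97)
    transcripts: list[Transcript] = []
    rows = []
    for k, row in enumerate(STANDIN_TABLE):
        protein = _plan_protein(row, seed=seed + 7 * k)
        tid = f"{row.accession}_synthetic"
        for _attempt in range(60):
            if row.complete:
                orf_nt = "ATG" + reverse_translate(protein[1:], rng)
                stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
                utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(25, 80))))
                utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(25, 80))))
                nt = utr5 + orf_nt + stop + utr3
            else:
                # 5'-truncated: the reading frame starts at base 0, no ATG start
                orf_nt = reverse_translate(protein, rng)
                stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
                utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(25, 80))))
                nt = orf_nt + stop + utr3
            tr = Transcript(id=tid, seq=nt)
            rec = None
            try:
                rec = longest_orf_protein(tr, min_aa=80)
            except Exception:
                pass
            if rec is not None and rec.aa_seq == protein and rec.orf.is_complete == row.complete:
                break
        else:
            raise RuntimeError(f"could not embed stand-in ORF for {row.gene}")
        # construction-time sanity: membership measured, not asserted
        classic_hit = bool(scan_motif(protein, lib["OBP_CLASSIC"]))
        if classic_hit != row.classic:
            raise AssertionError(
                f"stand-in for {row.gene}: classic-motif membership "
                f"{classic_hit} != planned {row.classic}"
            )
        if row.spec_name == "OBP_PLUSC" and not scan_motif(protein, lib["OBP_PLUSC"]):
            raise AssertionError(f"stand-in for {row.gene} lost its Plus-C motif")
        if row.spec_name == "CSP_RESULTS" and not scan_motif(protein, lib["CSP_RESULTS"]):
            raise AssertionError(f"stand-in for {row.gene} lost its CSP motif")
        transcripts.append(tr)
        rows.append(
            {
                "gene": row.gene,
                "accession": row.accession,
                "transcript_id": tid,
                "length_aa": row.length_aa,
                "complete": row.complete,
                "classic": row.classic,
                "family": "CSP" if row.gene.startswith("SaveCSP") else "OBP",
            }
        )
    return transcripts, pd.DataFrame(rows)
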