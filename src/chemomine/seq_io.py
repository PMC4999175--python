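"""Readers and writers for every external format the pipeline touches.

Formats handled here: nucleotide/protein FASTA (via Biopython), the per-gene
read-count CSV plus its companion library-size CSV, the long-format qPCR Ct
CSV, and the tab-separated candidate report.  All sequence text is uppercased
on read and RNA ``U`` is mapped to ``T`` so that downstream code sees a single
canonical alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import ValidationError

__all__ = [
    "Transcript",
    "CountTable",
    "CtTable",
    "read_fasta",
    "write_fasta",
    "read_count_table",
    "read_ct_table",
    "write_candidate_report",
]


@dataclass(frozen=True)
class Transcript:
    """A nucleotide unigene from an assembled transcriptome.

    ``seq`` is uppercase over {A, C, G, T, N}; ``description`` is the free
    text after the first whitespace of the FASTA header.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("transcript id must be non-empty")
        if len(self.seq) < 1:
            raise ValidationError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValidationError(
                f"transcript {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CountTable:
    """Per-gene uniquely-aligned read counts with per-library totals.

    ``counts`` is indexed by gene_id with a ``length_bp`` column and one
    integer column per condition.  ``library_sizes`` maps each condition to
    N, the total number of uniquely aligned reads of that library — supplied
    separately because N covers all unigenes, not only the genes tabulated.
    """

    counts: pd.DataFrame
    library_sizes: dict[str, int]

    def __post_init__(self) -> None:
        df = self.counts
        if "length_bp" not in df.columns:
            raise ValidationError("count table is missing the length_bp column")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if (df["length_bp"] < 1).any():
            raise ValidationError("length_bp must be >= 1 for every gene")
        for cond in self.conditions:
            if cond not in self.library_sizes:
                raise ValidationError(
                    f"condition {cond!r} has counts but no library size"
                )
        for cond, n in self.library_sizes.items():
            if cond not in df.columns:
                raise ValidationError(
                    f"library size given for unknown condition {cond!r}"
                )
            if n < 1:
                raise ValidationError(f"library size for {cond!r} must be positive")
            col = df[cond]
            if (col < 0).any():
                raise ValidationError(f"negative count in condition {cond!r}")
            if (col != col.astype(int)).any():
                raise ValidationError(f"non-integer count in condition {cond!r}")
            if int(col.max()) > n:
                raise ValidationError(
                    f"library size for {cond!r} ({n}) is smaller than the "
                    f"largest per-gene count ({int(col.max())})"
                )

    @property
    def conditions(self) -> list[str]:
        return [c for c in self.counts.columns if c != "length_bp"]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class CtTable:
    """Long-format qPCR quantification-cycle measurements.

    One row per (gene, sample, replicate); ``group_label`` ties samples into
    the comparison groups used by the ANOVA stage (e.g. tissues or instars).
    """

    data: pd.DataFrame

    REQUIRED = ("gene_id", "sample_id", "group_label", "replicate", "ct")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"Ct table is missing columns {missing}")
        if df["ct"].isna().any() or not pd.api.types.is_numeric_dtype(df["ct"]):
            raise ValidationError("Ct values must all be finite numbers")
        if (df["ct"] <= 0).any():
            raise ValidationError("Ct values must be > 0")
        key = df[["gene_id", "sample_id", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValidationError(
                f"duplicate (gene, sample, replicate) observation: {dup}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    def mean_ct(self) -> pd.DataFrame:
        """Replicate Cts averaged per (gene, sample), keeping group labels."""
        return (
            self.data.groupby(["gene_id", "sample_id", "group_label"], as_index=False)[
                "ct"
            ]
            .mean()
            .sort_values(["gene_id", "sample_id"])
            .reset_index(drop=True)
        )


def _canonical(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[Transcript]:
    """Parse a FASTA file into Transcripts, preserving record order.

    The header token up to the first whitespace is the id, the remainder the
    description.  Sequences are uppercased and U→T mapped.  Duplicate ids and
    empty records raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _canonical(str(rec.seq))
        if not seq:
            raise ValidationError(f"empty FASTA record {rec.id!r} in {path}")
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        out.append(Transcript(id=rec.id, seq=seq, description=desc))
    return out


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write Transcript-like records (``.id``, ``.seq``, opt ``.description``)."""
    seqrecs = []
    for r in records:
        desc = getattr(r, "description", "") or ""
        seqrecs.append(SeqRecord(Seq(r.seq), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_count_table(counts_path: str | Path, library_sizes_path: str | Path) -> CountTable:
    """Read the counts CSV (gene_id,length_bp,<cond>…) and library-size CSV (cond,N)."""
    counts_path, library_sizes_path = Path(counts_path), Path(library_sizes_path)
    for p in (counts_path, library_sizes_path):
        if not p.exists():
            raise FileNotFoundError(p)
    df = pd.read_csv(counts_path)
    if "gene_id" not in df.columns:
        raise ValidationError("counts CSV is missing the gene_id column")
    df = df.set_index("gene_id")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValidationError(f"non-numeric values in column {col!r}")
    lib = pd.read_csv(library_sizes_path)
    if list(lib.columns[:2]) != ["condition", "N"]:
        raise ValidationError(
            "library-size CSV must have header 'condition,N'"
        )
    sizes = {str(r.condition): int(r.N) for r in lib.itertuples()}
    return CountTable(counts=df, library_sizes=sizes)


def read_ct_table(path: str | Path) -> CtTable:
    """Read a long-format Ct CSV with columns gene_id,sample_id,group_label,replicate,ct."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "ct" in df.columns and not pd.api.types.is_numeric_dtype(df["ct"]):
        raise ValidationError("non-numeric ct values in Ct table")
    return CtTable(data=df)


# Family ordering used for deterministic report layout: OBP subfamilies first.
_FAMILY_ORDER = {"OBP_PLUSC": 0, "OBP_CLASSIC": 1, "OBP_GENERAL": 2, "CSP": 3, "NONE": 4}

REPORT_COLUMNS = (
    "protein_id",
    "family",
    "flags",
    "length_aa",
    "orf_complete",
    "anchor_positions_1based",
)


def write_candidate_report(candidates: Sequence[Mapping], path: str | Path) -> None:
    """Write candidates as TSV, one row each, ordered by (family, id).

    Candidate mappings must provide the :data:`REPORT_COLUMNS` keys. An empty
    candidate list produces a header-only file.
    """
    rows = sorted(
        candidates,
        key=lambda c: (_FAMILY_ORDER.get(str(c["family"]), 99), str(c["protein_id"])),
    )
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for c in rows:
            fh.write("\t".join(str(c[k]) for k in REPORT_COLUMNS) + "\n")
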