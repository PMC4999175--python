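"""Seeded generators that emulate the statistical structure of each input.

Every generator is a pure function of its plan plus a seed: proteins with
cysteine-spacing motifs planted at known positions (and near-miss negatives),
transcripts wrapping those proteins in ORFs with random UTRs, Poisson read
counts with known true RPKM, qPCR Ct tables with stable reference genes and
known fold changes, and gap-free alignments evolved along a known tree.

A single global seed expands to per-component seeds by fixed offsets, so
adding a generator never perturbs existing fixtures.  By default the residues
around planted anchors exclude the anchor letters themselves, making the
planted assignment provably the unique match; ``realistic=True`` lifts that
restriction for robustness stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import dendropy

from .errors import ValidationError
from .motif_engine import AA_ALPHABET, MotifSpec, builtin_motifs
from .seq_io import CountTable, CtTable, Transcript

__all__ = [
    "SEED_OFFSETS",
    "MotifPlan",
    "CtPlan",
    "TreePlan",
    "SimulationDesign",
    "plant_motif",
    "perturb_gap",
    "reverse_translate",
    "gen_transcript_set",
    "sim_counts",
    "sim_ct_table",
    "sim_alignment_on_tree",
]

# fixed offsets expanding one global seed into per-component streams
SEED_OFFSETS = {
    "motif": 11,
    "transcripts": 23,
    "counts": 37,
    "ct": 53,
    "alignment": 71,
}

_CODONS_BY_AA: dict[str, list[str]] = {}
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

for _codon, _aa in _tables[1].forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()
_STOP_CODONS = sorted(_tables[1].stop_codons)


@dataclass(frozen=True)
class MotifPlan:
    """One planted protein: which spec, the exact gap vector, flank lengths."""

    name: str
    spec_name: str
    gap_vector: tuple[int, ...]
    flank_lengths: tuple[int, int] = (20, 10)


@dataclass(frozen=True)
class CtPlan:
    """qPCR simulation plan.

    ``folds`` maps target gene -> per-sample fold levels (reference genes are
    implicitly fold 1 everywhere); ``sample_shifts`` are loading offsets in
    cycles shared by every gene of a sample; ``efficiencies`` are per-gene
    amplification factors (default 2).
    """

    genes: tuple[str, ...]
    reference_genes: tuple[str, ...]
    samples: tuple[str, ...]
    group_labels: tuple[str, ...]
    folds: dict[str, tuple[float, ...]]
    base_ct: float = 22.0
    noise_sd: float = 0.0
    n_replicates: int = 3
    sample_shifts: tuple[float, ...] | None = None
    efficiencies: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class TreePlan:
    """Sequence evolution plan: newick with branch lengths, root length, and
    the per-site substitution rate per unit branch length."""

    newick: str
    root_length: int = 120
    rate: float = 1.0


@dataclass(frozen=True)
class SimulationDesign:
    """Transcript-set plan: planted motif proteins plus shuffled negatives."""

    seed: int
    motif_plans: tuple[MotifPlan, ...]
    n_negatives: int = 5
    utr5: tuple[int, int] = (30, 90)
    utr3: tuple[int, int] = (30, 90)


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(seed + SEED_OFFSETS[component])


def _nonanchor_alphabet(spec: MotifSpec) -> str:
    excluded = set(spec.anchors)
    return "".join(a for a in AA_ALPHABET if a not in excluded)


def plant_motif(
    spec: MotifSpec,
    gap_vector: Sequence[int],
    flank_lengths: tuple[int, int],
    seed: int,
    realistic: bool = False,
) -> tuple[str, tuple[int, ...]]:
    """Build a protein with anchors at exactly the requested spacings.

    Returns (protein, planted anchor positions).  Gap and flank residues are
    drawn uniformly from the amino-acid alphabet excluding the spec's anchor
    letters (unless ``realistic``), so the planted assignment is the unique
    match.  Deterministic per seed.
    """
    gap_vector = tuple(int(g) for g in gap_vector)
    if len(gap_vector) != len(spec.gaps):
        raise ValidationError(
            f"gap vector length {len(gap_vector)} != {len(spec.gaps)} gaps"
        )
    for g, (lo, hi) in zip(gap_vector, spec.gaps):
        if not lo <= g <= hi:
            raise ValidationError(
                f"gap {g} outside range ({lo},{hi}) for motif {spec.name!r}"
            )
    lead, tail = flank_lengths
    if lead < 0 or tail < 0:
        raise ValidationError("flank lengths must be >= 0")
    if tail < spec.min_tail:
        raise ValidationError(
            f"motif {spec.name!r} requires a tail of >= {spec.min_tail} residues"
        )
    rng = _rng(seed, "motif")
    alphabet = AA_ALPHABET if realistic else _nonanchor_alphabet(spec)

    def draw(k: int) -> str:
        return "".join(rng.choice(list(alphabet), size=k)) if k else ""

    parts = [draw(lead)]
    positions = []
    cursor = lead
    for i, anchor in enumerate(spec.anchors):
        parts.append(anchor)
        positions.append(cursor)
        cursor += 1
        if i < len(gap_vector):
            parts.append(draw(gap_vector[i]))
            cursor += gap_vector[i]
    parts.append(draw(tail))
    return "".join(parts), tuple(positions)


def perturb_gap(
    protein: str,
    planted_positions: Sequence[int],
    gap_index: int,
    delta: int,
    seed: int = 0,
) -> tuple[str, tuple[int, ...]]:
    """Insert (delta > 0) or delete (delta < 0) residues inside one gap.

    Inserted residues are drawn from the alphabet excluding the letters at the
    planted anchor positions.  Returns the new protein and the shifted anchor
    positions; a delta that would make the gap negative raises.
    """
    pos = list(planted_positions)
    if not 0 <= gap_index < len(pos) - 1:
        raise ValidationError(f"gap_index {gap_index} out of range")
    left, right = pos[gap_index], pos[gap_index + 1]
    gap_len = right - left - 1
    if gap_len + delta < 0:
        raise ValidationError(
            f"delta {delta} would make gap {gap_index} negative (current {gap_len})"
        )
    anchors = {protein[p] for p in pos}
    alphabet = [a for a in AA_ALPHABET if a not in anchors]
    rng = _rng(seed, "motif")
    if delta >= 0:
        # insert just before the right anchor, inside the gap
        filler = "".join(rng.choice(alphabet, size=delta)) if delta else ""
        new = protein[:right] + filler + protein[right:]
    else:
        new = protein[: right + delta] + protein[right:]
    shifted = tuple(p if p <= left else p + delta for p in pos)
    return new, shifted


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous-codon reverse translation (no codon-usage model)."""
    codons = []
    for aa in protein:
        options = _CODONS_BY_AA.get(aa)
        if not options:
            raise ValidationError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _random_utr(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list("ACGT"), size=n))


def gen_transcript_set(
    design: SimulationDesign,
    motif_library: dict[str, MotifSpec] | None = None,
) -> tuple[list[Transcript], pd.DataFrame]:
    """Generate transcripts wrapping planted-motif ORFs plus shuffled negatives.

    Each planned protein (prefixed with M so the ORF starts at ATG) is
    reverse-translated, given a stop codon and random UTRs, and checked so the
    planted protein is what the longest-ORF rule recovers.  Negatives are
    nucleotide shuffles of the positives.  Returns (transcripts, truth table)
    with the truth table holding transcript_id, family, protein and planted
    anchor positions.
    """
    from .orf_finder import longest_orf_protein  # local: avoids cycle at import
    from .errors import NoOrfError

    lib = motif_library or builtin_motifs()
    rng = _rng(design.seed, "transcripts")
    transcripts: list[Transcript] = []
    truth_rows = []
    positives_nt: list[str] = []
    for idx, plan in enumerate(design.motif_plans):
        spec = lib[plan.spec_name]
        protein, positions = plant_motif(
            spec, plan.gap_vector, plan.flank_lengths, seed=design.seed + 1000 + idx
        )
        protein = "M" + protein
        positions = tuple(p + 1 for p in positions)
        orf_nt = "ATG" + reverse_translate(protein[1:], rng)
        stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
        tid = f"synth_{plan.name}"
        for _attempt in range(50):
            nt = (
                _random_utr(rng, *design.utr5)
                + orf_nt
                + stop
                + _random_utr(rng, *design.utr3)
            )
            tr = Transcript(id=tid, seq=nt)
            try:
                rec = longest_orf_protein(tr, min_aa=min(80, len(protein)))
            except NoOrfError:
                continue
            if rec.aa_seq == protein:
                break
        else:
            raise RuntimeError(f"could not embed ORF for {tid} without interference")
        transcripts.append(tr)
        positives_nt.append(nt)
        family = "CSP" if plan.spec_name.startswith("CSP") else plan.spec_name
        truth_rows.append(
            {
                "transcript_id": tid,
                "family": family,
                "spec_name": plan.spec_name,
                "protein": protein,
                "anchor_positions": ";".join(str(p) for p in positions),
            }
        )
    for i in range(design.n_negatives):
        src = positives_nt[i % len(positives_nt)] if positives_nt else _random_utr(
            rng, 300, 600
        )
        tid = f"synth_neg{i + 1}"
        for _attempt in range(100):
            arr = np.array(list(src))
            rng.shuffle(arr)
            nt = "".join(arr)
            tr = Transcript(id=tid, seq=nt)
            try:
                rec = longest_orf_protein(tr, min_aa=80)
            except NoOrfError:
                break
            from .motif_engine import classify_protein

            if classify_protein(rec).primary_family == "NONE":
                break
        else:
            raise RuntimeError(f"could not generate a clean negative {tid}")
        transcripts.append(tr)
        truth_rows.append(
            {
                "transcript_id": tid,
                "family": "NONE",
                "spec_name": "",
                "protein": "",
                "anchor_positions": "",
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "family", "spec_name", "protein", "anchor_positions"],
    )
    return transcripts, truth


def sim_counts(
    true_rpkm: dict[str, float],
    lengths: dict[str, int],
    library_sizes: dict[str, int],
    seed: int,
) -> CountTable:
    """Poisson read counts with known true RPKM per gene and condition.

    C_g ~ Poisson(rpkm_g * N * L_g / 1e9); the library size recorded is N
    itself, not the sum of simulated counts.
    """
    genes = sorted(true_rpkm)
    if set(genes) != set(lengths):
        raise ValidationError("true_rpkm and lengths must cover the same genes")
    for g in genes:
        if true_rpkm[g] < 0 or lengths[g] < 1:
            raise ValidationError(f"invalid plan for gene {g!r}")
    rng = _rng(seed, "counts")
    data = {"length_bp": [lengths[g] for g in genes]}
    for cond in sorted(library_sizes):
        n = library_sizes[cond]
        if n < 1:
            raise ValidationError(f"library size for {cond!r} must be positive")
        means = np.array([true_rpkm[g] * n * lengths[g] / 1e9 for g in genes])
        if np.any(means > 1e12):
            raise ValidationError("Poisson mean overflow; reduce rpkm, N or L")
        data[cond] = rng.poisson(means).astype(int)
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    return CountTable(counts=df, library_sizes=dict(library_sizes))


def sim_ct_table(plan: CtPlan, seed: int) -> CtTable:
    """Simulate a long-format Ct table under the relative-quantification model.

    Ct(g, s, rep) = base_ct - log_E(fold_{g,s}) + shift_s + Normal(0, sd);
    reference genes have fold 1 everywhere, so only the loading shift and
    noise move them.
    """
    n_s = len(plan.samples)
    if len(plan.group_labels) != n_s:
        raise ValidationError("group_labels must align with samples")
    shifts = plan.sample_shifts or tuple(0.0 for _ in plan.samples)
    if len(shifts) != n_s:
        raise ValidationError("sample_shifts must align with samples")
    for g, f in plan.folds.items():
        if len(f) != n_s:
            raise ValidationError(f"fold vector for {g!r} must align with samples")
        if any(x <= 0 for x in f):
            raise ValidationError(f"folds must be positive (gene {g!r})")
    rng = _rng(seed, "ct")
    rows = []
    all_genes = tuple(plan.genes) + tuple(
        rg for rg in plan.reference_genes if rg not in plan.genes
    )
    for g in all_genes:
        e = plan.efficiencies.get(g, 2.0)
        if e <= 1.0:
            raise ValidationError(f"amplification factor must exceed 1 (gene {g!r})")
        folds = plan.folds.get(g, tuple(1.0 for _ in plan.samples))
        for s_idx, s in enumerate(plan.samples):
            base = plan.base_ct - np.log(folds[s_idx]) / np.log(e) + shifts[s_idx]
            for rep in range(1, plan.n_replicates + 1):
                ct = base + (rng.normal(0.0, plan.noise_sd) if plan.noise_sd else 0.0)
                rows.append(
                    {
                        "gene_id": g,
                        "sample_id": s,
                        "group_label": plan.group_labels[s_idx],
                        "replicate": rep,
                        "ct": ct,
                    }
                )
    return CtTable(data=pd.DataFrame(rows))


def sim_alignment_on_tree(plan: TreePlan, seed: int) -> dict[str, str]:
    """Evolve a root protein along a tree; no indels, so leaves are aligned.

    Per branch, each site substitutes with probability 1 - exp(-rate*length);
    a substituted site draws a different residue uniformly.
    """
    if plan.root_length < 50:
        raise ValidationError("root sequence length must be >= 50")
    if not 0 <= plan.rate:
        raise ValidationError("substitution rate must be >= 0")
    tree = dendropy.Tree.get(data=plan.newick, schema="newick")
    rng = _rng(seed, "alignment")
    alphabet = np.array(list(AA_ALPHABET))
    root_seq = rng.choice(alphabet, size=plan.root_length)
    leaves: dict[str, str] = {}

    def evolve(seq: np.ndarray, length: float) -> np.ndarray:
        p = 1.0 - np.exp(-plan.rate * max(length, 0.0))
        if p <= 0:
            return seq.copy()
        out = seq.copy()
        hits = np.nonzero(rng.random(len(seq)) < p)[0]
        for i in hits:
            choices = alphabet[alphabet != out[i]]
            out[i] = choices[rng.integers(len(choices))]
        return out

    def walk(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 0.0
            child_seq = evolve(seq, bl)
            if child.is_leaf():
                leaves[child.taxon.label] = "".join(child_seq)
            else:
                walk(child, child_seq)

    walk(tree.seed_node, root_seq)
    return leaves
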