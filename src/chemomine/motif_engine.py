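"""Cysteine-spacing motif compilation, scanning and family classification.

Insect odorant-binding proteins (OBPs) and chemosensory proteins (CSPs) are
diagnosed by the spacing of their conserved cysteines.  Patterns are written
in a PROSITE-like dialect, e.g. ``C-x(15,39)-C-x(3)-C-x(21,44)-C-x(7,12)-C-x(8)-C``
for the general insect OBP motif: anchor residues separated by inclusive gap
ranges.  A protein "has the motif" iff at least one assignment of anchor
positions satisfies every gap range (any-assignment semantics), so scanning is
a backtracking search over candidate anchor positions rather than a greedy
regular-expression pass: greedy matching misses alternative cysteine
assignments.

Five motifs ship built in:

==============  ==============================================================
OBP_GENERAL     C1-X15-39-C2-X3-C3-X21-44-C4-X7-12-C5-X8-C6 (general insect OBP)
OBP_CLASSIC     C1-X22-32-C2-X3-C3-X36-46-C4-X8-14-C5-X8-C6 (classic hemipteran)
OBP_PLUSC       C1-X20-41-C2-X3-C3-X41-46-C4-X19-29-C4a-X9-C5-X8-C6-P-X9-10-C6a,
                encoded with the trailing X9-10 as ">= 9 residues after the
                final anchor" (the pattern leaves its right edge open)
CSP_METHODS     C1-X6-8-C2-X16-21-C3-X2-C4 (broad CSP spacing)
CSP_RESULTS     C1-X5-6-C2-X18-19-C3-X2-C4 (tight hemipteran CSP spacing; the
                default CSP variant)
==============  ==============================================================
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, ParseError, ValidationError
from .orf_finder import DEFAULT_MIN_AA, longest_orf_protein, ProteinRecord
from .errors import NoOrfError

__all__ = [
    "MotifSpec",
    "MotifMatch",
    "FamilyCall",
    "parse_motif",
    "scan_motif",
    "classify_protein",
    "mine_candidates",
    "builtin_motifs",
    "BUILTIN_PATTERNS",
    "FAMILY_PRECEDENCE",
    "MAX_ASSIGNMENTS",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Enumeration cap per protein; pathological C-rich inputs otherwise explode.
MAX_ASSIGNMENTS = 10_000

FAMILY_PRECEDENCE = ("OBP_PLUSC", "OBP_CLASSIC", "OBP_GENERAL", "CSP", "NONE")

BUILTIN_PATTERNS: dict[str, str] = {
    "OBP_GENERAL": "C-x(15,39)-C-x(3)-C-x(21,44)-C-x(7,12)-C-x(8)-C",
    "OBP_CLASSIC": "C-x(22,32)-C-x(3)-C-x(36,46)-C-x(8,14)-C-x(8)-C",
    "OBP_PLUSC": "C-x(20,41)-C-x(3)-C-x(41,46)-C-x(19,29)-C-x(9)-C-x(8)-C-P-x(9,10)-C",
    "CSP_METHODS": "C-x(6,8)-C-x(16,21)-C-x(2)-C",
    "CSP_RESULTS": "C-x(5,6)-C-x(18,19)-C-x(2)-C",
}

# The Plus-C pattern's trailing X9-10 has no right-hand anchor; it is encoded
# as a minimum tail after the final anchor.
_BUILTIN_MIN_TAIL = {"OBP_PLUSC": 9}


@dataclass(frozen=True)
class MotifSpec:
    """An ordered anchor-and-gap pattern.

    ``anchors`` are required residues; ``gaps[i]`` is the inclusive (min, max)
    number of unrestricted residues between anchors i and i+1.  ``min_tail``
    residues must follow the final anchor (0 for ordinary patterns).
    """

    name: str
    anchors: tuple[str, ...]
    gaps: tuple[tuple[int, int], ...]
    min_tail: int = 0

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValidationError(f"motif {self.name!r}: needs >= 2 anchors")
        if len(self.gaps) != len(self.anchors) - 1:
            raise ValidationError(
                f"motif {self.name!r}: {len(self.anchors)} anchors require "
                f"{len(self.anchors) - 1} gaps, got {len(self.gaps)}"
            )
        for lo, hi in self.gaps:
            if not (0 <= lo <= hi):
                raise ValidationError(
                    f"motif {self.name!r}: invalid gap range ({lo},{hi})"
                )
        for a in self.anchors:
            if len(a) != 1 or a not in AA_ALPHABET:
                raise ValidationError(f"motif {self.name!r}: bad anchor {a!r}")

    @property
    def min_span(self) -> int:
        return len(self.anchors) + sum(lo for lo, _ in self.gaps)

    @property
    def max_span(self) -> int:
        return len(self.anchors) + sum(hi for _, hi in self.gaps)


@dataclass(frozen=True)
class MotifMatch:
    """A concrete assignment of anchor positions in one protein."""

    motif: str
    anchor_positions: tuple[int, ...]

    @property
    def span(self) -> tuple[int, int]:
        return self.anchor_positions[0], self.anchor_positions[-1]

    def check(self, protein: str, spec: MotifSpec) -> bool:
        """Re-verify this match independently against its spec."""
        pos = self.anchor_positions
        if len(pos) != len(spec.anchors):
            return False
        if any(p2 <= p1 for p1, p2 in zip(pos, pos[1:])):
            return False
        if any(protein[p] != a for p, a in zip(pos, spec.anchors)):
            return False
        for (p1, p2), (lo, hi) in zip(zip(pos, pos[1:]), spec.gaps):
            if not (lo <= p2 - p1 - 1 <= hi):
                return False
        return len(protein) - 1 - pos[-1] >= spec.min_tail


@dataclass(frozen=True)
class FamilyCall:
    """Family-membership flags and the single primary family of one protein."""

    protein_id: str
    flags: frozenset[str]
    primary_family: str
    matches: tuple[MotifMatch, ...]

    def __post_init__(self) -> None:
        expected = _primary_from_flags(self.flags)
        if expected != self.primary_family:
            raise ValidationError(
                f"{self.protein_id}: primary {self.primary_family!r} does not "
                f"follow from flags {sorted(self.flags)}"
            )


def _primary_from_flags(flags: frozenset[str]) -> str:
    for fam in FAMILY_PRECEDENCE[:-1]:
        if fam in flags:
            return fam
    return "NONE"


_TOKEN_RE = re.compile(r"^(?:(?P<res>[A-Z])|x\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))$")


def parse_motif(pattern: str, name: str = "", min_tail: int = 0) -> MotifSpec:
    """Compile a pattern string like ``C-x(15,39)-C-x(3)-C`` into a MotifSpec.

    ``x(n)`` denotes an exact gap of n, ``x(n,m)`` a range; adjacent anchor
    letters written ``R-R`` mean a gap of (0, 0).
    """
    tokens = pattern.strip().split("-")
    anchors: list[str] = []
    gaps: list[tuple[int, int]] = []
    pending_gap: tuple[int, int] | None = None
    for idx, tok in enumerate(tokens):
        m = _TOKEN_RE.match(tok.strip())
        if not m:
            raise ParseError(f"malformed token {tok!r} at position {idx} in {pattern!r}")
        if m.group("res"):
            if anchors:
                gaps.append(pending_gap if pending_gap is not None else (0, 0))
            anchors.append(m.group("res"))
            pending_gap = None
        else:
            if pending_gap is not None or not anchors:
                raise ParseError(
                    f"gap token {tok!r} at position {idx} must sit between anchors"
                )
            lo = int(m.group("lo"))
            hi = int(m.group("hi")) if m.group("hi") is not None else lo
            if lo > hi:
                raise ValidationError(f"gap range ({lo},{hi}) has min > max")
            pending_gap = (lo, hi)
    if pending_gap is not None:
        raise ParseError(f"pattern {pattern!r} ends with a dangling gap")
    return MotifSpec(
        name=name or pattern, anchors=tuple(anchors), gaps=tuple(gaps), min_tail=min_tail
    )


def builtin_motifs() -> dict[str, MotifSpec]:
    """The five built-in motif specs keyed by name."""
    return {
        name: parse_motif(pat, name=name, min_tail=_BUILTIN_MIN_TAIL.get(name, 0))
        for name, pat in BUILTIN_PATTERNS.items()
    }


def scan_motif(protein: str, motif: MotifSpec) -> list[MotifMatch]:
    """All distinct anchor-position assignments of ``motif`` in ``protein``.

    Backtracking over candidate anchor positions with gap-range pruning;
    results are ordered lexicographically by anchor positions and capped at
    :data:`MAX_ASSIGNMENTS` (with a warning) on pathological inputs.
    """
    bad = set(protein) - set(AA_ALPHABET) - {"X"}
    if bad:
        raise ValidationError(f"non-amino-acid characters {sorted(bad)}")
    n = len(protein)
    # candidate positions per anchor residue, computed once
    pos_by_res = {a: [i for i, r in enumerate(protein) if r == a] for a in set(motif.anchors)}
    # suffix minimum span: residues needed from anchor k to the end of the match
    k_anchors = len(motif.anchors)
    suffix_min = [0] * (k_anchors + 1)
    for k in range(k_anchors - 1, -1, -1):
        gap_lo = motif.gaps[k][0] if k < k_anchors - 1 else 0
        suffix_min[k] = 1 + (gap_lo + suffix_min[k + 1] if k < k_anchors - 1 else 0)
    out: list[MotifMatch] = []
    truncated = False

    def backtrack(k: int, prev: int, acc: list[int]) -> None:
        nonlocal truncated
        if truncated:
            return
        if k == k_anchors:
            out.append(MotifMatch(motif=motif.name, anchor_positions=tuple(acc)))
            if len(out) >= MAX_ASSIGNMENTS:
                truncated = True
            return
        res = motif.anchors[k]
        if k == 0:
            candidates = pos_by_res.get(res, [])
        else:
            lo, hi = motif.gaps[k - 1]
            candidates = [
                p for p in pos_by_res.get(res, []) if lo <= p - prev - 1 <= hi
            ]
        for p in candidates:
            # room for the remaining minimum span plus the required tail
            if p + suffix_min[k] + motif.min_tail > n:
                continue
            backtrack(k + 1, p, acc + [p])

    backtrack(0, -1, [])
    if truncated:
        warnings.warn(
            f"motif {motif.name!r}: enumeration capped at {MAX_ASSIGNMENTS} "
            "assignments",
            RuntimeWarning,
            stacklevel=2,
        )
    out.sort(key=lambda m: m.anchor_positions)
    return out


def classify_protein(
    protein: ProteinRecord | str,
    motif_library: Mapping[str, MotifSpec] | None = None,
    csp_variant: str = "CSP_RESULTS",
    protein_id: str | None = None,
) -> FamilyCall:
    """Test a protein against every motif independently and call its family.

    Flags collect each motif with >= 1 assignment; the CSP flag comes from the
    configured variant (default the tight hemipteran spacing).  The primary
    family follows the fixed precedence Plus-C > classic > general OBP > CSP.
    Classic membership is tested on its own — its ranges overlap the general
    pattern's but neither contains the other.
    """
    if motif_library is None:
        motif_library = builtin_motifs()
    if not motif_library:
        raise ConfigurationError("empty motif library")
    if csp_variant not in ("CSP_METHODS", "CSP_RESULTS"):
        raise ConfigurationError(f"unknown CSP variant {csp_variant!r}")
    if isinstance(protein, ProteinRecord):
        aa, pid = protein.aa_seq, protein.id
    else:
        aa, pid = protein, (protein_id or "protein")
    flags: set[str] = set()
    matches: list[MotifMatch] = []
    for name, spec in motif_library.items():
        found = scan_motif(aa, spec)
        if not found:
            continue
        matches.extend(found)
        if name.startswith("CSP"):
            if name == csp_variant:
                flags.add("CSP")
        else:
            flags.add(name)
    return FamilyCall(
        protein_id=pid,
        flags=frozenset(flags),
        primary_family=_primary_from_flags(frozenset(flags)),
        matches=tuple(matches),
    )


def mine_candidates(
    transcripts: Iterable,
    motif_library: Mapping[str, MotifSpec] | None = None,
    min_aa: int = DEFAULT_MIN_AA,
    csp_variant: str = "CSP_RESULTS",
) -> list[dict]:
    """Mine OBP/CSP candidates from transcripts.

    Each transcript's longest-ORF protein is classified; only proteins with a
    primary family are returned.  Anchor positions are reported 1-based, as in
    the written report.
    """
    if motif_library is None:
        motif_library = builtin_motifs()
    out: list[dict] = []
    for tr in transcripts:
        try:
            prot = longest_orf_protein(tr, min_aa=min_aa)
        except NoOrfError:
            continue
        call = classify_protein(prot, motif_library, csp_variant=csp_variant)
        if call.primary_family == "NONE":
            continue
        primary_matches = [
            m for m in call.matches if m.motif == (
                csp_variant if call.primary_family == "CSP" else call.primary_family
            )
        ]
        first = primary_matches[0] if primary_matches else call.matches[0]
        out.append(
            {
                "protein_id": prot.id,
                "family": call.primary_family,
                "flags": ",".join(sorted(call.flags)),
                "length_aa": prot.length_aa,
                "orf_complete": prot.orf.is_complete,
                "anchor_positions_1based": ";".join(
                    str(p + 1) for p in first.anchor_positions
                ),
                "aa_seq": prot.aa_seq,
            }
        )
    return out
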