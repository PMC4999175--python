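"""Abundance and qPCR expression analysis.

Two quantification paths live here.  For the sequencing libraries, read
counts become RPKM (reads per kilobase of transcript per million mapped
reads):

    RPKM(A) = (1,000,000 x C x 1,000) / (N x L)

with C the reads uniquely aligned to gene A, N the total uniquely aligned
reads of the library and L the gene length in bases.  No pseudo-counts are
added; C = 0 yields exactly 0.

For qPCR, a dilution standard curve validates each assay's amplification
efficiency (E = 10^(-1/slope) - 1, acceptable between 90% and 110%), relative
quantities are normalized by the geometric mean of multiple reference genes
(geNorm-style multi-reference normalization), and group contrasts use a
classical one-way ANOVA followed by Fisher's least-significant-difference
pairwise test, summarized as a compact letter display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .seq_io import CountTable, CtTable

__all__ = [
    "RpkmRecord",
    "EfficiencyFit",
    "NormalizedExpression",
    "AnovaLetters",
    "compute_rpkm",
    "rpkm_table",
    "fit_standard_curve",
    "vandesompele_normalize",
    "anova_lsd",
]


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RpkmRecord:
    gene_id: str
    condition: str
    C: int
    N: int
    L: int
    rpkm: float


def compute_rpkm(C: int, N: int, L: int) -> float:
    """RPKM(A) = (1,000,000 x C x 1,000) / (N x L), exactly."""
    if N < 1:
        raise ValidationError("N (total uniquely aligned reads) must be >= 1")
    if L < 1:
        raise ValidationError("L (gene length in bases) must be >= 1")
    if C < 0:
        raise ValidationError("C (reads aligned to the gene) must be >= 0")
    return (1_000_000 * C * 1_000) / (N * L)


def rpkm_table(counts: CountTable) -> pd.DataFrame:
    """Per-gene, per-condition RPKM with cross-condition ratio and ranks.

    Rows are indexed by gene_id (sorted); for each condition there are
    ``rpkm_<cond>`` and ``rank_<cond>`` columns (rank 1 = most abundant, ties
    broken by gene id).  With exactly two conditions a ``ratio`` column holds
    first-condition over second-condition RPKM; a zero denominator yields
    ``inf`` (or ``nan`` for 0/0) — explicit markers, not pseudo-counts.
    """
    conds = counts.conditions
    genes = sorted(counts.gene_ids)
    df = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for cond in conds:
        n = counts.library_sizes[cond]
        vals = [
            compute_rpkm(int(counts.counts.loc[g, cond]), n, int(counts.counts.loc[g, "length_bp"]))
            for g in genes
        ]
        df[f"rpkm_{cond}"] = vals
        order = sorted(genes, key=lambda g: (-df.loc[g, f"rpkm_{cond}"], g))
        df[f"rank_{cond}"] = [order.index(g) + 1 for g in genes]
    if len(conds) == 2:
        a, b = conds
        with np.errstate(divide="ignore", invalid="ignore"):
            df["ratio"] = np.where(
                (df[f"rpkm_{a}"] == 0) & (df[f"rpkm_{b}"] == 0),
                np.nan,
                df[f"rpkm_{a}"] / df[f"rpkm_{b}"],
            )
    return df


def rpkm_records(counts: CountTable) -> list[RpkmRecord]:
    """The same quantities as :func:`rpkm_table`, as typed records."""
    out = []
    for g in sorted(counts.gene_ids):
        L = int(counts.counts.loc[g, "length_bp"])
        for cond in counts.conditions:
            C = int(counts.counts.loc[g, cond])
            N = counts.library_sizes[cond]
            out.append(RpkmRecord(g, cond, C, N, L, compute_rpkm(C, N, L)))
    return out


# ---------------------------------------------------------------------------
# Standard curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficiencyFit:
    """OLS fit of Ct on log10 template amount and the implied efficiency."""

    gene_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    passes: bool


def fit_standard_curve(
    dilution_cts: list[tuple[float, float]], gene_id: str = ""
) -> EfficiencyFit:
    """Fit a qPCR dilution series and judge the 90–110% efficiency window.

    ``dilution_cts`` holds (log10 input amount, Ct) pairs; the efficiency is
    100 x (10^(-1/slope) - 1).  A perfect doubling assay has slope -3.3219
    and efficiency 100%.  Curves with a non-negative slope are flagged as
    failing with a warning.
    """
    if len(dilution_cts) < 3:
        raise ValidationError("standard curve needs >= 3 dilution points")
    x = np.array([p[0] for p in dilution_cts], dtype=float)
    y = np.array([p[1] for p in dilution_cts], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("dilution amounts have zero variance")
    res = stats.linregress(x, y)
    slope, intercept, r = res.slope, res.intercept, res.rvalue
    if slope >= 0:
        warnings.warn(
            f"standard curve for {gene_id or 'gene'} has non-negative slope "
            f"({slope:.3g}); efficiency is not meaningful",
            RuntimeWarning,
            stacklevel=2,
        )
        eff = 100.0 * (10 ** (-1.0 / slope) - 1.0) if slope != 0 else float("nan")
        return EfficiencyFit(gene_id, slope, intercept, r**2, eff, False)
    eff = 100.0 * (10 ** (-1.0 / slope) - 1.0)
    return EfficiencyFit(gene_id, slope, intercept, r**2, eff, 90.0 <= eff <= 110.0)


# ---------------------------------------------------------------------------
# Multi-reference (geometric mean) normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedExpression:
    """Reference-normalized relative quantity of one gene in one sample.

    Q = E^(Ct_min - Ct) with Ct_min the gene's minimal mean Ct over samples;
    NF is the geometric mean of the reference genes' Q in the sample; norm =
    Q / NF; fold is norm relative to the calibrator sample.
    """

    gene_id: str
    sample_id: str
    group_label: str
    q: float
    nf: float
    norm: float
    fold_vs_calibrator: float


def vandesompele_normalize(
    ct: CtTable,
    reference_genes: list[str],
    efficiencies: dict[str, float] | None = None,
    calibrator_sample: str | None = None,
) -> list[NormalizedExpression]:
    """Multi-reference relative quantification of a Ct table.

    Technical replicates are averaged per (gene, sample).  Per gene, the
    relative quantity in a sample is E^(Ct_min - Ct); per sample, the
    normalization factor NF is the geometric mean of the reference genes'
    quantities, which cancels sample-loading shifts shared by all genes of a
    sample.  ``efficiencies`` maps gene to the amplification *factor* E
    (default 2.0, the ideal doubling); ``calibrator_sample`` defaults to the
    sample whose id sorts first.
    """
    if not reference_genes:
        raise ValidationError("at least one reference gene is required")
    eff = dict(efficiencies or {})
    means = ct.mean_ct()
    genes = means["gene_id"].unique().tolist()
    samples = sorted(means["sample_id"].unique())
    for g, e in eff.items():
        if e <= 0:
            raise ValidationError(f"non-positive efficiency for {g!r}")
    for rg in reference_genes:
        present = set(means.loc[means["gene_id"] == rg, "sample_id"])
        missing = [s for s in samples if s not in present]
        if rg not in genes:
            raise ValidationError(f"reference gene {rg!r} absent from the Ct table")
        if missing:
            raise ValidationError(
                f"reference gene {rg!r} missing in sample(s) {missing}"
            )
    if calibrator_sample is None:
        calibrator_sample = samples[0]
    elif calibrator_sample not in samples:
        raise ValidationError(f"calibrator sample {calibrator_sample!r} not found")

    pivot = means.pivot(index="gene_id", columns="sample_id", values="ct")
    group_of = dict(zip(means["sample_id"], means["group_label"]))
    q: dict[tuple[str, str], float] = {}
    for g in genes:
        e = eff.get(g, 2.0)
        row = pivot.loc[g]
        ct_min = row.min()
        for s in samples:
            if not math.isnan(row[s]):
                q[(g, s)] = e ** (ct_min - row[s])
    nf = {
        s: math.exp(
            sum(math.log(q[(rg, s)]) for rg in reference_genes) / len(reference_genes)
        )
        for s in samples
    }
    out: list[NormalizedExpression] = []
    norm: dict[tuple[str, str], float] = {
        key: val / nf[key[1]] for key, val in q.items()
    }
    for g in genes:
        base = norm.get((g, calibrator_sample))
        for s in samples:
            if (g, s) not in norm:
                continue
            fold = norm[(g, s)] / base if base else float("nan")
            out.append(
                NormalizedExpression(
                    gene_id=g,
                    sample_id=s,
                    group_label=group_of[s],
                    q=q[(g, s)],
                    nf=nf[s],
                    norm=norm[(g, s)],
                    fold_vs_calibrator=fold,
                )
            )
    return out


# ---------------------------------------------------------------------------
# One-way ANOVA + LSD compact letter display
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaLetters:
    """One-way ANOVA with Fisher's LSD post hoc, as compact letters.

    Groups that do not differ significantly at level alpha share at least one
    letter; letters are assigned over groups sorted by descending mean.
    """

    groups: tuple[str, ...]
    f_statistic: float
    p_value: float
    mse: float
    df_error: int
    letters: dict[str, str]

    def summary(self) -> str:
        lines = [
            f"one-way ANOVA: F = {self.f_statistic:.4g}, "
            f"p = {self.p_value:.4g}, MSE = {self.mse:.4g}, "
            f"df_error = {self.df_error}",
            "group\tletters",
        ]
        for g in self.groups:
            lines.append(f"{g}\t{self.letters[g]}")
        return "\n".join(lines)


def _compact_letters(
    order: list[str], differs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``order`` lists groups by descending mean; ``differs`` holds unordered
    significant pairs.  Start from one column holding all groups; for every
    significant pair sharing a column, split that column; absorb columns that
    are subsets of others; letter the surviving columns.
    """
    columns: list[set[str]] = [set(order)]
    for a, b in sorted(differs):
        split: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                split.extend((col - {b}, col - {a}))
            else:
                split.append(col)
        # absorb duplicates and proper subsets
        columns = []
        for c in split:
            if any(c < other for other in split):
                continue
            if c not in columns:
                columns.append(c)
    # order columns by the first (highest-mean) group they contain
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for idx, col in enumerate(columns):
        letter = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for g in col:
            letters[g] += letter
    return letters


def anova_lsd(values_by_group: dict[str, list[float]], alpha: float = 0.05) -> AnovaLetters:
    """Classical one-way ANOVA followed by Fisher's LSD letter grouping.

    Two groups differ iff |mean_i - mean_j| > t(1-alpha/2, df_error) *
    sqrt(MSE * (1/n_i + 1/n_j)).  With zero within-group variance and unequal
    means, F is reported as +inf and letters follow the exact ordering of
    means (equal means share a letter).
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if len(values_by_group) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    for g, vals in values_by_group.items():
        if len(vals) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 replicates")
    groups = list(values_by_group)
    data = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    n_tot = sum(len(v) for v in data.values())
    k = len(groups)
    grand = sum(v.sum() for v in data.values()) / n_tot
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_e = k - 1, n_tot - k
    mse = ss_within / df_e
    means = {g: data[g].mean() for g in groups}
    order = sorted(groups, key=lambda g: (-means[g], g))
    if mse == 0:
        if len({round(m, 12) for m in means.values()}) == 1:
            f_stat, p = 0.0, 1.0
            differs: set[tuple[str, str]] = set()
        else:
            f_stat, p = float("inf"), 0.0
            differs = {
                tuple(sorted((a, b)))
                for i, a in enumerate(groups)
                for b in groups[i + 1 :]
                if means[a] != means[b]
            }
    else:
        ms_between = ss_between / df_b
        f_stat = ms_between / mse
        p = float(stats.f.sf(f_stat, df_b, df_e))
        t_crit = stats.t.ppf(1 - alpha / 2, df_e)
        differs = set()
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                lsd = t_crit * math.sqrt(mse * (1 / len(data[a]) + 1 / len(data[b])))
                if abs(means[a] - means[b]) > lsd:
                    differs.add(tuple(sorted((a, b))))
    letters = _compact_letters(order, differs)
    return AnovaLetters(
        groups=tuple(order),
        f_statistic=float(f_stat),
        p_value=float(p),
        mse=float(mse),
        df_error=df_e,
        letters=letters,
    )
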