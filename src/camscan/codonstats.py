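"""Codon-usage statistics for eligible CDSs and group-level comparisons.

Implements, under the bacterial genetic code (table 11):

* relative synonymous codon usage (RSCU), the observed/expected ratio under
  uniform synonymous usage (Sharp & Li);
* Wright's effective number of codons (ENC) on the [20, 61] scale, from
  mean codon homozygosities per degeneracy class;
* parity-rule-2 (PR2) coordinates G3/(G3+C3) and A3/(A3+T3) at third codon
  positions, by default accumulated over the five four-fold families;
* significantly variable codons (SVCs) between two pooled groups;
* stop-codon preference tallies;
* the F-test-then-t-test comparison of per-gene ENC between groups.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from ._genetic_code import (
    DEGENERACY_CLASSES,
    FAMILIES,
    FOURFOLD_AAS,
    REPORTABLE_CODONS,
    STOP_CODONS,
)
from .io import CdsRecord

__all__ = [
    "CodonCounts",
    "RscuTable",
    "EncValue",
    "Pr2Point",
    "GroupComparison",
    "count_codons",
    "pool_counts",
    "rscu",
    "enc",
    "pr2_point",
    "svc",
    "stop_codon_tally",
    "enc_group_test",
    "gc_content",
]


@dataclass
class CodonCounts:
    """In-frame codon counts for one gene/strain (terminal codon held apart)."""

    gene_id: str
    strain_id: str
    counts: dict[str, int]
    terminal_codon: str | None = None
    eligible: bool = True
    warnings: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RscuTable:
    """codon -> RSCU over the 61 sense codons; absent families flagged."""

    values: dict[str, float]
    absent_families: frozenset[str] = frozenset()

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


@dataclass
class EncValue:
    gene_id: str
    strain_id: str
    enc: float
    f_bar: dict[int, float]
    imputed_classes: tuple[int, ...] = ()
    defined: bool = True


@dataclass
class Pr2Point:
    gene_id: str
    strain_id: str
    x: float  # G3/(G3+C3)
    y: float  # A3/(A3+T3)
    a3: int
    t3: int
    g3: int
    c3: int
    defined: bool = True


@dataclass
class GroupComparison:
    """ENC comparison of one gene between the two lineages."""

    gene_id: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    f_pvalue: float
    variant: str  # "equal-variance" | "unequal-variance"
    t_pvalue: float
    tier: str  # ">0.05" | "<0.05" | "<0.01"


def count_codons(cds: CdsRecord) -> CodonCounts:
    """In-frame triplet counts; codons containing N are skipped.

    Frame-flagged records are counted over floor(len/3) codons with a
    warning retained on the result.
    """
    seq = cds.sequence
    n_codons = len(seq) // 3
    counts: Counter[str] = Counter()
    notes = list(cds.warnings)
    if not cds.frame_ok and seq:
        notes.append("frame-flagged record: counted floor(len/3) codons")
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if "N" in codon:
            continue
        counts[codon] += 1
    return CodonCounts(
        gene_id=cds.gene_id,
        strain_id=cds.strain_id,
        counts=dict(counts),
        terminal_codon=cds.terminal_codon,
        eligible=cds.eligible,
        warnings=tuple(notes),
    )


def pool_counts(
    members: Sequence[CodonCounts], label: str = "pooled"
) -> CodonCounts:
    """Sum codon counts across strains of a group (count pooling).

    Group-level RSCU (and hence SVCs) is computed from pooled counts rather
    than from averaged per-strain RSCU: pooling is robust for short genes
    and mirrors consensus-sequence usage.
    """
    if not members:
        raise ValueError("cannot pool an empty group")
    total: Counter[str] = Counter()
    for m in members:
        total.update(m.counts)
    return CodonCounts(
        gene_id=members[0].gene_id,
        strain_id=label,
        counts=dict(total),
        eligible=all(m.eligible for m in members),
    )


def rscu(counts: CodonCounts) -> RscuTable:
    """RSCU(c) = n_c * family_size / family_total over sense codons.

    A family with zero total usage gets RSCU = 0 for every member and is
    flagged absent; RSCU = 0 is exactly the codon-aversion condition.
    """
    values: dict[str, float] = {}
    absent: set[str] = set()
    for aa, codons in FAMILIES.items():
        family_total = sum(counts.counts.get(c, 0) for c in codons)
        if family_total == 0:
            absent.add(aa)
            for c in codons:
                values[c] = 0.0
            continue
        k = len(codons)
        for c in codons:
            values[c] = counts.counts.get(c, 0) * k / family_total
    return RscuTable(values=values, absent_families=frozenset(absent))


def _family_homozygosity(n: int, counts: Sequence[int]) -> float:
    """F = (n * sum(p^2) - 1) / (n - 1); requires n >= 2."""
    s = sum((c / n) ** 2 for c in counts)
    return (n * s - 1) / (n - 1)


def enc(counts: CodonCounts) -> EncValue:
    """Wright's effective number of codons from codon homozygosities.

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with F the mean of per-family
    homozygosities within each degeneracy class; families observed at most
    once are excluded from their class mean. A degeneracy class with no
    estimable family is imputed at the uniform expectation 1/k and flagged.
    The result is clipped at 61 (sampling noise can push the raw sum past
    the uniform-usage ceiling).
    """
    f_bar: dict[int, float] = {}
    imputed: list[int] = []
    for k in (2, 3, 4, 6):
        fs = []
        for aa in DEGENERACY_CLASSES[k]:
            fam = FAMILIES[aa]
            n = sum(counts.counts.get(c, 0) for c in fam)
            if n <= 1:
                continue
            f = _family_homozygosity(n, [counts.counts.get(c, 0) for c in fam])
            if f > 0:
                fs.append(f)
        if fs:
            f_bar[k] = sum(fs) / len(fs)
        else:
            f_bar[k] = 1.0 / k
            imputed.append(k)
    if len(imputed) == 4:
        return EncValue(
            gene_id=counts.gene_id,
            strain_id=counts.strain_id,
            enc=math.nan,
            f_bar=f_bar,
            imputed_classes=tuple(imputed),
            defined=False,
        )
    value = 2 + 9 / f_bar[2] + 1 / f_bar[3] + 5 / f_bar[4] + 3 / f_bar[6]
    return EncValue(
        gene_id=counts.gene_id,
        strain_id=counts.strain_id,
        enc=min(value, 61.0),
        f_bar=f_bar,
        imputed_classes=tuple(imputed),
    )


def pr2_point(counts: CodonCounts, fourfold_only: bool = True) -> Pr2Point:
    """Third-position base composition as PR2 coordinates.

    By default only the five four-fold degenerate families (Val, Pro, Thr,
    Ala, Gly) contribute, where third-position changes are synonymous;
    with ``fourfold_only=False`` every counted codon contributes.
    """
    if fourfold_only:
        codons: Iterable[str] = (
            c for aa in FOURFOLD_AAS for c in FAMILIES[aa]
        )
    else:
        codons = counts.counts
    comp = Counter()
    for c in codons:
        comp[c[2]] += counts.counts.get(c, 0)
    a3, t3, g3, c3 = comp["A"], comp["T"], comp["G"], comp["C"]
    gc_den, at_den = g3 + c3, a3 + t3
    defined = gc_den > 0 and at_den > 0
    return Pr2Point(
        gene_id=counts.gene_id,
        strain_id=counts.strain_id,
        x=g3 / gc_den if gc_den else math.nan,
        y=a3 / at_den if at_den else math.nan,
        a3=a3,
        t3=t3,
        g3=g3,
        c3=c3,
        defined=defined,
    )


def svc(group_a: RscuTable, group_b: RscuTable) -> tuple[str, ...]:
    """Significantly variable codons between two pooled RSCU tables.

    A codon is an SVC when it is preferred (RSCU > 1) in exactly one of the
    groups; the boundary RSCU = 1 counts as unpreferred. Single-codon
    families are excluded (their RSCU is constant).
    """
    out = [
        c
        for c in REPORTABLE_CODONS
        if (group_a[c] > 1) != (group_b[c] > 1)
    ]
    return tuple(sorted(out))


def stop_codon_tally(
    terminal_codons: Iterable[str | None],
) -> list[tuple[str, int]]:
    """Ranked stop-codon counts; non-stop terminals are excluded with a warning.

    Ties rank TAA before TAG before TGA.
    """
    counts = Counter({c: 0 for c in STOP_CODONS})
    for t in terminal_codons:
        if t is None:
            continue
        if t not in STOP_CODONS:
            warnings.warn(f"non-stop terminal codon {t!r} excluded", stacklevel=2)
            continue
        counts[t] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _tier(p: float) -> str:
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    return ">0.05"


def enc_group_test(
    gene_id: str,
    enc_a: Sequence[float],
    enc_b: Sequence[float],
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-stage ENC comparison: F-test on variances, then the matching t-test.

    A two-sided F-test at ``alpha`` decides between the pooled-variance and
    the unequal-variance (Welch) two-sided t-test. Degenerate inputs with
    zero variance in both groups resolve by convention: equal means give
    p = 1, distinct means p = 0.
    """
    if len(enc_a) < 2 or len(enc_b) < 2:
        raise ValueError("need at least two values per group")
    a = [float(v) for v in enc_a]
    b = [float(v) for v in enc_b]
    mean_a, mean_b = sum(a) / len(a), sum(b) / len(b)
    var_a = sum((v - mean_a) ** 2 for v in a) / (len(a) - 1)
    var_b = sum((v - mean_b) ** 2 for v in b) / (len(b) - 1)
    sd_a, sd_b = math.sqrt(var_a), math.sqrt(var_b)

    if var_a == 0.0 and var_b == 0.0:
        p = 1.0 if mean_a == mean_b else 0.0
        return GroupComparison(
            gene_id, mean_a, sd_a, mean_b, sd_b,
            f_pvalue=1.0, variant="equal-variance", t_pvalue=p, tier=_tier(p),
        )

    if var_b == 0.0 or var_a == 0.0:
        f_p = 0.0  # infinite (or zero) variance ratio: clearly unequal
    else:
        fstat = var_a / var_b
        dist = stats.f(len(a) - 1, len(b) - 1)
        f_p = 2 * min(dist.cdf(fstat), dist.sf(fstat))
        f_p = min(f_p, 1.0)

    equal_var = f_p >= alpha
    t_res = stats.ttest_ind(a, b, equal_var=equal_var)
    t_p = float(t_res.pvalue)
    if math.isnan(t_p):
        t_p = 1.0 if mean_a == mean_b else 0.0
    return GroupComparison(
        gene_id, mean_a, sd_a, mean_b, sd_b,
        f_pvalue=float(f_p),
        variant="equal-variance" if equal_var else "unequal-variance",
        t_pvalue=t_p,
        tier=_tier(t_p),
    )


def gc_content(
    source: str | CodonCounts, positions: str = "all"
) -> float:
    """(G+C)/(A+C+G+T); N is excluded from the denominator.

    ``positions="third"`` restricts to third codon positions (for a string
    the frame starts at offset 0; for CodonCounts it uses the counted
    codons). Returns NaN on an empty denominator.
    """
    if positions not in ("all", "third"):
        raise ValueError("positions must be 'all' or 'third'")
    comp: Counter[str] = Counter()
    if isinstance(source, CodonCounts):
        for codon, n in source.counts.items():
            if positions == "third":
                comp[codon[2]] += n
            else:
                for base in codon:
                    comp[base] += n
    else:
        seq = source.upper()
        if positions == "third":
            seq = seq[2::3]
        comp.update(seq)
    denom = sum(comp[b] for b in "ACGT")
    if denom == 0:
        return math.nan
    return (comp["G"] + comp["C"]) / denom
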