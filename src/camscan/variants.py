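"""SNP and INDEL calling against a lineage consensus reference.

Variants are called column-wise from each query strain's aligned row versus
an aligned reference (normally the majority consensus of the other
lineage). Substitutions are classified as transitions or transversions;
gap runs become insertion/deletion records with the empirical small/large
size split at 40 bp. Identity (fraction of events shared by a whole
strain group) and divergence (summed event length over alignment length)
statistics follow the same conventions as the per-category report tables.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._genetic_code import PURINES
from ._util import round_half_up
from .errors import AlignmentShapeError
from .io import GeneAlignment

#: boundary between "small" and "large" INDELs (inclusive for small)
SMALL_MAX_BP = 40

#: (size class, polarity) categories in fixed report order
CATEGORIES: tuple[tuple[str, str], ...] = (
    ("small", "insertion"),
    ("small", "deletion"),
    ("large", "insertion"),
    ("large", "deletion"),
)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    gene_id: str
    strain_id: str
    column: int  # 1-based alignment column
    ref: str
    alt: str
    klass: str  # "transition" | "transversion"


@dataclass(frozen=True)
class IndelRecord:
    gene_id: str
    start: int  # 1-based first column of the event
    length: int
    polarity: str  # "insertion" | "deletion" (relative to the reference)
    sequence: str
    carriers: tuple[str, ...]

    @property
    def size_class(self) -> str:
        return "small" if self.length <= SMALL_MAX_BP else "large"

    @property
    def frame_preserving(self) -> bool:
        return self.length % 3 == 0


@dataclass
class IndelSummary:
    """Per-category counts, shares, and identity/divergence statistics.

    ``n_records`` counts merged records (one per distinct event);
    ``n_events`` expands records by their carrier sets — both conventions
    appear in genome-scale tallies, so both are reported.
    """

    counts: dict[tuple[str, str], int]
    shares_pct: dict[tuple[str, str], float]
    n_records: int
    n_events: int
    frame_preserving_fraction: float
    identity: dict[tuple[str, str], float] | None = None
    divergence: dict[tuple[str, str], tuple[float, float]] | None = None


def classify_substitution(ref: str, alt: str) -> str:
    """Transition iff both bases are purines or both pyrimidines."""
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"bases must be in ACGT, got {ref!r}->{alt!r}")
    if ref == alt:
        raise ValueError(f"identical bases {ref!r} are not a substitution")
    same_class = (ref in PURINES) == (alt in PURINES)
    return "transition" if same_class else "transversion"


def _check_reference(aln: GeneAlignment, reference: str) -> None:
    if len(reference) != aln.length:
        raise AlignmentShapeError(
            f"{aln.gene_id}: reference length {len(reference)} != "
            f"alignment length {aln.length}"
        )


def call_snps(
    aln: GeneAlignment,
    reference: str,
    strains: Iterable[str] | None = None,
) -> list[SnpRecord]:
    """One record per (strain, column) where both sides hold differing bases.

    Columns where either side shows ``-`` or ``N`` are skipped — gaps belong
    to the INDEL caller and ambiguous bases carry no substitution signal.
    Columns adjacent to gaps are kept.
    """
    _check_reference(aln, reference)
    targets = list(strains) if strains is not None else list(aln.rows)
    out: list[SnpRecord] = []
    for strain in targets:
        row = aln.rows[strain]
        for i, (r, q) in enumerate(zip(reference, row)):
            if r in _BASES and q in _BASES and r != q:
                out.append(
                    SnpRecord(
                        gene_id=aln.gene_id,
                        strain_id=strain,
                        column=i + 1,
                        ref=r,
                        alt=q,
                        klass=classify_substitution(r, q),
                    )
                )
    return out


def tstv_ratio(snps: Sequence[SnpRecord]) -> float:
    """Transitions / transversions.

    Returns inf when transversions are absent but transitions exist, and
    NaN (undefined) when there are no substitutions at all.
    """
    ts = sum(1 for s in snps if s.klass == "transition")
    tv = len(snps) - ts
    if tv == 0:
        return math.inf if ts else math.nan
    return ts / tv


def _gap_runs(row: str, reference: str, mode: str):
    """Yield (start0, end0_exclusive) of maximal runs for one polarity."""
    if mode == "deletion":
        cond = [q == "-" and r != "-" for r, q in zip(reference, row)]
    else:  # insertion
        cond = [r == "-" and q != "-" for r, q in zip(reference, row)]
    i, n = 0, len(cond)
    while i < n:
        if cond[i]:
            j = i
            while j < n and cond[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def call_indels(
    aln: GeneAlignment,
    reference: str,
    strains: Iterable[str] | None = None,
    strain_order: Sequence[str] | None = None,
) -> list[IndelRecord]:
    """Maximal gap runs against the reference, merged across carriers.

    A deletion is a maximal run where the strain shows gaps over reference
    bases (sequence recorded from the reference); an insertion the reverse
    (sequence from the carrier). Events identical in (start, length,
    polarity, sequence) merge into a single record with the union carrier
    set; insertions at the same place with different sequences stay
    separate records.
    """
    _check_reference(aln, reference)
    targets = list(strains) if strains is not None else list(aln.rows)
    keyed: dict[tuple, list[str]] = defaultdict(list)
    for strain in targets:
        row = aln.rows[strain]
        for i, j in _gap_runs(row, reference, "deletion"):
            keyed[(i + 1, j - i, "deletion", reference[i:j])].append(strain)
        for i, j in _gap_runs(row, reference, "insertion"):
            keyed[(i + 1, j - i, "insertion", row[i:j])].append(strain)

    order = {s: k for k, s in enumerate(strain_order or targets)}
    records = [
        IndelRecord(
            gene_id=aln.gene_id,
            start=start,
            length=length,
            polarity=polarity,
            sequence=seq,
            carriers=tuple(sorted(carriers, key=lambda s: order.get(s, 0))),
        )
        for (start, length, polarity, seq), carriers in keyed.items()
    ]
    records.sort(key=lambda r: (r.start, r.polarity, r.length, r.sequence))
    return records


def indel_identity(
    records: Sequence[IndelRecord],
    category: tuple[str, str],
    group: Sequence[str],
) -> float:
    """Fraction of a category's records carried by every group member.

    NaN when the category holds no records.
    """
    if len(group) < 2:
        raise ValueError("identity needs a group of at least two strains")
    size_class, polarity = category
    cat = [
        r
        for r in records
        if r.size_class == size_class and r.polarity == polarity
    ]
    if not cat:
        return math.nan
    shared = sum(1 for r in cat if set(group) <= set(r.carriers))
    return shared / len(cat)


def indel_divergence(
    aln: GeneAlignment,
    records: Sequence[IndelRecord],
    category: tuple[str, str] | None = None,
) -> float:
    """Summed event length over the total alignment column count.

    The denominator deliberately includes gap columns (the alignment size,
    not the ungapped reference length).
    """
    if aln.length == 0:
        return 0.0
    sel = [r for r in records if r.gene_id == aln.gene_id]
    if category is not None:
        size_class, polarity = category
        sel = [
            r
            for r in sel
            if r.size_class == size_class and r.polarity == polarity
        ]
    return sum(r.length for r in sel) / aln.length


def summarize_indels(
    records: Sequence[IndelRecord],
    group: Sequence[str] | None = None,
    alignments: Mapping[str, GeneAlignment] | None = None,
) -> IndelSummary:
    """Counts, percentage shares (half-up, 2 dp) and per-category statistics.

    With ``group`` given, identity is the shared-by-all fraction per
    category; with ``alignments`` given, divergence is the per-alignment
    mean ± SD over alignments containing at least one event of the
    category.
    """
    counts = {cat: 0 for cat in CATEGORIES}
    for r in records:
        counts[(r.size_class, r.polarity)] += 1
    n = len(records)
    shares = {
        cat: round_half_up(100.0 * c / n, 2) if n else 0.0
        for cat, c in counts.items()
    }
    n_events = sum(len(r.carriers) for r in records)
    frame = (
        sum(1 for r in records if r.frame_preserving) / n if n else math.nan
    )

    identity = None
    if group is not None and n:
        identity = {
            cat: indel_identity(records, cat, group)
            for cat in CATEGORIES
            if counts[cat]
        }

    divergence = None
    if alignments is not None and n:
        divergence = {}
        by_gene: dict[str, list[IndelRecord]] = defaultdict(list)
        for r in records:
            by_gene[r.gene_id].append(r)
        for cat in CATEGORIES:
            vals = []
            for gene_id, recs in by_gene.items():
                if gene_id not in alignments:
                    continue
                if not any(
                    r.size_class == cat[0] and r.polarity == cat[1]
                    for r in recs
                ):
                    continue
                vals.append(indel_divergence(alignments[gene_id], recs, cat))
            if vals:
                mean = sum(vals) / len(vals)
                sd = (
                    math.sqrt(
                        sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
                    )
                    if len(vals) > 1
                    else 0.0
                )
                divergence[cat] = (mean, sd)

    return IndelSummary(
        counts=counts,
        shares_pct=shares,
        n_records=n,
        n_events=n_events,
        frame_preserving_fraction=frame,
        identity=identity,
        divergence=divergence,
    )
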