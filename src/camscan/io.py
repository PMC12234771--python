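"""Reading, writing and validation of aligned ortholog CDS data.

The package operates on per-gene aligned FASTA files (gap character ``-``)
whose headers name strains listed in a two-column strain table
(``strain_id<TAB>lineage``, exactly two lineages). This module provides the
containers for those inputs, lineage consensus construction, and the
degap/validation step that feeds codon statistics.

Alignment columns are 1-based closed intervals in every reported table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._genetic_code import STOP_CODONS
from .errors import (
    AlignmentShapeError,
    AlphabetError,
    MetadataError,
    SelectionError,
)

#: alphabet accepted in aligned rows
ALPHABET = frozenset("ACGTN-")

#: fixed symbol priority used to break consensus ties (highest first)
CONSENSUS_TIE_ORDER = "ACGTN-"


@dataclass(frozen=True)
class StrainTable:
    """Strain ids and their lineage labels (exactly two lineages)."""

    strains: tuple[str, ...]
    lineage_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.strains)) != len(self.strains):
            raise MetadataError("duplicate strain ids in strain table")
        if len(self.strains) < 2:
            raise MetadataError("strain table needs at least two strains")
        labels = set(self.lineage_of.values())
        if len(labels) != 2:
            raise MetadataError(
                f"expected exactly two lineages, found {sorted(labels)}"
            )
        for s in self.strains:
            if s not in self.lineage_of:
                raise MetadataError(f"strain {s!r} has no lineage label")

    @property
    def lineages(self) -> tuple[str, str]:
        """The two lineage labels, sorted."""
        return tuple(sorted(set(self.lineage_of.values())))  # type: ignore[return-value]

    def strains_in(self, lineage: str) -> tuple[str, ...]:
        sel = tuple(s for s in self.strains if self.lineage_of[s] == lineage)
        if not sel:
            raise SelectionError(f"no strains in lineage {lineage!r}")
        return sel

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StrainTable":
        strains: list[str] = []
        lineage: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MetadataError(f"malformed strain-table line: {line!r}")
            strains.append(parts[0])
            lineage[parts[0]] = parts[1]
        return cls(strains=tuple(strains), lineage_of=lineage)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# strain_id\tlineage"]
        lines += [f"{s}\t{self.lineage_of[s]}" for s in self.strains]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class GeneAlignment:
    """One gene's aligned CDS rows across named strains (equal lengths)."""

    gene_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(seq) for seq in self.rows.values()}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"{self.gene_id}: ragged alignment, row lengths {sorted(lengths)}"
            )
        for strain, seq in self.rows.items():
            bad = set(seq) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"{self.gene_id}/{strain}: illegal characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def column(self, col: int) -> dict[str, str]:
        """Symbols at 1-based column ``col``."""
        return {s: seq[col - 1] for s, seq in self.rows.items()}


@dataclass
class CdsRecord:
    """An ungapped coding sequence extracted from one alignment row.

    ``sequence`` excludes the terminal codon when ``drop_terminal`` was set
    (it is kept in ``terminal_codon``); ``length`` is the full ungapped
    length before that removal. ``eligible`` applies the strictly-over
    ``min_len`` filter used for codon statistics.
    """

    gene_id: str
    strain_id: str
    sequence: str
    length: int
    eligible: bool
    frame_ok: bool
    terminal_codon: str | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)


def read_alignment(
    path: str | Path, strains: StrainTable, gene_id: str | None = None
) -> GeneAlignment:
    """Read one aligned FASTA file; headers must resolve to known strain ids."""
    path = Path(path)
    gene = gene_id or path.stem
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid not in strains.lineage_of:
            raise MetadataError(f"{gene}: unknown strain header {sid!r}")
        rows[sid] = str(rec.seq).upper()
    if not rows:
        raise MetadataError(f"{gene}: no FASTA records in {path}")
    return GeneAlignment(gene_id=gene, rows=rows)


def write_alignment(aln: GeneAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=strain, description="")
        for strain, seq in aln.rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_panel(
    directory: str | Path, strains: StrainTable, pattern: str = "*.fasta"
) -> dict[str, GeneAlignment]:
    """Read every per-gene aligned FASTA in a directory, keyed by gene id."""
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise MetadataError(f"no {pattern} files found in {directory}")
    return {p.stem: read_alignment(p, strains) for p in files}


def build_consensus(
    aln: GeneAlignment, strains: StrainTable, lineage: str
) -> str:
    """Column-wise majority consensus over one lineage's rows.

    The gap character votes like any other symbol, so a lineage-wide
    deletion yields a gapped reference (required to polarise INDELs called
    against it). Ties break by the fixed priority A<C<G<T<N<-.
    """
    members = [s for s in strains.strains_in(lineage) if s in aln.rows]
    if not members:
        raise SelectionError(
            f"{aln.gene_id}: no rows for lineage {lineage!r} in alignment"
        )
    seqs = [aln.rows[s] for s in members]
    out = []
    for col in zip(*seqs):
        best = max(
            set(col),
            key=lambda sym: (col.count(sym), -CONSENSUS_TIE_ORDER.index(sym)),
        )
        out.append(best)
    return "".join(out)


def degap_and_validate(
    gene_id: str,
    strain_id: str,
    aligned_seq: str,
    min_len: int = 300,
    drop_terminal: bool = True,
    check_internal_stops: bool = True,
) -> CdsRecord:
    """Strip gaps from one alignment row and apply the codon-stat filters.

    Eligibility follows the strictly-over rule: a CDS of exactly
    ``min_len`` nt is ineligible. Frame violations (ungapped length not a
    multiple of 3) are flagged, never fatal — incomplete or pseudogenised
    copies stay in the panel with a warning so downstream counts can floor
    to whole codons.
    """
    ungapped = aligned_seq.replace("-", "")
    length = len(ungapped)
    notes: list[str] = []
    frame_ok = length % 3 == 0 and length > 0
    if not frame_ok:
        notes.append(f"length {length} not divisible by 3; frame suspect")
        warnings.warn(
            f"{gene_id}/{strain_id}: {notes[-1]}", stacklevel=2
        )

    terminal: str | None = None
    sequence = ungapped
    if drop_terminal and frame_ok and length >= 6:
        terminal = ungapped[-3:]
        sequence = ungapped[:-3]

    if check_internal_stops and frame_ok:
        body = sequence if terminal is not None else ungapped[:-3]
        internal = [
            body[i : i + 3]
            for i in range(0, len(body) - len(body) % 3, 3)
            if body[i : i + 3] in STOP_CODONS
        ]
        if internal:
            notes.append(f"{len(internal)} internal stop codon(s)")

    return CdsRecord(
        gene_id=gene_id,
        strain_id=strain_id,
        sequence=sequence,
        length=length,
        eligible=length > min_len,
        frame_ok=frame_ok,
        terminal_codon=terminal,
        warnings=tuple(notes),
    )


def degap_panel(
    panel: Mapping[str, GeneAlignment],
    strains: Iterable[str],
    min_len: int = 300,
    drop_terminal: bool = True,
) -> dict[tuple[str, str], CdsRecord]:
    """degap_and_validate over (gene, strain) pairs present in a panel."""
    out: dict[tuple[str, str], CdsRecord] = {}
    for gene_id, aln in panel.items():
        for strain in strains:
            if strain in aln.rows:
                out[(gene_id, strain)] = degap_and_validate(
                    gene_id,
                    strain,
                    aln.rows[strain],
                    min_len=min_len,
                    drop_terminal=drop_terminal,
                )
    return out
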