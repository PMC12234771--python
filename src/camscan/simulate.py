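"""Synthetic two-clade ortholog panels with planted, fully recorded truth.

The generator emulates the statistical structure the comparative pipeline
assumes: two clades (default 3 and 4 strains) of protein-coding genes,
AT-rich composition (GC ≈ 34%), within-clade identity far above
between-clade identity (most divergence on the two stem branches), INDELs
dominated by multiple-of-three lengths, and optional gene-specific codon
aversions planted by synonymous recoding.

Every mutational event is recorded in a :class:`SimTruth` channel with its
final alignment coordinates, so scanners can be checked against the exact
planted history. To keep that check exact, event footprints are kept
disjoint by construction (with one column of padding, and substitutions
restricted to ancestral columns); the emitted alignment is the true one —
no realignment step exists to introduce ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._genetic_code import STOP_CODONS, synonyms
from .errors import GenerationError, InfeasibilityError, SelectionError
from .io import CdsRecord, GeneAlignment, StrainTable, write_alignment

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class SimConfig:
    """Parameters of the two-clade panel generator.

    Defaults emulate the study conditions of the real panels: gene lengths
    spanning roughly 300–3300 nt, target GC 0.34, clades of 3 and 4
    strains, transition-rich substitutions (kappa = 3 gives an expected
    transition fraction of 0.6, i.e. ts/tv around 3 per gene), rare INDELs
    (order one merged event per gene alignment) with 85% multiple-of-three
    lengths, and stem branches carrying ~30x the tip-branch divergence so
    that within-clade identity stays near 99% while between-clade identity
    falls to the mid-80s.
    """

    n_genes: int = 40
    length_range: tuple[int, int] = (300, 3300)  # nt, multiples of 3
    gc: float = 0.34
    clade_sizes: tuple[int, int] = (3, 4)
    sub_rate: float = 0.002  # substitutions/site on a tip branch
    stem_scale: float = 30.0  # stem-branch rate multiplier
    kappa: float = 3.0  # transition/transversion rate ratio
    indel_rate: float = 0.00001  # events/site on a tip branch
    indel_geom_p: float = 0.5  # geometric parameter for small lengths
    frame_mass: float = 0.85  # probability an INDEL length is a multiple of 3
    large_prob: float = 0.08  # probability an INDEL is large (>40 bp)
    large_max: int = 120  # upper bound for large INDEL lengths
    seed: int = 42
    lineage_names: tuple[str, str] = ("A1", "A2")

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo % 3 or hi % 3 or lo < 30 or hi < lo:
            raise ValueError("length_range must be multiples of 3, >=30, lo<=hi")
        for name in ("indel_geom_p", "frame_mass", "large_prob", "gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("sub_rate", "indel_rate", "stem_scale", "kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.clade_sizes) < 1:
            raise ValueError("clade sizes must be >= 1")
        if self.large_max <= 41:
            raise ValueError("large_max must exceed 41")

    def strain_table(self) -> StrainTable:
        la, lb = self.lineage_names
        na, nb = self.clade_sizes
        strains = [f"{la}-{i + 1}" for i in range(na)]
        strains += [f"{lb}-{i + 1}" for i in range(nb)]
        lineage = {s: (la if s.startswith(la + "-") else lb) for s in strains}
        return StrainTable(strains=tuple(strains), lineage_of=lineage)


@dataclass
class SubEvent:
    gene_id: str
    column: int  # 1-based final alignment column
    ref: str  # base before the event on that branch (ancestral)
    alt: str
    strains: tuple[str, ...]

    @property
    def klass(self) -> str:
        return "transition" if _TRANSITION[self.ref] == self.alt else "transversion"


@dataclass
class IndelEvent:
    gene_id: str
    start: int  # 1-based first alignment column of the event
    length: int
    kind: str  # "insertion" | "deletion"
    sequence: str
    strains: tuple[str, ...]

    @property
    def frame_preserving(self) -> bool:
        return self.length % 3 == 0


@dataclass
class AversionEvent:
    gene_id: str
    codon: str
    strains: tuple[str, ...]


@dataclass
class SimTruth:
    """Complete planted-event history plus the aligned ancestor rows."""

    subs: list[SubEvent] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)
    aversions: list[AversionEvent] = field(default_factory=list)
    ancestor_rows: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subs": [asdict(e) for e in self.subs],
            "indels": [asdict(e) for e in self.indels],
            "aversions": [asdict(e) for e in self.aversions],
            "ancestor_rows": self.ancestor_rows,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            subs=[
                SubEvent(**{**e, "strains": tuple(e["strains"])})
                for e in payload["subs"]
            ],
            indels=[
                IndelEvent(**{**e, "strains": tuple(e["strains"])})
                for e in payload["indels"]
            ],
            aversions=[
                AversionEvent(**{**e, "strains": tuple(e["strains"])})
                for e in payload["aversions"]
            ],
            ancestor_rows=dict(payload["ancestor_rows"]),
        )


def _adjusted_gc(target: float) -> float:
    """Base-level GC that yields ``target`` GC after stop-codon rejection.

    Rejecting the AT-rich stop codons pulls the accepted-codon GC slightly
    above the raw base composition; a short bisection on the closed-form
    expectation compensates.
    """

    def accepted_gc(gc: float) -> float:
        a = (1 - gc) / 2  # P(A) = P(T)
        g = gc / 2  # P(G) = P(C)
        p_stop = a**3 + 2 * a * a * g  # TAA, TAG, TGA
        e_all = 3 * gc  # expected GC count per codon
        e_stop = 2 * a * a * g  # TAG and TGA carry one G each
        return (e_all - e_stop) / (3 * (1 - p_stop))

    lo, hi = 0.0, 1.0
    for _ in range(50):
        mid = (lo + hi) / 2
        if accepted_gc(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_ancestor(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[CdsRecord]:
    """Random ancestral CDSs: ATG start, clean frame, no internal stops.

    Gene lengths are uniform over multiples of 3 in ``length_range``
    (including start and stop); internal codons are drawn base-wise at the
    stop-rejection-adjusted GC.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    gc = _adjusted_gc(cfg.gc)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    lo, hi = cfg.length_range
    out: list[CdsRecord] = []
    for g in range(cfg.n_genes):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        internal: list[str] = []
        tries = 0
        while len(internal) < n_codons - 2:
            codon = "".join(rng.choice(bases, size=3, p=probs))
            tries += 1
            if codon in STOP_CODONS:
                if tries > 100 * n_codons:
                    raise GenerationError("stop-rejection sampling stalled")
                continue
            internal.append(codon)
        stop = str(rng.choice(np.array(STOP_CODONS)))
        seq = "ATG" + "".join(internal) + stop
        out.append(
            CdsRecord(
                gene_id=f"g{g + 1:04d}",
                strain_id="ancestor",
                sequence=seq,
                length=len(seq),
                eligible=len(seq) > 300,
                frame_ok=True,
            )
        )
    return out


def _draw_alt(base: str, kappa: float, rng: np.random.Generator) -> str:
    """kappa-weighted choice among the three alternative bases (K80-like)."""
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][int(rng.integers(2))]


def _draw_indel_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    frame = rng.random() < cfg.frame_mass
    if rng.random() < cfg.large_prob:
        lo, hi = 41, cfg.large_max
        pool = [
            n for n in range(lo, hi + 1) if (n % 3 == 0) == frame
        ]
        return int(rng.choice(pool))
    if frame:
        return 3 * min(int(rng.geometric(cfg.indel_geom_p)), 13)  # 3..39
    while True:
        n = int(rng.geometric(cfg.indel_geom_p))
        if n <= 40 and n % 3 != 0:
            return n


class _GeneEvolver:
    """Event-sourced evolution of one gene down the two-clade tree.

    Node states are lists of (column_id, base); ancestral columns have ids
    0..L-1, insertions allocate fresh ids spliced into a master column
    order. A shared ``blocked`` set keeps event footprints (padded by one
    column) disjoint across all branches, which guarantees that every
    recorded event survives verbatim into the emitted alignment.
    """

    def __init__(self, gene_id: str, ancestor: str, cfg: SimConfig,
                 rng: np.random.Generator):
        self.gene_id = gene_id
        self.cfg = cfg
        self.rng = rng
        self.L = len(ancestor)
        self.master: list[int] = list(range(self.L))
        self.next_id = self.L
        # keep start and stop codons intact
        self.blocked: set[int] = set(range(3)) | set(range(self.L - 3, self.L))
        self.root = [(i, b) for i, b in enumerate(ancestor)]
        self.subs: list[tuple[int, str, str, tuple[str, ...]]] = []
        self.indels: list[tuple[int, int, str, str, tuple[str, ...]]] = []
        # indel tuple: (first_col_id, length, kind, sequence, strains)

    # -- branch operators -------------------------------------------------

    def _substitute(self, state, scale, carriers):
        eligible = [
            k for k, (cid, _) in enumerate(state)
            if cid < self.L and cid not in self.blocked
        ]
        p = min(self.cfg.sub_rate * scale, 0.75)
        if not eligible or p <= 0:
            return
        n = int(self.rng.binomial(len(eligible), p))
        if n == 0:
            return
        picks = self.rng.choice(len(eligible), size=n, replace=False)
        for k in picks:
            idx = eligible[int(k)]
            cid, base = state[idx]
            alt = _draw_alt(base, self.cfg.kappa, self.rng)
            state[idx] = (cid, alt)
            self.blocked.add(cid)
            self.subs.append((cid, base, alt, carriers))

    def _try_deletion(self, state, length, carriers) -> bool:
        if len(state) <= length + 2:
            return False
        idx = int(self.rng.integers(0, len(state) - length))
        run = state[idx : idx + length]
        first = run[0][0]
        ids = [cid for cid, _ in run]
        if ids != list(range(first, first + length)) or first + length > self.L:
            return False
        footprint = set(range(first - 1, first + length + 1))
        if footprint & self.blocked:
            return False
        self.blocked |= footprint
        seq = "".join(b for _, b in run)
        del state[idx : idx + length]
        self.indels.append((first, length, "deletion", seq, carriers))
        return True

    def _try_insertion(self, state, length, carriers) -> bool:
        if len(state) < 2:
            return False
        idx = int(self.rng.integers(0, len(state) - 1))
        (cid1, _), (cid2, _) = state[idx], state[idx + 1]
        if cid2 != cid1 + 1 or cid2 >= self.L:
            return False
        if {cid1, cid2} & self.blocked:
            return False
        self.blocked |= {cid1, cid2}
        # tandem-copy the sequence immediately left of the anchor
        window = [b for _, b in state[max(0, idx - length + 1) : idx + 1]]
        seq = "".join(window[i % len(window)] for i in range(length))
        new_ids = list(range(self.next_id, self.next_id + length))
        self.next_id += length
        at = self.master.index(cid1) + 1
        self.master[at:at] = new_ids
        state[idx + 1 : idx + 1] = list(zip(new_ids, seq))
        self.indels.append((new_ids[0], length, "insertion", seq, carriers))
        return True

    def _indels_on_branch(self, state, scale, carriers):
        lam = self.cfg.indel_rate * scale * len(state)
        for _ in range(int(self.rng.poisson(lam))):
            length = _draw_indel_length(self.cfg, self.rng)
            kind = "deletion" if self.rng.random() < 0.5 else "insertion"
            attempt = self._try_deletion if kind == "deletion" else self._try_insertion
            for _ in range(50):  # placement is rejection-sampled
                if attempt(state, length, carriers):
                    break

    def _evolve_branch(self, parent, scale, carriers):
        state = list(parent)
        self._substitute(state, scale, carriers)
        self._indels_on_branch(state, scale, carriers)
        return state

    # -- whole-tree run ---------------------------------------------------

    def run(self, table: StrainTable):
        cfg = self.cfg
        la, lb = cfg.lineage_names
        clade_a = table.strains_in(la)
        clade_b = table.strains_in(lb)
        tips: dict[str, list] = {}
        stem_a = self._evolve_branch(self.root, cfg.stem_scale, clade_a)
        for s in clade_a:
            tips[s] = self._evolve_branch(stem_a, 1.0, (s,))
        stem_b = self._evolve_branch(self.root, cfg.stem_scale, clade_b)
        for s in clade_b:
            tips[s] = self._evolve_branch(stem_b, 1.0, (s,))

        pos = {cid: k for k, cid in enumerate(self.master)}
        width = len(self.master)

        def project(state) -> str:
            row = ["-"] * width
            for cid, base in state:
                row[pos[cid]] = base
            return "".join(row)

        rows = {s: project(tips[s]) for s in table.strains}
        aln = GeneAlignment(gene_id=self.gene_id, rows=rows)
        anc_row = project(self.root)

        subs = [
            SubEvent(self.gene_id, pos[cid] + 1, ref, alt, tuple(carriers))
            for cid, ref, alt, carriers in self.subs
        ]
        indels = [
            IndelEvent(
                self.gene_id, pos[first] + 1, length, kind, seq, tuple(carriers)
            )
            for first, length, kind, seq, carriers in self.indels
        ]
        return aln, anc_row, subs, indels


def evolve_panel(
    ancestors: Sequence[CdsRecord],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, GeneAlignment], SimTruth]:
    """Evolve every ancestral CDS down ((a1..),(b1..)) and emit alignments.

    Substitutions follow the per-site kappa-weighted draw, INDEL lengths
    the small-geometric / large-uniform law with the configured
    multiple-of-three mass; the true alignment is emitted directly from
    the event history and every event lands in the returned SimTruth.
    """
    if not ancestors:
        raise SelectionError("ancestor panel is empty")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    table = cfg.strain_table()
    panel: dict[str, GeneAlignment] = {}
    truth = SimTruth()
    for anc in ancestors:
        ev = _GeneEvolver(anc.gene_id, anc.sequence, cfg, rng)
        aln, anc_row, subs, indels = ev.run(table)
        panel[anc.gene_id] = aln
        truth.ancestor_rows[anc.gene_id] = anc_row
        truth.subs.extend(subs)
        truth.indels.extend(indels)
    return panel, truth


def plant_cam_difference(
    panel: Mapping[str, GeneAlignment],
    truth: SimTruth,
    table: StrainTable,
    gene_id: str,
    codon: str,
    target: str | Iterable[str],
    rng: np.random.Generator,
) -> None:
    """Synonymously recode away every use of ``codon`` in the target strains.

    ``target`` is a lineage label, a strain id, or an iterable of strain
    ids. The protein is unchanged (same amino acid, table 11); each base
    edit is logged as a substitution event and the aversion itself as an
    AversionEvent. Single-codon families (ATG, TGG) and stops are
    infeasible.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise InfeasibilityError(f"{codon} is a stop codon")
    alts = [c for c in synonyms(codon) if c != codon]
    if not alts:
        raise InfeasibilityError(f"{codon} has no synonymous alternative")

    if isinstance(target, str):
        if target in table.lineage_of:
            strains: tuple[str, ...] = (target,)
        else:
            strains = table.strains_in(target)
    else:
        strains = tuple(target)

    aln = panel[gene_id]
    for strain in strains:
        row = list(aln.rows[strain])
        cols = [i for i, ch in enumerate(row) if ch != "-"]
        if len(cols) % 3:
            raise InfeasibilityError(
                f"{gene_id}/{strain}: frame-broken copy cannot be recoded"
            )
        for k in range(len(cols) // 3):
            trip = cols[3 * k : 3 * k + 3]
            if "".join(row[i] for i in trip) != codon:
                continue
            new = alts[int(rng.integers(len(alts)))]
            for i, base in zip(trip, new):
                if row[i] != base:
                    truth.subs.append(
                        SubEvent(gene_id, i + 1, row[i], base, (strain,))
                    )
                    row[i] = base
        aln.rows[strain] = "".join(row)
    truth.aversions.append(AversionEvent(gene_id, codon, strains))


def replay_alignment(truth: SimTruth, gene_id: str, strain: str) -> str:
    """Rebuild one strain's aligned row from the ancestor row and its events.

    Event-sourcing round trip: applying the recorded substitutions,
    deletions and insertions (in recorded order) to the ancestor must
    reproduce the emitted alignment exactly.
    """
    row = list(truth.ancestor_rows[gene_id])
    for e in truth.subs:
        if e.gene_id == gene_id and strain in e.strains:
            row[e.column - 1] = e.alt
    for e in truth.indels:
        if e.gene_id != gene_id or strain not in e.strains:
            continue
        if e.kind == "deletion":
            for i in range(e.start - 1, e.start - 1 + e.length):
                row[i] = "-"
        else:
            for off, base in enumerate(e.sequence):
                row[e.start - 1 + off] = base
    return "".join(row)


def expected_variants(
    truth: SimTruth,
    table: StrainTable,
    reference_lineage: str,
) -> tuple[set[tuple], set[tuple], list]:
    """Translate planted events into the calls a consensus-reference scan must make.

    With the majority consensus of ``reference_lineage`` as reference and
    the other lineage's strains as queries:

    * events carried by query-side strains appear verbatim;
    * events on the reference clade's stem (all members) flip polarity —
      a stem substitution swaps ref/alt, a stem deletion shows up as an
      insertion in every query strain, and vice versa;
    * minority events within the reference clade are absorbed by the
      majority consensus and produce no call.

    Returns (snps, indels, overlaps): ``snps`` as (gene, strain, column,
    ref, alt) tuples, ``indels`` as (gene, start, length, polarity,
    sequence, carriers) tuples, and any events sharing columns in
    ``overlaps`` (excluded from the expectation — they are flagged, not
    silently merged).
    """
    ref_strains = set(table.strains_in(reference_lineage))
    other = [l for l in table.lineages if l != reference_lineage][0]
    query = list(table.strains_in(other))
    majority = len(ref_strains) // 2 + 1

    # detect overlapping footprints per gene
    claimed: dict[str, dict[int, int]] = {}
    footprints: list[tuple] = []
    for e in truth.subs:
        footprints.append((e, range(e.column, e.column + 1)))
    for e in truth.indels:
        footprints.append((e, range(e.start, e.start + e.length)))
    overlaps = []
    for e, cols in footprints:
        seen = claimed.setdefault(e.gene_id, {})
        for c in cols:
            seen[c] = seen.get(c, 0) + 1
    for e, cols in footprints:
        if any(claimed[e.gene_id][c] > 1 for c in cols):
            overlaps.append(e)
    bad = {id(e) for e in overlaps}

    snps: set[tuple] = set()
    indels: set[tuple] = set()
    for e in truth.subs:
        if id(e) in bad:
            continue
        carriers = set(e.strains)
        if carriers <= set(query):
            for s in carriers:
                snps.add((e.gene_id, s, e.column, e.ref, e.alt))
        elif carriers <= ref_strains and len(carriers) >= majority:
            for s in query:
                snps.add((e.gene_id, s, e.column, e.alt, e.ref))
    for e in truth.indels:
        if id(e) in bad:
            continue
        carriers = set(e.strains)
        if carriers <= set(query):
            indels.add(
                (e.gene_id, e.start, e.length, e.kind, e.sequence,
                 tuple(sorted(carriers)))
            )
        elif carriers <= ref_strains and len(carriers) >= majority:
            flipped = "insertion" if e.kind == "deletion" else "deletion"
            indels.add(
                (e.gene_id, e.start, e.length, flipped, e.sequence,
                 tuple(sorted(query)))
            )
    return snps, indels, overlaps


def write_panel(
    outdir: str | Path,
    panel: Mapping[str, GeneAlignment],
    table: StrainTable,
    truth: SimTruth | None = None,
) -> None:
    """Write per-gene aligned FASTA, the strain TSV, and the truth JSON."""
    outdir = Path(outdir)
    genes_dir = outdir / "genes"
    genes_dir.mkdir(parents=True, exist_ok=True)
    for gene_id, aln in panel.items():
        write_alignment(aln, genes_dir / f"{gene_id}.fasta")
    table.to_tsv(outdir / "strains.tsv")
    if truth is not None:
        truth.to_json(outdir / "truth.json")


def simulate_panel(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, GeneAlignment], SimTruth, StrainTable]:
    """Convenience: generate an ancestor set and evolve it in one call."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ancestors = generate_ancestor(cfg, rng)
    panel, truth = evolve_panel(ancestors, cfg, rng)
    return panel, truth, cfg.strain_table()
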