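"""Codon aversion motifs (CAMs) and the strain-identification decision map.

A gene's CAM in a strain is the set of sense codons the gene never uses
there — exactly the codons with RSCU = 0. Because aversion sets turn out
to be strain- and lineage-specific, they can serve as diagnostic markers:
this module finds lineage-diagnostic genes, strain-specific motifs, and
greedily builds a decision tree that identifies a strain from its per-gene
motifs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._genetic_code import REPORTABLE_CODONS
from .codonstats import CodonCounts
from .errors import ConstructionError
from .io import StrainTable

#: a motif: lexicographically sorted tuple of unused sense codons
Motif = tuple[str, ...]

#: motifs keyed by (gene_id, strain_id)
MotifTable = Mapping[tuple[str, str], Motif]


@dataclass(frozen=True)
class CamMotif:
    gene_id: str
    strain_id: str
    motif: Motif


@dataclass
class MapNode:
    """One node of the identification map.

    Internal nodes carry the chosen gene and one child per distinct motif
    value observed among the node's strains; tied alternative gene choices
    are recorded rather than discarded. A leaf with more than one strain
    is flagged non-separable.
    """

    strains: tuple[str, ...]
    gene_id: str | None = None
    branches: dict[Motif, "MapNode"] = field(default_factory=dict)
    alternatives: tuple[str, ...] = ()
    non_separable: bool = False

    @property
    def is_leaf(self) -> bool:
        return self.gene_id is None

    def leaves(self) -> list["MapNode"]:
        if self.is_leaf:
            return [self]
        out: list[MapNode] = []
        for child in self.branches.values():
            out.extend(child.leaves())
        return out


@dataclass
class IdentificationResult:
    """Outcome of descending the map with a query's motifs."""

    strain_id: str | None
    candidates: tuple[str, ...]
    status: str  # "identified" | "novel-motif" | "missing-gene" | "non-separable"


def extract_cam(counts: CodonCounts) -> CamMotif:
    """Sorted sense codons with zero count (single-codon families excluded).

    Ineligible genes are skipped by callers; extracting from one anyway is
    allowed but warned, since short genes avert codons by chance alone.
    """
    if not counts.eligible:
        warnings.warn(
            f"{counts.gene_id}/{counts.strain_id}: CAM from an ineligible "
            "gene (<=300 bp) is unreliable",
            stacklevel=2,
        )
    motif = tuple(
        c for c in REPORTABLE_CODONS if counts.counts.get(c, 0) == 0
    )
    return CamMotif(
        gene_id=counts.gene_id, strain_id=counts.strain_id, motif=motif
    )


def _genes_with_full_coverage(
    motifs: MotifTable, strains: Sequence[str]
) -> list[str]:
    genes = sorted({g for g, _ in motifs})
    out = []
    for g in genes:
        if all((g, s) in motifs for s in strains):
            out.append(g)
        else:
            warnings.warn(
                f"gene {g} lacks a motif for some strains; excluded",
                stacklevel=3,
            )
    return out


def group_diagnostic_genes(
    motifs: MotifTable, strains: StrainTable
) -> list[str]:
    """Genes whose motif values never straddle the two lineages.

    Diagnosticity requires the motif-value sets of the lineages to be
    disjoint: a motif observed in both lineages (even the empty motif)
    disqualifies the gene, guaranteeing error-free lineage assignment of
    unseen members.
    """
    la, lb = strains.lineages
    a, b = strains.strains_in(la), strains.strains_in(lb)
    out = []
    for g in _genes_with_full_coverage(motifs, strains.strains):
        vals_a = {motifs[(g, s)] for s in a}
        vals_b = {motifs[(g, s)] for s in b}
        if not vals_a & vals_b:
            out.append(g)
    return out


def strain_specific_cams(
    motifs: MotifTable, strains: StrainTable
) -> dict[str, list[str]]:
    """For each strain, genes whose motif is unique to it among all strains.

    A gene where every strain is unique is a "perfect" marker; genes that
    single out only some strains give the coarser tiers.
    """
    out: dict[str, list[str]] = {s: [] for s in strains.strains}
    for g in _genes_with_full_coverage(motifs, strains.strains):
        by_motif: dict[Motif, list[str]] = {}
        for s in strains.strains:
            by_motif.setdefault(motifs[(g, s)], []).append(s)
        for members in by_motif.values():
            if len(members) == 1:
                out[members[0]].append(g)
    return out


def gene_partition(
    motifs: MotifTable, gene_id: str, strains: Sequence[str]
) -> dict[Motif, tuple[str, ...]]:
    """Partition of ``strains`` by motif equality for one gene."""
    blocks: dict[Motif, list[str]] = {}
    for s in strains:
        blocks.setdefault(motifs[(gene_id, s)], []).append(s)
    return {m: tuple(ss) for m, ss in blocks.items()}


def build_identification_map(
    motifs: MotifTable,
    strains: StrainTable,
    lineage_first: bool = True,
) -> MapNode:
    """Greedy decision-tree construction over motif-equality partitions.

    At every node the gene splitting the node's strains into the most
    blocks wins; ties break by fewest total motif codons over the node's
    strains, then lexicographic gene id, with the tied genes kept as
    recorded alternatives. With ``lineage_first`` the root must use a
    lineage-diagnostic gene when one exists. Strains that no gene can
    separate end in a flagged non-separable leaf.
    """
    genes = _genes_with_full_coverage(motifs, strains.strains)
    if not genes:
        raise ConstructionError("no genes with full motif coverage")

    diagnostic = set(group_diagnostic_genes(motifs, strains)) if lineage_first else set()

    def best_gene(node_strains: Sequence[str], pool: Sequence[str], at_root: bool):
        candidates = pool
        if at_root and diagnostic:
            restricted = [g for g in pool if g in diagnostic]
            if restricted:
                candidates = restricted

        def score(g: str):
            part = gene_partition(motifs, g, node_strains)
            total = sum(len(motifs[(g, s)]) for s in node_strains)
            return (-len(part), total, g)

        ranked = sorted(candidates, key=score)
        top = ranked[0]
        top_key = score(top)[:2]
        ties = tuple(g for g in ranked[1:] if score(g)[:2] == top_key)
        return top, ties

    def grow(node_strains: tuple[str, ...], pool: list[str], at_root: bool) -> MapNode:
        if len(node_strains) == 1:
            return MapNode(strains=node_strains)
        if not pool:
            return MapNode(strains=node_strains, non_separable=True)
        gene, ties = best_gene(node_strains, pool, at_root)
        part = gene_partition(motifs, gene, node_strains)
        if len(part) == 1:
            # no remaining gene separates these strains
            if all(
                len(gene_partition(motifs, g, node_strains)) == 1 for g in pool
            ):
                return MapNode(strains=node_strains, non_separable=True)
        remaining = [g for g in pool if g != gene]
        node = MapNode(
            strains=node_strains, gene_id=gene, alternatives=ties
        )
        for motif_value, members in sorted(part.items()):
            node.branches[motif_value] = grow(members, remaining, False)
        return node

    return grow(tuple(strains.strains), genes, True)


def identify_strain(
    query: Mapping[str, Motif], tree: MapNode
) -> IdentificationResult:
    """Descend the map along matching motif branches.

    A novel motif (no matching branch) or a gene missing from the query
    stops the descent and returns the remaining candidate set — never a
    silent wrong answer.
    """
    node = tree
    while not node.is_leaf:
        if node.gene_id not in query:
            return IdentificationResult(
                None, node.strains, status="missing-gene"
            )
        value = tuple(sorted(query[node.gene_id]))
        child = node.branches.get(value)
        if child is None:
            return IdentificationResult(
                None, node.strains, status="novel-motif"
            )
        node = child
    if node.non_separable or len(node.strains) > 1:
        return IdentificationResult(
            None, node.strains, status="non-separable"
        )
    return IdentificationResult(
        node.strains[0], node.strains, status="identified"
    )


# -- export ----------------------------------------------------------------


def map_to_dict(node: MapNode) -> dict:
    if node.is_leaf:
        return {
            "strains": list(node.strains),
            "non_separable": node.non_separable,
        }
    return {
        "strains": list(node.strains),
        "gene": node.gene_id,
        "alternatives": list(node.alternatives),
        "branches": {
            ",".join(motif) if motif else "(none)": map_to_dict(child)
            for motif, child in node.branches.items()
        },
    }


def map_to_json(node: MapNode, indent: int = 1) -> str:
    return json.dumps(map_to_dict(node), indent=indent)


def map_to_dot(node: MapNode) -> str:
    """Graphviz DOT rendering of the identification map."""
    lines = ["digraph identification_map {", '  node [shape=box];']
    counter = [0]

    def walk(n: MapNode) -> str:
        name = f"n{counter[0]}"
        counter[0] += 1
        if n.is_leaf:
            label = "/".join(n.strains)
            if n.non_separable:
                label += r"\n(non-separable)"
            lines.append(f'  {name} [label="{label}", shape=ellipse];')
        else:
            label = n.gene_id
            if n.alternatives:
                label += r"\nalt: " + ",".join(n.alternatives)
            lines.append(f'  {name} [label="{label}"];')
            for motif, child in n.branches.items():
                cname = walk(child)
                edge = ",".join(motif) if motif else "(none)"
                lines.append(f'  {name} -> {cname} [label="{edge}"];')
        return name

    walk(node)
    lines.append("}")
    return "\n".join(lines)
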