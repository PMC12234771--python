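"""Codon aversion motifs, diagnostic genes and the identification map."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from camscan._genetic_code import REPORTABLE_CODONS, SENSE_CODONS
from camscan.cam import (
    build_identification_map,
    extract_cam,
    gene_partition,
    group_diagnostic_genes,
    identify_strain,
    map_to_dict,
    map_to_dot,
    strain_specific_cams,
)
from camscan.codonstats import CodonCounts
from camscan.errors import ConstructionError
from camscan.io import StrainTable


def _counts(present, gene="g", strain="s"):
    return CodonCounts(
        gene_id=gene, strain_id=strain,
        counts={c: 1 for c in present},
    )


def _table(n_a=3, n_b=4):
    strains = tuple(
        [f"A1-{i+1}" for i in range(n_a)] + [f"A2-{i+1}" for i in range(n_b)]
    )
    return StrainTable(strains, {s: s.split("-")[0] for s in strains})


def _motifs(table, assignment):
    """assignment: gene -> {strain: motif tuple}"""
    return {
        (g, s): tuple(sorted(m))
        for g, per_strain in assignment.items()
        for s, m in per_strain.items()
    }


class TestExtractCam:
    def test_all_codons_used_gives_empty_motif(self):
        cam = extract_cam(_counts(REPORTABLE_CODONS))
        assert cam.motif == ()

    def test_missing_codons_listed_sorted(self):
        present = [c for c in REPORTABLE_CODONS if c not in ("CGC", "TTA")]
        cam = extract_cam(_counts(present))
        assert cam.motif == ("CGC", "TTA")

    def test_singletons_never_in_motif(self):
        cam = extract_cam(_counts(["TTT"]))
        assert "ATG" not in cam.motif
        assert "TGG" not in cam.motif

    def test_ineligible_gene_warns(self):
        c = _counts(["TTT"])
        c.eligible = False
        with pytest.warns(UserWarning, match="ineligible"):
            extract_cam(c)

    @given(
        st.sets(st.sampled_from(SENSE_CODONS), max_size=61).map(sorted)
    )
    def test_motif_disjoint_from_used_codons(self, present):
        cam = extract_cam(_counts(present))
        assert not set(cam.motif) & set(present)

    @given(
        st.sets(st.sampled_from(REPORTABLE_CODONS), max_size=59),
        st.sampled_from(REPORTABLE_CODONS),
    )
    def test_adding_usage_shrinks_or_keeps_motif(self, present, extra):
        before = set(extract_cam(_counts(sorted(present))).motif)
        after = set(extract_cam(_counts(sorted(present | {extra}))).motif)
        assert after <= before


class TestGroupDiagnostic:
    def test_shared_motif_not_diagnostic(self):
        table = _table()
        motifs = _motifs(
            table, {"g1": {s: ("TTA",) for s in table.strains}}
        )
        assert group_diagnostic_genes(motifs, table) == []

    def test_disjoint_motifs_diagnostic(self):
        table = _table()
        motifs = _motifs(
            table,
            {"g1": {
                **{s: ("TTA",) for s in table.strains_in("A1")},
                **{s: ("CGC",) for s in table.strains_in("A2")},
            }},
        )
        assert group_diagnostic_genes(motifs, table) == ["g1"]

    def test_shared_empty_motif_breaks_diagnosticity(self):
        table = _table(n_a=2, n_b=2)
        motifs = _motifs(
            table,
            {"g1": {
                "A1-1": ("TTA",), "A1-2": (),
                "A2-1": (), "A2-2": ("CGC",),
            }},
        )
        assert group_diagnostic_genes(motifs, table) == []

    def test_partial_coverage_excluded_with_warning(self):
        table = _table(n_a=2, n_b=2)
        motifs = {("g1", "A1-1"): ("TTA",)}
        with pytest.warns(UserWarning, match="lacks a motif"):
            assert group_diagnostic_genes(motifs, table) == []


class TestStrainSpecific:
    def test_all_distinct_is_perfect_marker(self):
        table = _table(n_a=2, n_b=2)
        motifs = _motifs(
            table,
            {"g1": {
                "A1-1": ("AAT",), "A1-2": ("CCT",),
                "A2-1": ("GGT",), "A2-2": ("TTA",),
            }},
        )
        spec = strain_specific_cams(motifs, table)
        assert all(spec[s] == ["g1"] for s in table.strains)

    def test_shared_pair_not_separable(self):
        table = _table(n_a=2, n_b=2)
        motifs = _motifs(
            table,
            {"g1": {
                "A1-1": ("AAT",), "A1-2": ("CCT",),
                "A2-1": ("GGT",), "A2-2": ("GGT",),
            }},
        )
        spec = strain_specific_cams(motifs, table)
        assert spec["A1-1"] == ["g1"] and spec["A1-2"] == ["g1"]
        assert spec["A2-1"] == [] and spec["A2-2"] == []


def _distinct_motif_set(table):
    """One gene per strain carrying a strain-unique aversion, plus a
    lineage-diagnostic gene."""
    assignment = {}
    codons = ["AAT", "CCT", "GGT", "TTA", "CGC", "GCA", "ACA"]
    for i, strain in enumerate(table.strains):
        assignment[f"g_{strain}"] = {
            s: ((codons[i],) if s == strain else ()) for s in table.strains
        }
    assignment["g_lineage"] = {
        **{s: ("TCA",) for s in table.strains_in("A1")},
        **{s: ("AGA",) for s in table.strains_in("A2")},
    }
    return _motifs(table, assignment)


class TestIdentificationMap:
    def test_single_strain_is_one_leaf(self):
        table = _table(n_a=1, n_b=1)
        motifs = _motifs(
            table, {"g1": {"A1-1": ("TTA",), "A2-1": ()}}
        )
        tree = build_identification_map(motifs, table)
        assert all(len(l.strains) == 1 for l in tree.leaves())

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ConstructionError):
            build_identification_map({}, _table())

    def test_all_distinct_motifs_fully_separate(self):
        table = _table()
        motifs = _distinct_motif_set(table)
        tree = build_identification_map(motifs, table)
        leaves = tree.leaves()
        assert sorted(l.strains[0] for l in leaves) == sorted(table.strains)
        assert not any(l.non_separable for l in leaves)

    def test_lineage_first_uses_diagnostic_gene_at_root(self):
        table = _table()
        motifs = _distinct_motif_set(table)
        tree = build_identification_map(motifs, table, lineage_first=True)
        assert tree.gene_id == "g_lineage"

    def test_identical_strains_flagged_non_separable(self):
        table = _table(n_a=2, n_b=2)
        motifs = _motifs(
            table,
            {"g1": {
                "A1-1": ("AAT",), "A1-2": ("CCT",),
                "A2-1": ("GGT",), "A2-2": ("GGT",),
            }},
        )
        tree = build_identification_map(motifs, table, lineage_first=False)
        flagged = [l for l in tree.leaves() if l.non_separable]
        assert len(flagged) == 1
        assert flagged[0].strains == ("A2-1", "A2-2")

    def test_training_strains_identified(self):
        table = _table()
        motifs = _distinct_motif_set(table)
        tree = build_identification_map(motifs, table)
        genes = sorted({g for g, _ in motifs})
        for s in table.strains:
            query = {g: motifs[(g, s)] for g in genes}
            res = identify_strain(query, tree)
            assert res.status == "identified"
            assert res.strain_id == s

    def test_novel_motif_returns_ambiguity_set(self):
        table = _table()
        motifs = _distinct_motif_set(table)
        tree = build_identification_map(motifs, table)
        query = {g: ("NNN",) for g in {g for g, _ in motifs}}
        res = identify_strain(query, tree)
        assert res.status == "novel-motif"
        assert set(res.candidates) == set(table.strains)

    def test_missing_gene_gives_partial_descent(self):
        table = _table()
        motifs = _distinct_motif_set(table)
        tree = build_identification_map(motifs, table)
        res = identify_strain({}, tree)
        assert res.status == "missing-gene"
        assert set(res.candidates) == set(table.strains)

    def test_greedy_reaches_the_finest_achievable_partition(self):
        # exhaustive oracle: strains are separable iff they differ in any
        # gene, so the finest achievable partition is the equivalence
        # classes of "identical motifs everywhere"
        table = _table(n_a=2, n_b=2)
        pool = [(), ("AAT",), ("CCT",), ("AAT", "CCT")]
        genes = ["g1", "g2", "g3"]
        for combo in itertools.islice(
            itertools.product(range(4), repeat=len(genes) * 4), 0, 4096, 37
        ):
            motifs = {}
            for gi, g in enumerate(genes):
                for si, s in enumerate(table.strains):
                    motifs[(g, s)] = pool[combo[gi * 4 + si]]
            profile = {
                s: tuple(motifs[(g, s)] for g in genes)
                for s in table.strains
            }
            expected = {}
            for s, p in profile.items():
                expected.setdefault(p, []).append(s)
            expected_partition = sorted(
                tuple(sorted(v)) for v in expected.values()
            )
            tree = build_identification_map(
                motifs, table, lineage_first=False
            )
            got_partition = sorted(
                tuple(sorted(l.strains)) for l in tree.leaves()
            )
            assert got_partition == expected_partition

    def test_exports_render(self):
        table = _table()
        motifs = _distinct_motif_set(table)
        tree = build_identification_map(motifs, table)
        d = map_to_dict(tree)
        assert d["gene"] == "g_lineage"
        dot = map_to_dot(tree)
        assert dot.startswith("digraph") and "g_lineage" in dot

    def test_tie_recording(self):
        table = _table(n_a=2, n_b=2)
        motifs = _motifs(
            table,
            {
                "g1": {"A1-1": ("AAT",), "A1-2": (), "A2-1": (), "A2-2": ()},
                "g2": {"A1-1": ("CCT",), "A1-2": (), "A2-1": (), "A2-2": ()},
            },
        )
        tree = build_identification_map(motifs, table, lineage_first=False)
        assert tree.gene_id == "g1"  # lexicographic tie-break
        assert tree.alternatives == ("g2",)


class TestGenePartition:
    def test_partition_blocks(self):
        table = _table(n_a=2, n_b=2)
        motifs = _motifs(
            table,
            {"g1": {
                "A1-1": ("AAT",), "A1-2": ("AAT",),
                "A2-1": ("GGT",), "A2-2": (),
            }},
        )
        part = gene_partition(motifs, "g1", table.strains)
        assert part[("AAT",)] == ("A1-1", "A1-2")
        assert part[("GGT",)] == ("A2-1",)
        assert part[()] == ("A2-2",)
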