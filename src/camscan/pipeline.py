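"""End-to-end orchestration: simulate/load -> scan -> codon stats -> CAM map.

The pipeline reads (or simulates) a panel of per-gene aligned CDSs with a
two-lineage strain table, calls variants for the query lineage against the
reference lineage's majority consensus, computes per-gene codon-usage
statistics and group comparisons, extracts codon aversion motifs and the
identification map, and writes machine-readable TSV/JSON outputs plus a
summary report with reproducible provenance.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from ._genetic_code import CODON_TO_AA, STOP_CODONS
from ._util import round_half_up
from .cam import (
    build_identification_map,
    extract_cam,
    group_diagnostic_genes,
    identify_strain,
    map_to_dict,
    map_to_dot,
    strain_specific_cams,
)
from .codonstats import (
    CodonCounts,
    enc,
    enc_group_test,
    gc_content,
    pool_counts,
    pr2_point,
    rscu,
    stop_codon_tally,
    svc,
)
from .errors import CamscanError, SelectionError
from .io import (
    StrainTable,
    build_consensus,
    degap_panel,
    read_panel,
)
from .simulate import SimConfig, simulate_panel, write_panel
from .variants import (
    CATEGORIES,
    call_indels,
    call_snps,
    summarize_indels,
    tstv_ratio,
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input source)."""

    sim: SimConfig | None = None
    input_dir: str | None = None
    strains_path: str | None = None
    out_dir: str = "camscan_out"
    min_len: int = 300
    drop_terminal: bool = True
    fourfold_only: bool = True
    alpha: float = 0.05
    lineage_first: bool = True
    reference_lineage: str | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        has_sim = self.sim is not None
        has_dir = self.input_dir is not None
        if has_sim == has_dir:
            raise CamscanError(
                "config must name exactly one input source "
                "(a simulation config or an input directory)"
            )
        if has_dir and self.strains_path is None:
            raise CamscanError("an input directory needs a strain table path")


def percent_share(part: int, whole: int) -> float:
    """100*part/whole, rounded half-up to 2 decimals; NaN when whole = 0."""
    if whole == 0:
        return math.nan
    if not 0 <= part <= whole:
        raise ValueError(f"need 0 <= part <= whole, got {part}/{whole}")
    return round_half_up(100.0 * part / whole, 2)


def _provenance_config(cfg: RunConfig) -> dict:
    """Scientific parameters only: the output location does not affect results."""
    d = asdict(cfg)
    d.pop("out_dir", None)
    return d


def _cfg_hash(cfg: RunConfig) -> str:
    blob = json.dumps(_provenance_config(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _majority_terminal(terminals: list[str]) -> str | None:
    """Majority stop codon for a gene within a group; ties rank TAA<TAG<TGA."""
    stops = [t for t in terminals if t in STOP_CODONS]
    if not stops:
        return None
    return max(sorted(set(stops)), key=lambda c: (stops.count(c), -STOP_CODONS.index(c)))


@dataclass
class Report:
    """Bundled outputs of a run; ``summary`` is the JSON-serialisable core."""

    summary: dict
    snps: pd.DataFrame
    indels: pd.DataFrame
    codon_tables: dict[str, pd.DataFrame]
    cams: pd.DataFrame
    identification_map: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> Report:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- stage: input -----------------------------------------------------
    try:
        if cfg.sim is not None:
            rng = np.random.default_rng(cfg.seed)
            panel, truth, table = simulate_panel(cfg.sim, rng)
            write_panel(out_dir / "simulated", panel, table, truth)
        else:
            table = StrainTable.from_tsv(cfg.strains_path)
            panel = read_panel(cfg.input_dir, table)
    except CamscanError as exc:
        raise CamscanError(f"[input] {exc}") from exc

    la, lb = table.lineages
    ref_lineage = cfg.reference_lineage or la
    if ref_lineage not in (la, lb):
        raise CamscanError(f"[input] unknown reference lineage {ref_lineage!r}")
    query_lineage = lb if ref_lineage == la else la
    query_strains = list(table.strains_in(query_lineage))

    # ---- stage: variant scan ---------------------------------------------
    try:
        snp_rows, indel_rows = [], []
        all_records = []
        per_gene_tstv = {}
        for gene_id in sorted(panel):
            aln = panel[gene_id]
            present = [s for s in query_strains if s in aln.rows]
            if not present:
                continue
            try:
                reference = build_consensus(aln, table, ref_lineage)
            except SelectionError:
                continue
            snps = call_snps(aln, reference, present)
            records = call_indels(
                aln, reference, present, strain_order=table.strains
            )
            all_records.extend(records)
            if snps:
                per_gene_tstv[gene_id] = tstv_ratio(snps)
            snp_rows += [
                (s.gene_id, s.strain_id, s.column, s.ref, s.alt, s.klass)
                for s in snps
            ]
            indel_rows += [
                (
                    r.gene_id, r.start, r.length, r.polarity, r.size_class,
                    r.frame_preserving, ",".join(r.carriers), r.sequence,
                )
                for r in records
            ]
        snp_df = pd.DataFrame(
            snp_rows,
            columns=["gene", "strain", "column", "ref", "alt", "class"],
        )
        indel_df = pd.DataFrame(
            indel_rows,
            columns=[
                "gene", "start", "length", "polarity", "size_class",
                "frame_preserving", "carriers", "sequence",
            ],
        )
        indel_summary = summarize_indels(
            all_records, group=query_strains, alignments=panel
        )
    except CamscanError as exc:
        raise CamscanError(f"[variant-scan] {exc}") from exc

    # ---- stage: codon statistics -----------------------------------------
    try:
        from .codonstats import count_codons

        cds = degap_panel(
            panel, table.strains,
            min_len=cfg.min_len, drop_terminal=cfg.drop_terminal,
        )
        counts: dict[tuple[str, str], CodonCounts] = {
            key: count_codons(rec) for key, rec in cds.items()
        }
        eligible = {k: c for k, c in counts.items() if c.eligible}

        enc_rows, pr2_rows, gc_rows = [], [], []
        for (gene_id, strain), c in sorted(eligible.items()):
            e = enc(c)
            if e.defined:
                enc_rows.append((gene_id, strain, round_half_up(e.enc, 2)))
            p = pr2_point(c, fourfold_only=cfg.fourfold_only)
            if p.defined:
                pr2_rows.append(
                    (gene_id, strain,
                     round_half_up(p.x, 2), round_half_up(p.y, 2))
                )
            gc_rows.append(
                (gene_id, strain,
                 round_half_up(100 * gc_content(cds[(gene_id, strain)].sequence), 2))
            )
        enc_df = pd.DataFrame(enc_rows, columns=["gene", "strain", "enc"])
        pr2_df = pd.DataFrame(
            pr2_rows, columns=["gene", "strain", "gc_bias_x", "at_bias_y"]
        )
        gc_df = pd.DataFrame(gc_rows, columns=["gene", "strain", "gc_pct"])

        genes = sorted({g for g, _ in eligible})
        svc_rows, rscu_rows, test_rows = [], [], []
        stop_by_group: dict[str, list[str]] = {la: [], lb: []}
        for gene_id in genes:
            pooled = {}
            for lineage in (la, lb):
                members = [
                    eligible[(gene_id, s)]
                    for s in table.strains_in(lineage)
                    if (gene_id, s) in eligible
                ]
                if members:
                    pooled[lineage] = rscu(pool_counts(members, label=lineage))
                    for codon, value in sorted(pooled[lineage].values.items()):
                        rscu_rows.append(
                            (gene_id, lineage, codon, CODON_TO_AA[codon],
                             round_half_up(value, 3))
                        )
                term = _majority_terminal(
                    [
                        eligible[(gene_id, s)].terminal_codon
                        for s in table.strains_in(lineage)
                        if (gene_id, s) in eligible
                        and eligible[(gene_id, s)].terminal_codon
                    ]
                )
                if term:
                    stop_by_group[lineage].append(term)
            if len(pooled) == 2:
                codons = svc(pooled[la], pooled[lb])
                svc_rows.append((gene_id, len(codons), ",".join(codons)))

            vals = {
                lineage: [
                    float(enc(eligible[(gene_id, s)]).enc)
                    for s in table.strains_in(lineage)
                    if (gene_id, s) in eligible
                    and enc(eligible[(gene_id, s)]).defined
                ]
                for lineage in (la, lb)
            }
            if len(vals[la]) >= 2 and len(vals[lb]) >= 2:
                t = enc_group_test(gene_id, vals[la], vals[lb], alpha=cfg.alpha)
                test_rows.append(
                    (gene_id,
                     round_half_up(t.mean_a, 2), round_half_up(t.sd_a, 2),
                     round_half_up(t.mean_b, 2), round_half_up(t.sd_b, 2),
                     t.f_pvalue, t.variant, t.t_pvalue, t.tier)
                )
        svc_df = pd.DataFrame(svc_rows, columns=["gene", "n_svc", "svcs"])
        rscu_df = pd.DataFrame(
            rscu_rows, columns=["gene", "group", "codon", "aa", "rscu"]
        )
        test_df = pd.DataFrame(
            test_rows,
            columns=[
                "gene", f"mean_{la}", f"sd_{la}", f"mean_{lb}", f"sd_{lb}",
                "f_pvalue", "t_variant", "t_pvalue", "tier",
            ],
        )
        stop_rank = {
            lineage: stop_codon_tally(stop_by_group[lineage])
            for lineage in (la, lb)
        }
    except CamscanError as exc:
        raise CamscanError(f"[codon-stats] {exc}") from exc

    # ---- stage: CAM map ---------------------------------------------------
    try:
        motifs = {
            key: extract_cam(c).motif for key, c in eligible.items()
        }
        cam_rows = [
            (g, s, ",".join(m)) for (g, s), m in sorted(motifs.items())
        ]
        cam_df = pd.DataFrame(cam_rows, columns=["gene", "strain", "motif"])
        diagnostic = group_diagnostic_genes(motifs, table)
        specific = strain_specific_cams(motifs, table)
        tree = None
        map_dict: dict = {}
        training_accuracy = math.nan
        n_non_separable = 0
        covered = [
            g for g in genes
            if all((g, s) in motifs for s in table.strains)
        ]
        if covered:
            tree = build_identification_map(
                motifs, table, lineage_first=cfg.lineage_first
            )
            map_dict = map_to_dict(tree)
            leaves = tree.leaves()
            n_non_separable = sum(1 for leaf in leaves if leaf.non_separable)
            hits = 0
            for s in table.strains:
                query = {g: motifs[(g, s)] for g in covered}
                res = identify_strain(query, tree)
                hits += res.strain_id == s
            training_accuracy = hits / len(table.strains)
    except CamscanError as exc:
        raise CamscanError(f"[cam] {exc}") from exc

    # ---- stage: report ----------------------------------------------------
    n_records = indel_summary.n_records
    summary = {
        "provenance": {
            "camscan_version": __version__,
            "seed": cfg.seed,
            "config": _provenance_config(cfg),
            "config_hash": _cfg_hash(cfg),
        },
        "panel": {
            "n_genes": len(panel),
            "strains": list(table.strains),
            "lineages": [la, lb],
            "reference_lineage": ref_lineage,
            "mean_gc_pct": round_half_up(float(gc_df["gc_pct"].mean()), 2)
            if len(gc_df) else math.nan,
        },
        "snps": {
            "n_snps": int(len(snp_df)),
            "per_strain": {
                s: int((snp_df["strain"] == s).sum()) for s in query_strains
            },
            "tstv_overall": (
                float(
                    (snp_df["class"] == "transition").sum()
                    / max((snp_df["class"] == "transversion").sum(), 1)
                )
                if len(snp_df)
                else math.nan
            ),
            "tstv_per_gene": {
                g: (None if math.isinf(v) else round(v, 4))
                for g, v in sorted(per_gene_tstv.items())
            },
        },
        "indels": {
            "n_records": n_records,
            "n_events": indel_summary.n_events,
            "counts": {
                f"{sc}_{pol}": indel_summary.counts[(sc, pol)]
                for sc, pol in CATEGORIES
            },
            "shares_pct": {
                f"{sc}_{pol}": indel_summary.shares_pct[(sc, pol)]
                for sc, pol in CATEGORIES
            },
            "frame_preserving_fraction": (
                None
                if math.isnan(indel_summary.frame_preserving_fraction)
                else round(indel_summary.frame_preserving_fraction, 4)
            ),
            "identity": {
                f"{sc}_{pol}": round(v, 4)
                for (sc, pol), v in (indel_summary.identity or {}).items()
                if not math.isnan(v)
            },
            "divergence": {
                f"{sc}_{pol}": [round(m, 4), round(sd, 4)]
                for (sc, pol), (m, sd) in (indel_summary.divergence or {}).items()
            },
        },
        "codon_usage": {
            "n_eligible_gene_strain": len(eligible),
            "mean_enc": round_half_up(float(enc_df["enc"].mean()), 2)
            if len(enc_df) else math.nan,
            "stop_codon_ranking": {
                lineage: [[c, n] for c, n in stop_rank[lineage]]
                for lineage in (la, lb)
            },
            "n_significant_enc_genes": int(
                (test_df["tier"] != ">0.05").sum()
            ) if len(test_df) else 0,
        },
        "cam": {
            "n_group_diagnostic_genes": len(diagnostic),
            "group_diagnostic_genes": diagnostic,
            "n_strain_specific": {
                s: len(gs) for s, gs in specific.items()
            },
            "n_non_separable_leaves": n_non_separable,
            "training_accuracy": (
                None if math.isnan(training_accuracy) else training_accuracy
            ),
        },
    }

    # ---- write outputs ----------------------------------------------------
    def _tsv(df: pd.DataFrame, name: str, comment: str) -> None:
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(f"# {comment}\n")
            df.to_csv(fh, sep="\t", index=False)

    _tsv(snp_df, "snps.tsv", "SNPs vs reference-lineage consensus (1-based columns)")
    _tsv(indel_df, "indels.tsv", "merged INDEL records vs reference consensus")
    _tsv(enc_df, "enc.tsv", "effective number of codons per eligible gene/strain")
    _tsv(pr2_df, "pr2.tsv", "PR2 third-position bias coordinates")
    _tsv(gc_df, "gc.tsv", "GC percentage per eligible gene/strain")
    _tsv(rscu_df, "rscu.tsv", "pooled per-lineage RSCU values")
    _tsv(svc_df, "svc.tsv", "significantly variable codons per gene")
    _tsv(test_df, "group_tests.tsv", "F-test-then-t-test ENC comparisons")
    _tsv(cam_df, "cams.tsv", "codon aversion motifs per gene/strain")
    (out_dir / "report.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    if tree is not None:
        (out_dir / "identification_map.json").write_text(
            json.dumps(map_dict, indent=1)
        )
        (out_dir / "identification_map.dot").write_text(map_to_dot(tree))

    return Report(
        summary=summary,
        snps=snp_df,
        indels=indel_df,
        codon_tables={
            "enc": enc_df, "pr2": pr2_df, "gc": gc_df, "rscu": rscu_df,
            "svc": svc_df, "group_tests": test_df,
        },
        cams=cam_df,
        identification_map=map_dict,
    )
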