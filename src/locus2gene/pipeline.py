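"""End-to-end orchestration: fixture generation, configuration, pipeline run.

``run_pipeline`` executes the full analysis from one config: marker QC ->
associated regions -> cis-eQTL mapping and instrument selection -> the four
prioritization lines -> co-regulation clustering -> trans-mediation scan ->
(optionally) the gene-set permutation DE statistic.  Every stage writes a
TSV, a consolidated per-gene evidence table joins them, and a manifest
records every threshold actually used.  The run is a pure function of
(inputs, config): repeated runs produce byte-identical outputs.

``make_fixture`` writes a ready-to-run synthetic cohort with planted ground
truth at two scales (tiny: 200 x 500 x 50; standard: 2,000 x 5,000 x 500).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort_io, coregulation, eqtl, mediation, permde, prioritize, regions as regions_mod
from .syndata import (
    DeStatTable,
    PlantedArchitecture,
    derive_annotation,
    simulate_component_matrix,
    simulate_de_experiment,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the analysis' standard operating point: clump and
    instrument entry at p < 5e-6, clump r2 > 0.5 within +/- 250 kb, +/- 1 Mb
    region flanks, +/- 1.5 Mb cis window, trans-eQTL p < 5e-8, H4 > 0.9,
    LD-overlap r2 > 0.8, co-expression |r| > 0.1, family-wise alpha 0.05 for
    both the MR and mediation Bonferroni corrections.
    """

    gwas: str = ""
    genotypes: str = ""
    expression: str = ""
    annotation: str = ""
    component_matrix: str | None = None
    depict: str | None = None
    de_stats: str | None = None
    de_gene_set: str | None = None
    out_dir: str = "out"
    seed: int = 1

    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    clump_p: float = 5e-6
    clump_r2: float = 0.5
    clump_window_kb: float = 250.0
    flank_mb: float = 1.0
    exclude: list[list] = field(default_factory=lambda: [["6", 25e6, 37e6]])
    cis_window_bp: float = 1.5e6
    instrument_p: float = 5e-6
    instrument_r2_guard: float = 0.9
    mr_family_alpha: float = 0.05
    min_instruments: int = 3
    h4_min: float = 0.9
    ld_overlap_r2: float = 0.8
    eqtl_sig: float = 5e-6
    gwas_sig: float = 5e-6
    genome_wide: float = 5e-8
    trans_p: float = 5e-8
    coexpression_r: float = 0.1
    mediation_family_alpha: float = 0.05
    n_clusters: int = 4
    n_perm: int = 1_000_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

_SCALES = {
    # n_individuals, variants/chrom, n_chroms, genes, noise_sd, cis_beta,
    # chain_coef, gwas_beta (liability per allele), theta (liability per SD
    # mediator expression), n_chain_targets
    "tiny": dict(n=200, vpc=100, chroms=5, genes=50, noise=0.5, cis=1.2,
                 chain=1.0, gwas=1.4, theta=1.3, targets=5, gwas_only=False,
                 spacing=10_000, block=25, pool=30),
    "standard": dict(n=2000, vpc=500, chroms=10, genes=500, noise=1.0, cis=0.6,
                     chain=0.6, gwas=0.4, theta=0.45, targets=41, gwas_only=True,
                     spacing=5_000, block=50, pool=30),
}


def _fixture_architecture(scale: str, seed: int):
    p = _SCALES[scale]
    layout = []
    blocks = []
    idx = 0
    for c in range(p["chroms"]):
        for v in range(p["vpc"]):
            layout.append((str(c + 1), 1_000_000 + v * p["spacing"], 0.2 + 0.3 * ((v * 7) % 10) / 9))
        for b0 in range(0, p["vpc"], p["block"]):
            blocks.append((idx + b0, idx + min(b0 + p["block"], p["vpc"]), p["pool"]))
        idx += p["vpc"]
    geno = simulate_genotypes(p["n"], layout, blocks, seed=seed)

    def vid(chrom: int, offset: int) -> str:
        return f"snp_{chrom}_{1_000_000 + offset * p['spacing']}"

    mid = p["block"] // 2
    cis_effects: dict[str, tuple[str, float]] = {}
    gwas_causal: list[tuple[str, float]] = []
    shared_flags: dict[str, str] = {}

    # chrom 1: shared colocalization locus
    cis_effects["cis_shared_a"] = (vid(1, mid), p["cis"])
    gwas_causal.append((vid(1, mid), p["gwas"]))
    shared_flags["locus_chr1"] = "shared"
    # chrom 2: distinct locus (GWAS causal in the next LD block)
    cis_effects["cis_distinct_b"] = (vid(2, mid), p["cis"])
    gwas_causal.append((vid(2, p["block"] + mid), p["gwas"]))
    shared_flags["locus_chr2"] = "distinct"
    # chrom 3: master-regulator locus, three independent cis variants for MR
    med_betas = (0.9 * p["cis"], 0.7 * p["cis"], 0.55 * p["cis"])
    med_variants = [vid(3, mid), vid(3, p["block"] + mid), vid(3, 2 * p["block"] + mid)]
    cis_effects["mediator_gene"] = (med_variants[0], med_betas[0])
    for v, b in zip(med_variants, med_betas):
        gwas_causal.append((v, p["theta"] * b))
    shared_flags["locus_chr3"] = "shared"
    if p["gwas_only"]:
        # chrom 4: GWAS-only locus, no eQTL anywhere nearby
        gwas_causal.append((vid(4, mid), p["gwas"]))
        shared_flags["locus_chr4"] = "null"

    targets = [f"trans_target_{i:03d}" for i in range(p["targets"])]
    chains = [("mediator_gene", t, p["chain"]) for t in targets]
    n_bg = p["genes"] - len(cis_effects) - len(targets)
    background = [f"background_{i:03d}" for i in range(n_bg)]

    arch = PlantedArchitecture(
        cis_effects=cis_effects,
        mediation_chains=chains,
        gwas_causal=gwas_causal,
        shared_flags=shared_flags,
        de_target_set=["mediator_gene"] + targets,
        background_genes=background,
    )
    return geno, arch, med_variants, med_betas


def make_fixture(scale: str, seed: int, out_dir: str | Path) -> PipelineConfig:
    """Write an on-disk synthetic cohort with truth tables and a run config."""
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    geno, arch, med_variants, med_betas = _fixture_architecture(scale, seed)
    p = _SCALES[scale]

    # secondary mediator cis effects enter expression directly
    expr = simulate_expression(geno, arch, noise_sd=p["noise"], seed=seed + 1)
    med_idx = expr.genes.index("mediator_gene")
    for v, b in zip(med_variants[1:], med_betas[1:]):
        extra = b * geno.dosage_of(v)
        expr.values[:, med_idx] += extra
        for med, tgt, coef in arch.mediation_chains:
            expr.values[:, expr.genes.index(tgt)] += coef * extra

    gwas = simulate_gwas(geno, arch.gwas_causal, prevalence_threshold=0.5, seed=seed + 2)
    annotation = derive_annotation(arch, geno)
    comp = simulate_component_matrix(
        expr.genes,
        n_components=200,
        cluster_labels={g: hash_cluster(g) for g in expr.genes},
        seed=seed + 3,
    )
    de = simulate_de_experiment(
        n_genes=len(expr.genes),
        target_set=arch.de_target_set,
        shift=4.0,
        n_replicates=3,
        correlation=0.3,
        seed=seed + 4,
        genes=expr.genes,
    )
    depict = pd.DataFrame(
        {"gene_id": ["cis_shared_a"], "depict_fdr": [0.01]}
    )

    if scale == "tiny":
        cohort_io.write_vcf(geno, out / "genotypes.vcf")
        geno_path = "genotypes.vcf"
    else:
        cohort_io.write_dosage_matrix(geno, out / "genotypes.tsv")
        geno_path = "genotypes.tsv"
    cohort_io.write_expression(expr, out / "expression.tsv")
    cohort_io.write_gwas(gwas, out / "gwas.tsv")
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    comp.to_csv(out / "components.tsv", sep="\t", float_format=_FLOAT_FMT)
    de.to_frame().to_csv(out / "de_stats.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    depict.to_csv(out / "depict.tsv", sep="\t", index=False)
    (out / "de_set.txt").write_text("\n".join(arch.de_target_set) + "\n")

    # truth tables
    pd.DataFrame(
        [(g, v, b) for g, (v, b) in arch.cis_effects.items()],
        columns=["gene_id", "variant_id", "beta"],
    ).to_csv(out / "truth" / "cis_effects.tsv", sep="\t", index=False)
    pd.DataFrame(
        arch.mediation_chains, columns=["mediator_gene", "target_gene", "coef"]
    ).to_csv(out / "truth" / "chains.tsv", sep="\t", index=False)
    pd.DataFrame(arch.gwas_causal, columns=["variant_id", "beta"]).to_csv(
        out / "truth" / "gwas_causal.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(arch.shared_flags.items()), columns=["locus", "flag"]
    ).to_csv(out / "truth" / "shared_flags.tsv", sep="\t", index=False)

    config = PipelineConfig(
        gwas=geno_rel(out, "gwas.tsv"),
        genotypes=geno_rel(out, geno_path),
        expression=geno_rel(out, "expression.tsv"),
        annotation=geno_rel(out, "annotation.tsv"),
        component_matrix=geno_rel(out, "components.tsv"),
        depict=geno_rel(out, "depict.tsv"),
        de_stats=geno_rel(out, "de_stats.tsv"),
        de_gene_set=geno_rel(out, "de_set.txt"),
        out_dir=geno_rel(out, "results"),
        seed=seed,
        n_perm=5000,
    )
    config.to_yaml(out / "config.yaml")
    return config


def geno_rel(out: Path, name: str) -> str:
    return str(out / name)


def hash_cluster(gene_id: str) -> int:
    """Deterministic 4-way co-regulation cluster assignment for fixtures."""
    if gene_id.startswith("cis_"):
        return 0
    if gene_id == "mediator_gene" or gene_id.startswith("trans_target"):
        return 1
    return 2 + (sum(ord(c) for c in gene_id) % 2)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full locus-to-gene analysis; returns the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gwas = cohort_io.read_gwas(config.gwas)
    geno = cohort_io.read_genotypes(config.genotypes)
    expr = cohort_io.read_expression(config.expression)
    annotation = cohort_io.read_annotation(config.annotation)
    if expr.individuals != geno.individuals:
        raise ValueError("pipeline: expression and genotype sample order differ")

    # --- stage 1: marker QC -------------------------------------------------
    geno, qc_report = cohort_io.filter_variants(geno, config.maf_min, config.hwe_p_min)
    qc_report.to_csv(out / "qc_removed.tsv", sep="\t", index=False)

    # --- stage 2: regions ---------------------------------------------------
    for chrom, start, end in config.exclude:
        gwas = regions_mod.exclude_interval(gwas, str(chrom), float(start), float(end))
    leads = regions_mod.clump(
        gwas, geno, config.clump_p, config.clump_r2, config.clump_window_kb
    )
    region_table = regions_mod.build_regions(leads, flank_bp=config.flank_mb * 1e6)
    gene_map = regions_mod.candidate_genes(region_table, annotation)
    leads.to_csv(out / "leads.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    region_table.to_csv(out / "regions.tsv", sep="\t", index=False)
    cohort_io.write_bed(region_table, out / "regions.bed")

    candidates = sorted({g for gs in gene_map.values() for g in gs if g in expr})
    region_of_gene = {
        g: rid for rid, gs in sorted(gene_map.items()) for g in gs
    }

    # --- stage 3: cis eQTLs and instruments ---------------------------------
    cis_expr_idx = [expr.genes.index(g) for g in candidates]
    from .syndata import ExpressionMatrix

    cand_expr = ExpressionMatrix(
        individuals=list(expr.individuals),
        genes=candidates,
        values=expr.values[:, cis_expr_idx] if candidates else np.empty((len(expr.individuals), 0)),
    )
    cis_records = (
        eqtl.map_eqtl(cand_expr, geno, annotation, scope="cis",
                      cis_window_bp=config.cis_window_bp)
        if candidates else pd.DataFrame(
            columns=["gene_id", "variant_id", "chrom", "pos", "beta", "se", "p_value", "relation"])
    )
    cis_records.to_csv(out / "cis_eqtl.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    instruments: dict[str, eqtl.InstrumentSet] = {}
    for g in candidates:
        inst = eqtl.select_instruments(
            g, cand_expr, geno, annotation,
            p_enter=config.instrument_p, r2_guard=config.instrument_r2_guard,
            cis_window_bp=config.cis_window_bp,
        )
        if len(inst):
            instruments[g] = inst
    inst_rows = [
        inst.table.assign(gene_id=g) for g, inst in sorted(instruments.items())
    ]
    inst_table = (
        pd.concat(inst_rows, ignore_index=True)
        if inst_rows else pd.DataFrame(columns=["variant_id", "beta", "se", "p_value", "step", "gene_id"])
    )
    inst_table.to_csv(out / "instruments.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    # --- stage 4: prioritization --------------------------------------------
    depict_flags: dict[str, bool] = {}
    if config.depict:
        dep = pd.read_csv(config.depict, sep="\t")
        if "depict_fdr" in dep.columns:
            depict_flags = {r["gene_id"]: bool(r["depict_fdr"] < 0.05) for _, r in dep.iterrows()}
        else:
            depict_flags = {r["gene_id"]: bool(r["depict_flag"]) for _, r in dep.iterrows()}

    mr_testable = [
        g for g in candidates
        if g in instruments and len(instruments[g]) >= config.min_instruments
    ]
    mr_alpha = (
        prioritize.bonferroni_alpha(config.mr_family_alpha, len(mr_testable))
        if mr_testable else config.mr_family_alpha
    )

    gwas_by_variant = gwas.set_index("variant_id")
    evidence_rows = []
    for g in candidates:
        rid = region_of_gene.get(g)
        region = region_table[region_table["region_id"] == rid]
        gwas_slice = gwas[
            (gwas["chrom"].astype(str) == str(region.iloc[0]["chrom"]))
            & (gwas["pos"] >= region.iloc[0]["start"])
            & (gwas["pos"] <= region.iloc[0]["end"])
        ] if len(region) else gwas.iloc[0:0]
        gene_cis = cis_records[cis_records["gene_id"] == g]
        eqtl_slice = gene_cis[gene_cis["variant_id"].isin(gwas_slice["variant_id"])]

        mr = (
            prioritize.mr_ivw(
                instruments[g], gwas, eqtl_alleles=None,
                min_instruments=config.min_instruments, seed=config.seed,
            )
            if g in mr_testable else None
        )
        coloc = (
            prioritize.coloc_abf(
                gwas_slice[["variant_id", "beta", "se"]],
                eqtl_slice[["variant_id", "beta", "se"]],
                gene_id=g, region_id=rid or "",
            )
            if len(eqtl_slice) >= 2 else None
        )
        ld_flag = None
        top_inst = instruments[g].top_variant() if g in instruments else None
        top_gwas_variant = (
            gwas_slice.sort_values(["p_value", "variant_id"]).iloc[0]["variant_id"]
            if len(gwas_slice) else None
        )
        if top_inst is not None and top_gwas_variant is not None:
            ld_flag = prioritize.ld_overlap(
                top_inst, top_gwas_variant, geno, config.ld_overlap_r2
            )
        rec = prioritize.aggregate_evidence(
            g, mr, coloc, ld_flag, depict_flags.get(g), mr_alpha, config.h4_min
        )

        direction = "?"
        top_eqtl_variant = top_inst
        if top_eqtl_variant is None and len(eqtl_slice):
            top_eqtl_variant = eqtl_slice.sort_values(
                ["p_value", "variant_id"]).iloc[0]["variant_id"]
        if top_eqtl_variant is not None and top_gwas_variant is not None:
            pair_e = _top_pair(top_eqtl_variant, gene_cis, gwas_by_variant, geno)
            pair_g = _top_pair(top_gwas_variant, gene_cis, gwas_by_variant, geno)
            if pair_e is not None and pair_g is not None:
                direction = prioritize.assign_direction(
                    pair_e, pair_g, mr,
                    eqtl_sig=config.eqtl_sig, gwas_sig=config.gwas_sig,
                    genome_wide=config.genome_wide, mr_alpha=mr_alpha,
                )
        rec.direction = direction

        evidence_rows.append(
            {
                "gene_id": g,
                "region_id": rid,
                "mr_ivw": _flag_str(rec.mr_ivw),
                "coloc": _flag_str(rec.coloc),
                "ld_overlap": _flag_str(rec.ld_overlap),
                "depict_external": _flag_str(rec.depict_external),
                "lines_of_evidence": rec.lines_of_evidence,
                "direction": rec.direction,
                "mr_estimate": mr.estimate if mr else np.nan,
                "mr_se": mr.se if mr else np.nan,
                "mr_p": mr.p_value if mr else np.nan,
                "mr_n_instruments": mr.n_instruments if mr else 0,
                "cochran_q": mr.cochran_q if mr else np.nan,
                "cochran_q_p": mr.q_p if mr else np.nan,
                "weighted_median": mr.weighted_median_estimate if mr else np.nan,
                **{
                    f"pp_h{i}": (coloc.pp[i] if coloc else np.nan) for i in range(5)
                },
            }
        )
    evidence = pd.DataFrame(evidence_rows)
    evidence.to_csv(out / "evidence.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    prioritized = (
        evidence[evidence["lines_of_evidence"] >= 1]["gene_id"].tolist()
        if len(evidence) else []
    )

    # --- stage 5: co-regulation clustering ----------------------------------
    clusters = None
    if config.component_matrix and len(prioritized) >= 2:
        comp = pd.read_csv(config.component_matrix, sep="\t", index_col=0)
        usable = [g for g in prioritized if g in comp.index]
        k = min(config.n_clusters, len(usable))
        if k >= 1 and len(usable) >= 2:
            zmat = coregulation.profile_correlate(usable, comp)
            labels, _linkage, newick = coregulation.cluster_genes(zmat, k=k)
            clusters = pd.DataFrame(
                sorted(labels.items()), columns=["gene_id", "cluster"]
            )
            clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
            (out / "dendrogram.nwk").write_text(newick + "\n")

    # --- stage 6: trans mediation -------------------------------------------
    region_variants = regions_mod.variants_in_regions(geno.variants, region_table)
    inside_ids = geno.variants.loc[region_variants.notna(), "variant_id"].tolist()
    mediation_table = pd.DataFrame()
    mediation_summary = pd.DataFrame()
    if inside_ids and prioritized:
        region_geno = geno.subset_variants(inside_ids)
        trans_records = eqtl.map_eqtl(
            expr, region_geno, annotation, scope="trans",
            cis_window_bp=config.cis_window_bp,
        )
        mediators_by_region = {
            rid: sorted(
                g for g in gs if g in prioritized and g in expr
            )
            for rid, gs in gene_map.items()
        }
        triples = mediation.find_trans_targets(
            trans_records, region_table, annotation, mediators_by_region,
            p_thresh=config.trans_p,
        )
        triples = mediation.coexpression_filter(expr, triples, r_min=config.coexpression_r)
        mediation_table, mediation_summary = mediation.mediation_scan(
            geno, expr, triples, alpha_family=config.mediation_family_alpha
        )
    mediation_table.to_csv(out / "mediation.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    mediation_summary.to_csv(
        out / "mediation_summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    # --- stage 7: permutation DE statistic ----------------------------------
    perm_result = None
    if config.de_stats:
        de = DeStatTable.from_frame(pd.read_csv(config.de_stats, sep="\t"))
        if config.de_gene_set:
            gene_set = [
                line.strip() for line in Path(config.de_gene_set).read_text().splitlines()
                if line.strip()
            ]
        else:
            gene_set = sorted(
                set(mediation_table[mediation_table["significant"]]["target_gene"])
                | set(mediation_table[mediation_table["significant"]]["mediator_gene"])
            ) if len(mediation_table) else []
        if gene_set:
            perm_result = permde.run_permde(
                de, gene_set, n_perm=config.n_perm, seed=config.seed
            )
            with open(out / "permde.json", "w") as fh:
                json.dump(dataclasses.asdict(perm_result), fh, indent=2, sort_keys=True)

    # --- manifest -----------------------------------------------------------
    manifest = dataclasses.asdict(config)
    manifest["package_version"] = __version__
    manifest["n_candidate_genes"] = len(candidates)
    manifest["n_prioritized"] = len(prioritized)
    manifest["n_regions"] = len(region_table)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return {
        "qc_report": qc_report,
        "leads": leads,
        "regions": region_table,
        "candidate_genes": gene_map,
        "cis_eqtl": cis_records,
        "instruments": instruments,
        "evidence": evidence,
        "prioritized": prioritized,
        "clusters": clusters,
        "mediation": mediation_table,
        "mediation_summary": mediation_summary,
        "permde": perm_result,
    }


def _flag_str(flag: bool | None) -> str:
    return "NT" if flag is None else ("true" if flag else "false")


def _top_pair(variant_id, gene_cis, gwas_by_variant, geno):
    """Harmonized eQTL/GWAS effect pair at one variant, or None if untestable."""
    if variant_id not in gwas_by_variant.index:
        return None
    hit = gene_cis[gene_cis["variant_id"] == variant_id]
    if hit.empty:
        return None
    erec = hit.iloc[0]
    grec = gwas_by_variant.loc[variant_id]
    vrow = geno.variants.iloc[geno.variant_index(variant_id)]
    try:
        aligned, status = prioritize.harmonize(
            vrow["alt"], vrow["ref"],
            grec["effect_allele"], grec["other_allele"], float(grec["beta"]),
        )
    except ValueError:
        return None
    return prioritize.TopVariantPair(
        variant_id=variant_id,
        beta_eqtl=float(erec["beta"]),
        p_eqtl=float(erec["p_value"]),
        beta_gwas=aligned,
        p_gwas=float(grec["p_value"]),
        palindromic=(status == "palindromic"),
    )
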