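"""Calibration and planted-truth recovery suites.

Self-contained simulation studies that measure, at configurable problem
sizes, whether each statistical component behaves as designed: posterior
concentration of the colocalization test under shared vs. distinct causal
variants, confidence-interval coverage of the MR-IVW estimator and the
null distribution of its Cochran's Q, the type-I error of the
Freedman-Schatzkin mediation test, recovery of a planted master-regulator
mediation network, and recovery of planted co-regulation clusters.  The
acceptance script and the test suite both run these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import eqtl, mediation, prioritize
from .coregulation import cluster_genes, profile_correlate
from .syndata import (
    PlantedArchitecture,
    simulate_component_matrix,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas,
    uniform_layout,
)


# ---------------------------------------------------------------------------
# colocalization scenario suite
# ---------------------------------------------------------------------------

def _one_coloc_locus(
    scenario: str, n_individuals: int, seed: int,
    cis_beta: float = 0.5, gwas_beta: float = 0.5,
) -> prioritize.ColocResult:
    """One synthetic locus: two independent LD blocks of 25 variants each.

    The eQTL causal variant sits mid-block-1; the GWAS causal variant is the
    same variant ("shared") or mid-block-2 ("distinct", r^2 ~ 0 across
    blocks).
    """
    n_var = 50
    layout = uniform_layout(n_var, chrom="1", start=1_000_000, spacing=10_000, maf=0.3)
    blocks = [(0, 25, 20), (25, 50, 20)]
    geno = simulate_genotypes(n_individuals, layout, blocks, seed=seed)
    eqtl_causal = geno.variants.iloc[12]["variant_id"]
    gwas_causal = eqtl_causal if scenario == "shared" else geno.variants.iloc[37]["variant_id"]

    arch = PlantedArchitecture(
        cis_effects={"gene_a": (eqtl_causal, cis_beta)},
        shared_flags={"locus": scenario},
    )
    expr = simulate_expression(geno, arch, noise_sd=1.0, seed=seed + 1)
    annotation = pd.DataFrame(
        [("gene_a", "1", 1_100_000, 1_120_000, "+")],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    eqtl_slice = eqtl.map_eqtl(expr, geno, annotation, scope="cis")
    gwas = simulate_gwas(geno, [(gwas_causal, gwas_beta)], prevalence_threshold=0.5,
                         seed=seed + 2)
    result = prioritize.coloc_abf(
        gwas[["variant_id", "beta", "se"]],
        eqtl_slice[["variant_id", "beta", "se"]],
        gene_id="gene_a", region_id="locus",
    )
    assert result is not None
    return result


def coloc_scenario_suite(
    scenario: str, n_loci: int = 50, n_individuals: int = 5000, seed: int = 0
) -> list[prioritize.ColocResult]:
    """Colocalization posteriors over seeded loci of one planted scenario."""
    if scenario not in ("shared", "distinct"):
        raise ValueError("scenario must be 'shared' or 'distinct'")
    base = np.random.SeedSequence(seed).generate_state(n_loci, dtype=np.uint32)
    return [
        _one_coloc_locus(scenario, n_individuals, int(s) % (2**31 - 10))
        for s in base
    ]


# ---------------------------------------------------------------------------
# MR-IVW calibration
# ---------------------------------------------------------------------------

@dataclass
class MrCalibration:
    coverage: float          # fraction of 95% CIs containing the true effect
    q_p_values: np.ndarray   # Cochran's Q p per replicate (homogeneous truth)
    n_replicates: int


def mr_calibration_suite(
    n_replicates: int = 500,
    n_instruments: int = 10,
    true_theta: float = 0.3,
    se_y: float = 0.05,
    seed: int = 0,
    n_boot: int = 50,
) -> MrCalibration:
    """Coverage and Q-calibration of MR-IVW with strong, valid instruments.

    Exposure effects are measured essentially without error (the strong-
    instrument regime where the first-order ratio SE is exact); outcome
    effects are ``theta * beta_x`` plus N(0, se_y) noise, so every replicate
    is homogeneous by construction.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    q_ps = np.empty(n_replicates)
    for r in range(n_replicates):
        beta_x = rng.uniform(0.2, 0.6, n_instruments) * rng.choice([-1, 1], n_instruments)
        beta_y = true_theta * beta_x + se_y * rng.standard_normal(n_instruments)
        inst = eqtl.InstrumentSet(
            gene_id="g",
            table=pd.DataFrame(
                {
                    "variant_id": [f"v{j}" for j in range(n_instruments)],
                    "beta": beta_x,
                    "se": np.full(n_instruments, 1e-8),
                    "p_value": np.full(n_instruments, 1e-12),
                    "step": np.arange(1, n_instruments + 1),
                }
            ),
        )
        gwas = pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(n_instruments)],
                "effect_allele": "G",
                "other_allele": "A",
                "beta": beta_y,
                "se": np.full(n_instruments, se_y),
            }
        )
        res = prioritize.mr_ivw(inst, gwas, n_boot=n_boot, seed=int(rng.integers(2**31)))
        assert res is not None
        lo, hi = res.estimate - 1.96 * res.se, res.estimate + 1.96 * res.se
        covered += int(lo <= true_theta <= hi)
        q_ps[r] = res.q_p
    return MrCalibration(
        coverage=covered / n_replicates, q_p_values=q_ps, n_replicates=n_replicates
    )


# ---------------------------------------------------------------------------
# Freedman-Schatzkin calibration
# ---------------------------------------------------------------------------

def fs_null_rejection_rate(
    n_replicates: int = 2000, n: int = 300, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the mediation test under a complete null.

    Mediator independent of both the dosage and the target; the target has a
    genuine direct dosage effect, so the unadjusted and adjusted coefficients
    estimate the same quantity and any "mediation" signal is noise.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        g = rng.binomial(2, 0.3, n).astype(float)
        m = rng.standard_normal(n)
        y = 0.2 * g + rng.standard_normal(n)
        res = mediation.mediate(g, m, y)
        rejections += int(res.fs_p < alpha)
    return rejections / n_replicates


def fs_bootstrap_comparison(
    n: int = 500, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """FS p-value vs. a nonparametric bootstrap p on one fixed dataset.

    The bootstrap resamples individuals, recomputes the unadjusted-minus-
    adjusted coefficient difference, and converts the observed difference to
    a two-sided normal p using the bootstrap SE.
    """
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, n).astype(float)
    m = 0.4 * g + rng.standard_normal(n)
    y = 0.08 * m + 0.2 * g + rng.standard_normal(n)
    res = mediation.mediate(g, m, y)
    d_hat = res.beta_unadj - res.beta_adj

    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        rb = mediation.mediate(g[idx], m[idx], y[idx])
        diffs[b] = rb.beta_unadj - rb.beta_adj
    p_boot = float(2.0 * sps.norm.sf(abs(d_hat) / diffs.std(ddof=1)))
    return res.fs_p, p_boot


# ---------------------------------------------------------------------------
# master-regulator recovery
# ---------------------------------------------------------------------------

@dataclass
class MasterRegulatorRecovery:
    n_planted: int
    n_planted_recovered: int
    n_decoys: int
    n_false_positives: int
    mean_z_diff_planted: float

    @property
    def recovery_rate(self) -> float:
        return self.n_planted_recovered / self.n_planted


def master_regulator_suite(
    n_individuals: int = 2000,
    n_targets: int = 41,
    n_decoys: int = 100,
    cis_beta: float = 0.8,
    chain_coef: float = 0.6,
    seed: int = 0,
) -> MasterRegulatorRecovery:
    """Recovery of a planted master-regulator mediation network.

    One cis gene mediates ``n_targets`` trans genes; ``n_decoys`` genes are
    pure noise.  All mediator-target pairs (planted and decoy) run through
    the FS mediation scan with per-pair Bonferroni control; decoy flags are
    false positives.
    """
    layout = uniform_layout(10, chrom="1", start=1_000_000, spacing=20_000, maf=0.3)
    geno = simulate_genotypes(n_individuals, layout, [(0, 10, 40)], seed=seed)
    causal = geno.variants.iloc[5]["variant_id"]
    targets = [f"target_{i:03d}" for i in range(n_targets)]
    decoys = [f"decoy_{i:03d}" for i in range(n_decoys)]
    arch = PlantedArchitecture(
        cis_effects={"mediator": (causal, cis_beta)},
        mediation_chains=[("mediator", t, chain_coef) for t in targets],
        background_genes=decoys,
    )
    expr = simulate_expression(geno, arch, noise_sd=1.0, seed=seed + 1)
    pairs = pd.DataFrame(
        {
            "mediator_gene": "mediator",
            "target_gene": targets + decoys,
            "variant_id": causal,
        }
    )
    table, _summary = mediation.mediation_scan(geno, expr, pairs, alpha_family=0.05)
    planted = table[table["target_gene"].isin(targets)]
    decoy_rows = table[table["target_gene"].isin(decoys)]
    return MasterRegulatorRecovery(
        n_planted=n_targets,
        n_planted_recovered=int(planted["significant"].sum()),
        n_decoys=n_decoys,
        n_false_positives=int(decoy_rows["significant"].sum()),
        mean_z_diff_planted=float(planted["z_diff"].mean()),
    )


# ---------------------------------------------------------------------------
# co-regulation cluster recovery
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index between two partitions of the same items."""
    a = pd.Categorical(labels_a).codes
    b = pd.Categorical(labels_b).codes
    contingency = pd.crosstab(a, b).to_numpy()

    def comb2(x: np.ndarray) -> np.ndarray:
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    n = comb2(np.array([len(a)]))[0]
    expected = sum_a * sum_b / n
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def cluster_recovery_suite(
    n_clusters: int = 4, genes_per_cluster: int = 10, n_components: int = 200,
    seed: int = 0,
) -> float:
    """ARI between planted co-regulation clusters and Ward recovery at k."""
    genes = [
        f"g{c}_{i:02d}" for c in range(n_clusters) for i in range(genes_per_cluster)
    ]
    truth = {g: g.split("_")[0] for g in genes}
    comp = simulate_component_matrix(genes, n_components, truth, seed=seed)
    zmat = profile_correlate(genes, comp)
    labels, _linkage, _newick = cluster_genes(zmat, k=n_clusters)
    ordered = sorted(labels)
    return adjusted_rand_index([truth[g] for g in ordered], [labels[g] for g in ordered])
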