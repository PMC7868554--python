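"""Synthetic cohorts with planted genetic architecture.

Every downstream stage of the pipeline (region definition, eQTL mapping,
prioritization, mediation, the permutation DE statistic) is validated against
cohorts generated here, because the planted architecture is known exactly:
which variant drives which gene in cis, which cis gene relays a trans effect
to which target genes, which variants act on disease liability, and which
gene set carries a planted expression shift.

Design notes
------------
* Linkage disequilibrium is produced by founder-haplotype copying: each LD
  block owns a small pool of founder haplotypes and every individual draws
  two haplotypes per block.  This yields exactly block-diagonal LD (r2 == 0
  across blocks in expectation) at negligible cost.
* Case/control GWAS statistics come from a liability-threshold model with
  single-variant linear regression on case status (score-test equivalent).
* All randomness flows through one ``numpy.random.Generator`` seeded
  explicitly; there is no global random state anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import linear_assoc

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Dosage matrix with variant metadata.

    ``dosages`` is (n_individuals, n_variants) with values in [0, 2];
    ``variants`` is a DataFrame with columns variant_id, chrom, pos, ref, alt,
    sorted by (chrom, pos) with strictly increasing positions per chromosome.
    """

    individuals: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        return self._index[variant_id]

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)]

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(v) for v in variant_ids]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Expression values for the same ordered individuals as a GenotypeMatrix.

    ``values`` is (n_individuals, n_genes).
    """

    individuals: list[str]
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.individuals), len(self.genes)):
            raise ValueError("expression shape mismatch")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[:, self._index[gene_id]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index


@dataclass
class DeStatTable:
    """Per-gene DE test statistics for a control and a knockdown contrast."""

    genes: list[str]
    stat_control: np.ndarray
    stat_kd: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.genes) == len(self.stat_control) == len(self.stat_kd)):
            raise ValueError("DeStatTable columns must share the gene universe")
        if not (np.isfinite(self.stat_control).all() and np.isfinite(self.stat_kd).all()):
            raise ValueError("DE statistics must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.genes,
             "stat_control": self.stat_control,
             "stat_kd": self.stat_kd}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DeStatTable":
        return cls(
            genes=list(df["gene_id"]),
            stat_control=df["stat_control"].to_numpy(float),
            stat_kd=df["stat_kd"].to_numpy(float),
        )


@dataclass
class PlantedArchitecture:
    """Ground-truth record of everything planted into a synthetic cohort.

    cis_effects      : gene -> (causal variant id, effect in expression-SD/allele)
    mediation_chains : (mediator gene, target gene, chain coefficient); the
                       target inherits ``coef * mediator_expression``
    gwas_causal      : (variant id, liability-scale beta)
    shared_flags     : locus label -> "shared" | "distinct" | "null"
    de_target_set    : genes carrying the planted DE shift
    background_genes : genes with no planted signal (pure noise)
    """

    cis_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    mediation_chains: list[tuple[str, str, float]] = field(default_factory=list)
    gwas_causal: list[tuple[str, float]] = field(default_factory=list)
    shared_flags: dict[str, str] = field(default_factory=dict)
    de_target_set: list[str] = field(default_factory=list)
    background_genes: list[str] = field(default_factory=list)

    def gene_universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.cis_effects:
            seen.setdefault(g)
        for med, tgt, _ in self.mediation_chains:
            seen.setdefault(med)
            seen.setdefault(tgt)
        for g in self.background_genes:
            seen.setdefault(g)
        return list(seen)

    def validate(self, genotypes: GenotypeMatrix) -> None:
        genes = set(self.gene_universe())
        for gene, (variant, beta) in self.cis_effects.items():
            if variant not in genotypes.variants["variant_id"].values:
                raise ValueError(f"cis effect of {gene} references unknown variant {variant}")
        for med, tgt, coef in self.mediation_chains:
            if coef == 0:
                raise ValueError(f"chain {med}->{tgt} has zero coefficient")
            if med not in genes or tgt not in genes:
                raise ValueError("mediation chain references unknown gene")
        for variant, _ in self.gwas_causal:
            if variant not in genotypes.variants["variant_id"].values:
                raise ValueError(f"GWAS causal variant {variant} not in cohort")
        for flag in self.shared_flags.values():
            if flag not in ("shared", "distinct", "null"):
                raise ValueError(f"unknown colocalization flag {flag!r}")
        for g in self.de_target_set:
            if g not in genes:
                raise ValueError(f"DE target {g} not in gene universe")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_individuals: int,
    variant_layout: Sequence[tuple[str, int, float]],
    ld_blocks: Sequence[tuple[int, int, int]],
    seed: int,
) -> GenotypeMatrix:
    """Simulate a dosage matrix with block-diagonal LD.

    Parameters
    ----------
    variant_layout
        (chromosome, position, target alt-allele frequency) per variant,
        sorted by (chromosome, position).
    ld_blocks
        (start index, stop index, founder-pool size) half-open ranges into
        the layout.  Variants not covered by any block are drawn with an
        effectively infinite founder pool (independent Bernoulli haplotypes).
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    layout = list(variant_layout)
    # chromosomes must be contiguous runs with strictly increasing positions
    seen_chroms: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = -1
    for chrom, pos, maf in layout:
        chrom, pos = str(chrom), int(pos)
        if chrom != prev_chrom:
            if chrom in seen_chroms:
                raise ValueError(f"variants of chromosome {chrom} are not contiguous")
            seen_chroms.add(chrom)
            prev_chrom, prev_pos = chrom, -1
        if pos <= prev_pos:
            raise ValueError(
                f"positions must be strictly increasing within chromosome "
                f"(got {chrom}:{pos} after {chrom}:{prev_pos})"
            )
        prev_pos = pos
        if not 0.0 < maf < 1.0:
            raise ValueError(f"target allele frequency {maf} outside (0, 1)")

    n_var = len(layout)
    freqs = np.array([m for _, _, m in layout])
    rng = np.random.default_rng(seed)
    dosages = np.empty((n_individuals, n_var), dtype=float)
    covered = np.zeros(n_var, dtype=bool)

    for start, stop, pool_size in ld_blocks:
        if pool_size < 1:
            raise ValueError("founder-pool size must be >= 1")
        if covered[start:stop].any():
            raise ValueError("overlapping LD blocks")
        covered[start:stop] = True
        width = stop - start
        founders = (rng.random((pool_size, width)) < freqs[start:stop]).astype(float)
        picks = rng.integers(0, pool_size, size=(2, n_individuals))
        dosages[:, start:stop] = founders[picks[0]] + founders[picks[1]]

    if not covered.all():
        # independent haplotypes for uncovered variants
        free = ~covered
        hap = rng.random((2, n_individuals, int(free.sum()))) < freqs[free]
        dosages[:, free] = hap.sum(axis=0)

    variants = pd.DataFrame(
        {
            "variant_id": [f"snp_{c}_{p}" for c, p, _ in layout],
            "chrom": [str(c) for c, _, _ in layout],
            "pos": [int(p) for _, p, _ in layout],
            "ref": "A",
            "alt": "G",
        }
    )
    geno = GenotypeMatrix(
        individuals=[f"ind{i:05d}" for i in range(n_individuals)],
        variants=variants,
        dosages=dosages,
    )
    monomorphic = int((geno.dosages.var(axis=0) == 0).sum())
    if monomorphic:
        logger.warning("%d simulated variants are monomorphic (zero variance)", monomorphic)
    return geno


def uniform_layout(
    n_variants: int,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 10_000,
    maf: float | Sequence[float] = 0.3,
) -> list[tuple[str, int, float]]:
    """Evenly spaced variant layout helper."""
    mafs = np.broadcast_to(np.asarray(maf, float), (n_variants,))
    return [(chrom, start + i * spacing, float(mafs[i])) for i in range(n_variants)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genotypes: GenotypeMatrix,
    architecture: PlantedArchitecture,
    noise_sd: float,
    seed: int,
) -> ExpressionMatrix:
    """Generate expression with planted cis effects and mediation chains.

    A gene with a cis effect gets ``beta * dosage + noise``; a chain target
    additionally inherits ``coef * mediator_expression``.  The target thereby
    carries a trans association with the mediator's cis variant that vanishes
    once the mediator's expression is conditioned on — the signature the
    mediation module must recover.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    architecture.validate(genotypes)
    genes = architecture.gene_universe()
    n = genotypes.n_individuals
    rng = np.random.default_rng(seed)
    values = np.zeros((n, len(genes)))
    gi = {g: i for i, g in enumerate(genes)}

    chains_by_target: dict[str, list[tuple[str, float]]] = {}
    for med, tgt, coef in architecture.mediation_chains:
        chains_by_target.setdefault(tgt, []).append((med, coef))

    # topological order: mediators (no incoming chain) before chain targets
    order = sorted(genes, key=lambda g: g in chains_by_target)
    for g in order:
        expr = rng.standard_normal(n) * noise_sd
        if g in architecture.cis_effects:
            variant, beta = architecture.cis_effects[g]
            expr = expr + beta * genotypes.dosage_of(variant)
        for med, coef in chains_by_target.get(g, ()):
            if med in chains_by_target:
                raise ValueError("mediation chains deeper than one level are not supported")
            expr = expr + coef * values[:, gi[med]]
        values[:, gi[g]] = expr

    return ExpressionMatrix(individuals=list(genotypes.individuals), genes=genes, values=values)


def derive_annotation(
    architecture: PlantedArchitecture,
    genotypes: GenotypeMatrix,
    gene_span: int = 20_000,
    far_chrom: str = "20",
    far_start: int = 1_000_000,
    far_spacing: int = 4_000_000,
) -> pd.DataFrame:
    """Gene annotation consistent with the planted architecture.

    Genes with a cis effect sit on top of their causal variant; all other
    genes (chain targets, background) are laid out far away on ``far_chrom``
    so their planted associations are genuinely trans.
    """
    rows = []
    far_i = 0
    for g in architecture.gene_universe():
        if g in architecture.cis_effects:
            variant, _ = architecture.cis_effects[g]
            row = genotypes.variants.iloc[genotypes.variant_index(variant)]
            start = max(1, int(row["pos"]) - gene_span // 2)
            rows.append((g, str(row["chrom"]), start, start + gene_span, "+"))
        else:
            start = far_start + far_i * far_spacing
            rows.append((g, far_chrom, start, start + gene_span, "+"))
            far_i += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas(
    genotypes: GenotypeMatrix,
    causal_effects: Sequence[tuple[str, float]],
    prevalence_threshold: float,
    seed: int,
) -> pd.DataFrame:
    """Case/control summary statistics from a liability-threshold model.

    Liability = sum(beta * dosage) + N(0, 1); individuals above the
    ``prevalence_threshold`` quantile of liability are cases.  Per-variant
    effect/SE/p come from linear regression of case status on dosage
    (score-test equivalent of logistic regression for small effects).
    Effect allele is the alt allele.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    liability = rng.standard_normal(n)
    for variant, beta in causal_effects:
        liability = liability + beta * genotypes.dosage_of(variant)
    cutoff = np.quantile(liability, prevalence_threshold)
    status = (liability > cutoff).astype(float)
    if status.min() == status.max():
        raise ValueError("all individuals fall in one case/control class")

    beta, se, p = linear_assoc(genotypes.dosages, status)
    out = genotypes.variants.copy()
    out["effect_allele"] = out["alt"]
    out["other_allele"] = out["ref"]
    out["beta"] = beta
    out["se"] = se
    out["p_value"] = p
    out["eaf"] = genotypes.allele_freq()
    return out[
        ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
         "beta", "se", "p_value", "eaf"]
    ]


# ---------------------------------------------------------------------------
# differential-expression statistic tables
# ---------------------------------------------------------------------------

def de_gene_ids(n_genes: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n_genes)]


def simulate_de_experiment(
    n_genes: int,
    target_set: Sequence[str],
    shift: float,
    n_replicates: int,
    correlation: float,
    seed: int,
    genes: Sequence[str] | None = None,
) -> DeStatTable:
    """Two-contrast per-gene t statistics with correlated noise in the target set.

    Three arms are simulated — untreated (WT), non-targeting control (SCR)
    and knockdown (KD) — and the contrasts share the SCR arm: stat_control
    compares WT vs SCR (no planted shift anywhere), stat_kd compares SCR vs
    KD, where the target set's mean is shifted by ``shift`` SD units in the
    KD arm.  Genes in the target set share a per-replicate latent factor
    with weight ``sqrt(correlation)`` inside every arm, so the set-level
    statistic fluctuates coherently in *both* contrasts — the co-expression
    structure whose cancellation the permutation fold-change relies on.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per arm")
    if not 0.0 <= correlation < 1.0:
        raise ValueError("correlation must be in [0, 1)")
    universe = list(genes) if genes is not None else de_gene_ids(n_genes)
    if len(universe) != n_genes:
        raise ValueError("genes length must equal n_genes")
    missing = set(target_set) - set(universe)
    if missing:
        raise ValueError(f"target genes not in universe: {sorted(missing)[:5]}")
    target_mask = np.isin(np.asarray(universe), list(target_set))

    rng = np.random.default_rng(seed)

    def one_arm() -> np.ndarray:
        eps = rng.standard_normal((n_replicates, n_genes))
        latent = rng.standard_normal((n_replicates, 1))
        eps[:, target_mask] = (
            np.sqrt(correlation) * latent
            + np.sqrt(1.0 - correlation) * eps[:, target_mask]
        )
        return eps

    def t_stat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp2 = ((n_replicates - 1) * (va + vb)) / (2 * n_replicates - 2)
        return (mb - ma) / np.sqrt(sp2 * (2.0 / n_replicates))

    wt, scr, kd = one_arm(), one_arm(), one_arm()
    kd[:, target_mask] += shift
    return DeStatTable(
        genes=universe,
        stat_control=t_stat(wt, scr),
        stat_kd=t_stat(scr, kd),
    )


# ---------------------------------------------------------------------------
# co-regulation component matrix
# ---------------------------------------------------------------------------

def simulate_component_matrix(
    genes: Sequence[str],
    n_components: int,
    cluster_labels: Mapping[str, object],
    seed: int,
    within_weight: float = 0.9,
) -> pd.DataFrame:
    """Gene x component loading matrix with planted co-regulation clusters.

    Genes in the same cluster share a cluster prototype profile with weight
    ``sqrt(within_weight)``; prototypes of different clusters are independent
    draws, hence near-orthogonal for large n_components.
    """
    if n_components < 4:
        raise ValueError("need at least 4 components")
    labels = [cluster_labels[g] for g in genes]
    distinct = sorted(set(map(str, labels)))
    if len(distinct) < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(seed)
    prototypes = {c: rng.standard_normal(n_components) for c in distinct}
    rows = []
    for g, lab in zip(genes, labels):
        noise = rng.standard_normal(n_components)
        rows.append(
            np.sqrt(within_weight) * prototypes[str(lab)]
            + np.sqrt(1.0 - within_weight) * noise
        )
    return pd.DataFrame(
        np.vstack(rows),
        index=list(genes),
        columns=[f"comp{j:05d}" for j in range(n_components)],
    )
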