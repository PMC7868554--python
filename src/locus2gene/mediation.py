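"""Trans-eQTL mediation analysis.

A disease-region variant that associates with the expression of a *distant*
gene (a trans-eQTL) may act through a nearby cis gene: the variant perturbs
the cis gene's expression, which in turn drives the trans gene.  Evidence
for that route is attenuation of the variant -> trans-gene effect once the
cis gene's expression enters the model as a covariate.  The significance of
the attenuation is assessed with the Freedman-Schatzkin test for the
difference between the unadjusted and adjusted regression coefficients,

    T = (b_unadj - b_adj) / sqrt(se_u^2 + se_a^2 - 2 se_u se_a sqrt(1 - rho^2)),

where rho is the sample correlation between the variant dosage and the
mediator expression, with a two-sided p from a t distribution on n - 3 df.

Covariate controls (cell-type proportions, or residualizing the mediator on
a neighboring gene's expression) are supported by residualizing before
testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import ols, pearson_r, residualize_matrix, simple_regression
from .syndata import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    mediator_gene: str
    target_gene: str
    variant_id: str
    beta_unadj: float
    se_unadj: float
    beta_adj: float
    se_adj: float
    rho_gm: float            # corr(dosage, mediator expression)
    fs_stat: float
    fs_p: float
    z_diff: float            # |trans Z| change: b_u/se_u - b_a/se_a
    coexpression_r: float    # corr(mediator, target)


def find_trans_targets(
    trans_eqtls: pd.DataFrame,
    regions: pd.DataFrame,
    annotation: pd.DataFrame,
    mediators_by_region: dict[str, list[str]],
    p_thresh: float = 5e-8,
) -> pd.DataFrame:
    """Candidate (mediator, target, variant) triples for mediation testing.

    Keeps trans-eQTL records with p below ``p_thresh`` whose variant lies
    inside an associated region and whose gene lies outside every region,
    takes the top (smallest-p) variant per (region, target gene), and pairs
    each with every mediator (prioritized cis gene) of that region.
    """
    strong = trans_eqtls[
        (trans_eqtls["relation"] == "trans") & (trans_eqtls["p_value"] < p_thresh)
    ].copy()
    if strong.empty:
        return pd.DataFrame(
            columns=["region_id", "mediator_gene", "target_gene", "variant_id", "trans_p"]
        )
    ann = annotation.set_index("gene_id")

    def gene_in_any_region(gene_id: str) -> bool:
        if gene_id not in ann.index:
            return False
        g = ann.loc[gene_id]
        hit = (
            (regions["chrom"].astype(str) == str(g["chrom"]))
            & (regions["start"] <= g["end"])
            & (regions["end"] >= g["start"])
        )
        return bool(hit.any())

    rows = []
    for _, region in regions.iterrows():
        inside = strong[
            (strong["chrom"].astype(str) == str(region["chrom"]))
            & (strong["pos"] >= region["start"])
            & (strong["pos"] <= region["end"])
        ]
        if inside.empty:
            continue
        mediators = mediators_by_region.get(region["region_id"], [])
        if not mediators:
            continue
        top = (
            inside.sort_values(["p_value", "variant_id"], kind="mergesort")
            .groupby("gene_id", sort=True)
            .head(1)
        )
        for _, rec in top.iterrows():
            target = rec["gene_id"]
            if gene_in_any_region(target):
                continue
            for mediator in mediators:
                if mediator == target:
                    continue
                rows.append(
                    (region["region_id"], mediator, target, rec["variant_id"],
                     float(rec["p_value"]))
                )
    return pd.DataFrame(
        rows, columns=["region_id", "mediator_gene", "target_gene", "variant_id", "trans_p"]
    )


def coexpression_filter(
    expr: ExpressionMatrix, pairs: pd.DataFrame, r_min: float = 0.1, signed: bool = False
) -> pd.DataFrame:
    """Keep mediator/target pairs whose expression correlation passes r_min.

    By default the threshold applies to |r|, so negatively co-regulated
    chains are retained; ``signed=True`` switches to a one-sided r > r_min
    rule.  The correlation is recorded in a ``coexpression_r`` column.
    """
    if pairs.empty:
        return pairs.assign(coexpression_r=pd.Series(dtype=float))
    r_values = [
        pearson_r(expr.gene_values(m), expr.gene_values(t))
        for m, t in zip(pairs["mediator_gene"], pairs["target_gene"])
    ]
    out = pairs.copy()
    out["coexpression_r"] = r_values
    keep = out["coexpression_r"] > r_min if signed else out["coexpression_r"].abs() > r_min
    return out[keep].reset_index(drop=True)


def residualize(expr_vector: np.ndarray, covariate_vector: np.ndarray) -> np.ndarray:
    """Residuals of a simple regression of the input on the covariate.

    Exactly uncorrelated with the covariate; a constant covariate degrades
    gracefully to mean-centering (logged).
    """
    y = np.asarray(expr_vector, float)
    c = np.asarray(covariate_vector, float)
    if len(y) != len(c):
        raise ValueError("length mismatch")
    if c.std() == 0:
        logger.warning("residualize: constant covariate, returning centered input")
        return y - y.mean()
    return residualize_matrix(y[:, None], c[:, None])[:, 0]


def mediate(
    dosage: np.ndarray,
    mediator: np.ndarray,
    target: np.ndarray,
    covariates: np.ndarray | None = None,
    mediator_gene: str = "",
    target_gene: str = "",
    variant_id: str = "",
    denom_eps: float = 1e-12,
) -> MediationResult:
    """Freedman-Schatzkin mediation test for one (variant, mediator, target).

    Fits target ~ dosage (unadjusted) and target ~ dosage + mediator
    (adjusted); the FS statistic compares the two dosage coefficients using
    the closed-form covariance implied by the dosage-mediator correlation.
    Covariates, when given, are residualized out of all three variables
    first.
    """
    g = np.asarray(dosage, float)
    m = np.asarray(mediator, float)
    y = np.asarray(target, float)
    n = len(g)
    if not (len(m) == n == len(y)):
        raise ValueError("length mismatch")
    if n < 10:
        raise ValueError("need at least 10 observations")
    if covariates is not None:
        stacked = residualize_matrix(np.column_stack([g, m, y]), covariates)
        g, m, y = stacked.T

    beta_u, se_u, _ = simple_regression(g, y)
    coef, se, _, _ = ols(np.column_stack([g, m]), y)
    beta_a, se_a = float(coef[0]), float(se[0])
    rho = pearson_r(g, m)
    if not np.isfinite(rho):
        rho = 0.0
    var_diff = se_u**2 + se_a**2 - 2.0 * se_u * se_a * np.sqrt(max(1.0 - rho * rho, 0.0))
    if var_diff <= denom_eps**2:
        warnings.warn(
            "Freedman-Schatzkin denominator numerically zero; floored", RuntimeWarning
        )
        var_diff = denom_eps**2
    fs = (beta_u - beta_a) / np.sqrt(var_diff)
    fs_p = float(np.clip(2.0 * sps.t.sf(abs(fs), df=n - 3), np.finfo(float).tiny, 1.0))
    return MediationResult(
        mediator_gene=mediator_gene,
        target_gene=target_gene,
        variant_id=variant_id,
        beta_unadj=beta_u, se_unadj=se_u,
        beta_adj=beta_a, se_adj=se_a,
        rho_gm=float(rho),
        fs_stat=float(fs), fs_p=fs_p,
        z_diff=float(beta_u / se_u - beta_a / se_a),
        coexpression_r=pearson_r(m, y),
    )


def mediation_scan(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    pairs: pd.DataFrame,
    alpha_family: float = 0.05,
    covariates: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the FS mediation test over candidate pairs with Bonferroni control.

    The per-test threshold is ``alpha_family / n_pairs`` (pairs actually
    tested).  Returns (per-pair results with a ``significant`` flag,
    per-mediator summary with counts and mean z_diff).
    """
    results = []
    for _, row in pairs.iterrows():
        res = mediate(
            geno.dosage_of(row["variant_id"]),
            expr.gene_values(row["mediator_gene"]),
            expr.gene_values(row["target_gene"]),
            covariates=covariates,
            mediator_gene=row["mediator_gene"],
            target_gene=row["target_gene"],
            variant_id=row["variant_id"],
        )
        results.append(res.__dict__)
    table = pd.DataFrame(
        results,
        columns=["mediator_gene", "target_gene", "variant_id", "beta_unadj", "se_unadj",
                 "beta_adj", "se_adj", "rho_gm", "fs_stat", "fs_p", "z_diff",
                 "coexpression_r"],
    )
    if table.empty:
        return table.assign(significant=pd.Series(dtype=bool)), pd.DataFrame(
            columns=["mediator_gene", "n_pairs", "n_significant", "mean_z_diff"]
        )
    threshold = alpha_family / len(table)
    table["significant"] = table["fs_p"] < threshold
    summary = (
        table.groupby("mediator_gene")
        .agg(
            n_pairs=("target_gene", "size"),
            n_significant=("significant", "sum"),
            mean_z_diff=("z_diff", "mean"),
        )
        .reset_index()
    )
    return table, summary
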