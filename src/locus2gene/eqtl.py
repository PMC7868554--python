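"""cis/trans eQTL mapping and conditional instrument selection.

Mapping is single-variant linear regression of (optionally standardized)
expression on alt-allele dosage, with the cis/trans relation assigned by a
+/- 1.5 Mb window around the gene span: this wider-than-usual window keeps
eQTL associations overlapping a 1 Mb GWAS flank even for genes at a region's
edge.

Instrument selection is exact forward stepwise regression on the
individual-level data: at each step every remaining cis candidate is scored
by its conditional p-value given the variants already selected, the best one
enters while it clears the entry threshold and a pairwise-LD collinearity
guard, and the final conditional effects come from the joint model.  This is
the individual-level analogue of summary-statistic conditional analysis
(GCTA-COJO): the target quantity is identical, but with genotypes in hand
the computation is exact rather than LD-reference approximated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import dosage_r2, ols
from .syndata import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 1.5e6


@dataclass
class InstrumentSet:
    """Conditionally independent cis instruments for one gene.

    ``table`` has columns variant_id, beta, se, p_value, step where beta/se/p
    are the joint-model conditional estimates and step is the 1-based order
    of entry.
    """

    gene_id: str
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    def top_variant(self) -> str | None:
        if self.table.empty:
            return None
        return self.table.sort_values(["p_value", "variant_id"]).iloc[0]["variant_id"]


def _standardize(y: np.ndarray) -> np.ndarray:
    sd = y.std()
    if sd == 0:
        raise ValueError("gene has zero expression variance")
    return (y - y.mean()) / sd


def cis_mask(
    gene: pd.Series, variants: pd.DataFrame, cis_window_bp: float = CIS_WINDOW_BP
) -> np.ndarray:
    """True where a variant is cis to the gene (within the window of its span)."""
    same = variants["chrom"].astype(str).to_numpy() == str(gene["chrom"])
    pos = variants["pos"].to_numpy()
    return same & (pos >= gene["start"] - cis_window_bp) & (pos <= gene["end"] + cis_window_bp)


def map_eqtl(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    annotation: pd.DataFrame,
    scope: str = "all",
    cis_window_bp: float = CIS_WINDOW_BP,
    standardize: bool = True,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-variant eQTL scan over (gene, variant) pairs.

    Returns a DataFrame with columns gene_id, variant_id, chrom, pos, beta,
    se, p_value, relation.  ``scope`` restricts testing to "cis", "trans" or
    "all" pairs; betas are expression change per effect-allele dose, in
    expression-SD units when ``standardize`` is on.  Covariates, if given,
    are residualized out of expression before mapping.  Zero-variance
    variants are skipped.
    """
    if scope not in ("cis", "trans", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    if expr.individuals != geno.individuals:
        raise ValueError("expression and genotype individual order differ")
    n = len(expr.individuals)
    if n <= 3:
        raise ValueError("need more than 3 individuals")
    ann = annotation.set_index("gene_id")

    values = expr.values
    if covariates is not None:
        from .stats import residualize_matrix

        values = residualize_matrix(values, covariates)

    G = geno.dosages
    Gc = G - G.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    poly = sxx > 0
    n_skipped = int((~poly).sum())
    if n_skipped:
        logger.warning("map_eqtl: skipping %d monomorphic variants", n_skipped)

    chunks: list[pd.DataFrame] = []
    var_meta = geno.variants
    for gi, gene_id in enumerate(expr.genes):
        if gene_id not in ann.index:
            logger.warning("map_eqtl: gene %s missing from annotation, skipped", gene_id)
            continue
        gene = ann.loc[gene_id]
        is_cis = cis_mask(gene, var_meta, cis_window_bp)
        if scope == "cis":
            test = is_cis & poly
        elif scope == "trans":
            test = ~is_cis & poly
        else:
            test = poly
        if not test.any():
            continue
        y = values[:, gi].astype(float)
        y = _standardize(y) if standardize else y - y.mean()
        sxy = Gc[:, test].T @ y
        syy = float(y @ y)
        sx = sxx[test]
        beta = sxy / sx
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / (n - 2) / sx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = np.clip(2.0 * sps.t.sf(np.abs(t), df=n - 2), np.finfo(float).tiny, 1.0)
        idx = np.flatnonzero(test)
        chunks.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "variant_id": var_meta["variant_id"].to_numpy()[idx],
                    "chrom": var_meta["chrom"].to_numpy()[idx],
                    "pos": var_meta["pos"].to_numpy()[idx],
                    "beta": beta,
                    "se": se,
                    "p_value": p,
                    "relation": np.where(is_cis[idx], "cis", "trans"),
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=["gene_id", "variant_id", "chrom", "pos", "beta", "se", "p_value", "relation"]
        )
    return pd.concat(chunks, ignore_index=True)


def select_instruments(
    gene_id: str,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    annotation: pd.DataFrame,
    p_enter: float = 5e-6,
    r2_guard: float = 0.9,
    max_steps: int = 10,
    cis_window_bp: float = CIS_WINDOW_BP,
    standardize: bool = True,
) -> InstrumentSet:
    """Forward stepwise selection of conditionally independent cis eQTLs."""
    ann = annotation.set_index("gene_id")
    if gene_id not in ann.index:
        raise ValueError(f"gene {gene_id} not annotated")
    gene = ann.loc[gene_id]
    mask = cis_mask(gene, geno.variants, cis_window_bp)
    mask &= geno.dosages.var(axis=0) > 0
    cand_idx = np.flatnonzero(mask)
    empty = InstrumentSet(
        gene_id=gene_id,
        table=pd.DataFrame(columns=["variant_id", "beta", "se", "p_value", "step"]),
    )
    if cand_idx.size == 0:
        return empty

    y = expr.gene_values(gene_id).astype(float)
    y = _standardize(y) if standardize else y - y.mean()
    n = y.shape[0]
    X = geno.dosages[:, cand_idx]
    Xc = X - X.mean(axis=0)

    selected: list[int] = []  # positions within cand_idx
    # residualized working copies (intercept already absorbed by centering)
    ry = y.copy()
    RX = Xc.copy()
    alive = np.ones(cand_idx.size, dtype=bool)

    while len(selected) < max_steps:
        df = n - 2 - len(selected)
        if df <= 0:
            break
        sxx = np.einsum("ij,ij->j", RX, RX)
        # rank-deficient candidates: residual variance ~ 0 after projection
        degenerate = alive & (sxx <= 1e-10 * n)
        if degenerate.any():
            for j in np.flatnonzero(degenerate):
                logger.info(
                    "select_instruments(%s): dropping collinear candidate %s",
                    gene_id, geno.variants.iloc[cand_idx[j]]["variant_id"],
                )
            alive[degenerate] = False
        live = np.flatnonzero(alive)
        if live.size == 0:
            break
        sxy = RX[:, live].T @ ry
        syy = float(ry @ ry)
        beta = sxy / sxx[live]
        rss = np.maximum(syy - beta * sxy, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / np.sqrt(rss / df / sxx[live])
        pvals = np.clip(2.0 * sps.t.sf(np.abs(tstat), df=df), np.finfo(float).tiny, 1.0)
        order = np.lexsort((cand_idx[live], pvals))
        best = None
        for o in order:
            j = live[o]
            if pvals[o] >= p_enter:
                break
            if all(
                dosage_r2(X[:, j], X[:, s]) < r2_guard for s in selected
            ):
                best = j
                break
        if best is None:
            break
        selected.append(best)
        alive[best] = False
        # project the chosen column out of everything still in play
        u = RX[:, best] / np.sqrt(float(RX[:, best] @ RX[:, best]))
        ry = ry - u * float(u @ ry)
        RX = RX - np.outer(u, u @ RX)

    if not selected:
        return empty
    joint_beta, joint_se, joint_p, _ = ols(X[:, selected], y)
    table = pd.DataFrame(
        {
            "variant_id": geno.variants["variant_id"].to_numpy()[cand_idx[selected]],
            "beta": joint_beta,
            "se": joint_se,
            "p_value": joint_p,
            "step": np.arange(1, len(selected) + 1),
        }
    )
    return InstrumentSet(gene_id=gene_id, table=table)
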