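"""Gene prioritization: MR-IVW, colocalization, LD overlap, evidence scoring.

Four lines of evidence are combined per candidate gene:

* **MR-IVW** — inverse-variance-weighted causal estimate of expression on
  disease liability using the gene's conditionally independent cis eQTLs as
  instruments (>= 3 required), with Cochran's Q heterogeneity and a
  weighted-median sensitivity estimate.
* **Colocalization** — Wakefield approximate Bayes factors per variant for
  both traits, enumerated over the five standard hypotheses (H0: no signal,
  H1/H2: signal in one trait, H3: two distinct causal variants, H4: one
  shared causal variant).
* **LD overlap** — dosage r^2 between the top independent eQTL and the top
  GWAS variant of the region.
* **External co-regulation evidence** — an externally computed per-gene flag
  (e.g. a DEPICT-style FDR call), consumed as given, never computed here.

A gene is prioritized when at least one line is significant.  Each
prioritized gene also receives an effect direction ("+": the
expression-increasing allele increases risk) via a six-rule decision
procedure over the top eQTL and top GWAS variants with an MR override.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .eqtl import InstrumentSet
from .stats import dosage_r2
from .syndata import GenotypeMatrix

logger = logging.getLogger(__name__)

_PALINDROMIC = ({"A", "T"}, {"C", "G"})


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def is_palindromic(allele_a: str, allele_b: str) -> bool:
    return {allele_a.upper(), allele_b.upper()} in _PALINDROMIC


def harmonize(
    eqtl_effect_allele: str,
    eqtl_other_allele: str,
    gwas_effect_allele: str,
    gwas_other_allele: str,
    gwas_beta: float,
) -> tuple[float, str]:
    """Align a GWAS effect onto the eQTL effect allele.

    Returns (aligned beta, status) with status one of "ok" (alleles matched,
    possibly after a swap-and-flip) or "palindromic" (A/T or G/C pair, unsafe
    without strand information; excluded from direction calls).  Raises
    ValueError when the allele sets are incompatible.
    """
    ea, oa = eqtl_effect_allele.upper(), eqtl_other_allele.upper()
    ga, go = gwas_effect_allele.upper(), gwas_other_allele.upper()
    if {ea, oa} != {ga, go}:
        raise ValueError(f"incompatible allele sets {{{ea},{oa}}} vs {{{ga},{go}}}")
    status = "palindromic" if is_palindromic(ea, oa) else "ok"
    if ga == ea:
        return float(gwas_beta), status
    return -float(gwas_beta), status


# ---------------------------------------------------------------------------
# Mendelian randomization
# ---------------------------------------------------------------------------

@dataclass
class MrResult:
    gene_id: str
    estimate: float          # disease log-odds per SD expression
    se: float
    p_value: float
    n_instruments: int
    cochran_q: float
    q_p: float
    weighted_median_estimate: float
    weighted_median_se: float


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(theta)
    th = theta[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(th[0])
    if cum[-1] <= 0.5:
        return float(th[-1])
    return float(np.interp(0.5, cum, th))


def mr_ivw(
    instruments: InstrumentSet,
    gwas: pd.DataFrame,
    eqtl_alleles: pd.DataFrame | None = None,
    min_instruments: int = 3,
    n_boot: int = 1000,
    seed: int = 0,
    second_order: bool = False,
) -> MrResult | None:
    """Inverse-variance-weighted MR of expression on disease.

    Per instrument j the Wald ratio is theta_j = beta_Y(j) / beta_X(j) with
    first-order se(theta_j) = se_Y(j) / |beta_X(j)| (second-order adds the
    exposure term behind a flag); the IVW estimate is the precision-weighted
    mean, equivalent to weighted least squares through the origin.
    Heterogeneity: Cochran's Q with chi-square (k-1) p.  A weighted-median
    estimate with a parametric-bootstrap SE (fixed seed) accompanies it.

    ``eqtl_alleles``, when given, holds variant_id/effect_allele/other_allele
    for the instruments so GWAS effects can be harmonized; instruments with
    beta_X == 0 are dropped with a log line.  Returns None (not-testable)
    when fewer than ``min_instruments`` usable instruments remain.
    """
    gw = gwas.set_index("variant_id")
    beta_x, se_x, beta_y, se_y = [], [], [], []
    alle = eqtl_alleles.set_index("variant_id") if eqtl_alleles is not None else None
    for _, row in instruments.table.iterrows():
        vid = row["variant_id"]
        if vid not in gw.index:
            logger.info("mr_ivw(%s): instrument %s absent from GWAS", instruments.gene_id, vid)
            continue
        g = gw.loc[vid]
        by = float(g["beta"])
        if alle is not None and vid in alle.index:
            a = alle.loc[vid]
            by, _status = harmonize(
                a["effect_allele"], a["other_allele"],
                g["effect_allele"], g["other_allele"], by,
            )
        if row["beta"] == 0:
            logger.info("mr_ivw(%s): dropping zero-effect instrument %s",
                        instruments.gene_id, vid)
            continue
        beta_x.append(float(row["beta"]))
        se_x.append(float(row["se"]))
        beta_y.append(by)
        se_y.append(float(g["se"]))
    k = len(beta_x)
    if k < min_instruments:
        return None
    bx = np.array(beta_x)
    sx = np.array(se_x)
    by = np.array(beta_y)
    sy = np.array(se_y)

    theta = by / bx
    if second_order:
        se_theta = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se_theta = sy / np.abs(bx)
    w = se_theta**-2
    est = float((w * theta).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    p = float(np.clip(2.0 * sps.norm.sf(abs(est) / se), np.finfo(float).tiny, 1.0))
    q = float((w * (theta - est) ** 2).sum())
    q_p = float(sps.chi2.sf(q, df=k - 1))

    wm = _weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(k)
        by_b = by + sy * rng.standard_normal(k)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        th_b = by_b / bx_b
        se_b = sy / np.abs(bx_b)
        boots[b] = _weighted_median(th_b, se_b**-2)
    wm_se = float(boots.std(ddof=1))

    return MrResult(
        gene_id=instruments.gene_id,
        estimate=est, se=se, p_value=p, n_instruments=k,
        cochran_q=q, q_p=q_p,
        weighted_median_estimate=wm, weighted_median_se=wm_se,
    )


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance threshold controlling family-wise error."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return family_alpha / n_tests


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

@dataclass
class ColocResult:
    gene_id: str
    region_id: str
    pp: np.ndarray            # posterior probabilities of H0..H4
    priors: tuple[float, float, float]
    n_variants: int

    @property
    def pp_h3(self) -> float:
        return float(self.pp[3])

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    def best_hypothesis(self) -> int:
        return int(np.argmax(self.pp))


def wakefield_labf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor per variant (normal prior on the effect)."""
    z = np.asarray(beta, float) / np.asarray(se, float)
    v = np.asarray(se, float) ** 2
    w = prior_sd**2
    r = w / (w + v)
    return 0.5 * (np.log1p(-r) + r * z * z)


def coloc_abf(
    gwas_slice: pd.DataFrame,
    eqtl_slice: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_quant: float = 0.15,
    prior_sd_cc: float = 0.2,
    gene_id: str = "",
    region_id: str = "",
) -> ColocResult | None:
    """Five-hypothesis colocalization from approximate Bayes factors.

    ``gwas_slice`` (case/control trait, prior SD ``prior_sd_cc``) and
    ``eqtl_slice`` (quantitative trait, prior SD ``prior_sd_quant``) are
    matched on variant_id; at least two shared variants are required, else
    None (not-testable).  Configuration sums, computed in log space:

        H1 ~ p1 * sum_i ABF_gwas(i)
        H2 ~ p2 * sum_i ABF_eqtl(i)
        H3 ~ p1*p2 * (sum_i ABF_gwas(i) * sum_j ABF_eqtl(j) - same-variant products)
        H4 ~ p12 * sum_i ABF_gwas(i) * ABF_eqtl(i)
        H0 ~ 1
    """
    merged = gwas_slice.merge(
        eqtl_slice, on="variant_id", suffixes=("_gwas", "_eqtl")
    )
    if len(merged) < 2:
        return None
    l_g = wakefield_labf(merged["beta_gwas"].to_numpy(), merged["se_gwas"].to_numpy(),
                         prior_sd_cc)
    l_e = wakefield_labf(merged["beta_eqtl"].to_numpy(), merged["se_eqtl"].to_numpy(),
                         prior_sd_quant)
    lse_g = logsumexp(l_g)
    lse_e = logsumexp(l_e)
    lse_both = logsumexp(l_g + l_e)

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + lse_g
    lh[2] = np.log(p2) + lse_e
    # sum over i != j = (sum_i)(sum_j) - sum_{i==j}; guard the log-difference
    delta = lse_both - (lse_g + lse_e)
    with np.errstate(divide="ignore"):
        cross = np.log1p(-np.exp(min(delta, -1e-15)))
    lh[3] = np.log(p1) + np.log(p2) + lse_g + lse_e + cross
    lh[4] = np.log(p12) + lse_both

    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(
        gene_id=gene_id, region_id=region_id, pp=pp,
        priors=(p1, p2, p12), n_variants=len(merged),
    )


# ---------------------------------------------------------------------------
# LD overlap
# ---------------------------------------------------------------------------

def ld_overlap(
    top_instrument_variant: str,
    top_gwas_variant: str,
    ld_ref: GenotypeMatrix,
    r2_thresh: float = 0.8,
) -> bool | None:
    """True iff the two top variants are in strong LD (r^2 > threshold).

    None (not-testable) when either variant is missing or monomorphic.
    """
    try:
        a = ld_ref.dosage_of(top_instrument_variant)
        b = ld_ref.dosage_of(top_gwas_variant)
    except KeyError:
        return None
    if a.var() == 0 or b.var() == 0:
        return None
    return bool(dosage_r2(a, b) > r2_thresh)


# ---------------------------------------------------------------------------
# evidence aggregation
# ---------------------------------------------------------------------------

@dataclass
class EvidenceRecord:
    gene_id: str
    mr_ivw: bool | None
    coloc: bool | None
    ld_overlap: bool | None
    depict_external: bool | None
    lines_of_evidence: int
    direction: str = "?"

    @property
    def prioritized(self) -> bool:
        return self.lines_of_evidence >= 1


def aggregate_evidence(
    gene_id: str,
    mr: MrResult | None,
    coloc: ColocResult | None,
    ld: bool | None,
    depict_external: bool | None,
    mr_alpha: float,
    h4_min: float = 0.9,
) -> EvidenceRecord:
    """Score a gene across the four prioritization methods.

    ``mr_alpha`` is the Bonferroni per-test threshold (family alpha divided
    by the number of MR-testable genes, computed by the caller).  A method
    whose inputs are unavailable is recorded as None (not-testable) and
    contributes no line of evidence.
    """
    mr_flag = None if mr is None else bool(mr.p_value < mr_alpha)
    coloc_flag = None if coloc is None else bool(coloc.pp_h4 > h4_min)
    flags = [mr_flag, coloc_flag, ld, depict_external]
    lines = sum(1 for f in flags if f is True)
    return EvidenceRecord(
        gene_id=gene_id,
        mr_ivw=mr_flag,
        coloc=coloc_flag,
        ld_overlap=ld,
        depict_external=depict_external,
        lines_of_evidence=lines,
    )


# ---------------------------------------------------------------------------
# effect direction
# ---------------------------------------------------------------------------

@dataclass
class TopVariantPair:
    """Harmonized eQTL and GWAS effects observed at one top variant."""

    variant_id: str
    beta_eqtl: float
    p_eqtl: float
    beta_gwas: float        # aligned onto the eQTL effect allele
    p_gwas: float
    palindromic: bool = False

    def direction_sign(self) -> int:
        return int(np.sign(self.beta_eqtl * self.beta_gwas))


def _sig_both(pair: TopVariantPair, eqtl_sig: float, gwas_sig: float) -> bool:
    return pair.p_eqtl < eqtl_sig and pair.p_gwas < gwas_sig


def assign_direction(
    eqtl_top: TopVariantPair,
    gwas_top: TopVariantPair,
    mr: MrResult | None,
    eqtl_sig: float = 5e-6,
    gwas_sig: float = 5e-6,
    genome_wide: float = 5e-8,
    mr_alpha: float = 3.1e-4,
) -> str:
    """Six-rule effect-direction call for one gene.

    The per-variant direction is sign(beta_eqtl * beta_gwas): "+" means the
    expression-increasing allele increases disease risk.  Rules, applied to
    the top eQTL variant and the top GWAS variant of the region:

    1. concordant directions, both variants significant in both datasets ->
       that direction;
    2. concordant but some significance missing -> "?", unless MR is
       significant, then the MR sign;
    3. discordant, both significant in both datasets -> "?", unless MR is
       significant, then the MR sign;
    4. discordant, only the eQTL top variant genome-wide significant (in the
       eQTL data) -> the eQTL top variant's direction;
    5. discordant, only the GWAS top variant genome-wide significant (in the
       GWAS data) -> the GWAS top variant's direction;
    6. otherwise "?".

    Palindromic top variants are excluded -> "?".  When both tops are the
    same variant, concordance is automatic and rules 1-2 apply.
    """
    if eqtl_top.palindromic or gwas_top.palindromic:
        return "?"
    sign_e = eqtl_top.direction_sign()
    sign_g = gwas_top.direction_sign()
    if sign_e == 0 or sign_g == 0:
        return "?"

    def as_str(sign: int) -> str:
        return "+" if sign > 0 else "-"

    mr_sig = mr is not None and mr.p_value < mr_alpha and mr.estimate != 0
    mr_dir = as_str(int(np.sign(mr.estimate))) if mr_sig else None

    concordant = sign_e == sign_g
    both_sig = _sig_both(eqtl_top, eqtl_sig, gwas_sig) and _sig_both(
        gwas_top, eqtl_sig, gwas_sig
    )
    if concordant:
        if both_sig:
            return as_str(sign_e)                      # rule 1
        return mr_dir if mr_dir is not None else "?"   # rule 2
    if both_sig:
        return mr_dir if mr_dir is not None else "?"   # rule 3
    eqtl_gw = eqtl_top.p_eqtl < genome_wide
    gwas_gw = gwas_top.p_gwas < genome_wide
    if eqtl_gw and not gwas_gw:
        return as_str(sign_e)                          # rule 4
    if gwas_gw and not eqtl_gw:
        return as_str(sign_g)                          # rule 5
    return "?"                                         # rule 6
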