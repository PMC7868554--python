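"""Disease-associated regions from GWAS summary statistics.

Greedy p-value clumping against an LD reference panel, exclusion of an
extended MHC interval whose long-range LD breaks clump assumptions, merging
of flanked lead-variant windows into non-overlapping associated regions, and
overlap-based candidate-gene assignment.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import dosage_r2
from .syndata import GenotypeMatrix

logger = logging.getLogger(__name__)


def clump(
    gwas: pd.DataFrame,
    ld_ref: GenotypeMatrix,
    p_thresh: float = 5e-6,
    r2_thresh: float = 0.5,
    window_kb: float = 250.0,
) -> pd.DataFrame:
    """Greedy LD clumping of GWAS variants.

    Repeatedly promotes the unassigned variant with the smallest p-value
    below ``p_thresh`` to lead status and absorbs all unassigned variants
    within ``window_kb`` of it whose dosage r^2 with the lead exceeds
    ``r2_thresh``.  Ties broken by (p, chrom, pos, variant_id) so output is
    independent of input row order.  Variants absent from the LD reference
    are logged and treated as un-clumpable singletons: they may lead but
    neither absorb nor get absorbed.

    Returns the lead rows with an added ``clump_rank`` column (1 = smallest p).
    """
    cand = gwas[gwas["p_value"] < p_thresh].copy()
    if cand.empty:
        return cand.assign(clump_rank=pd.Series(dtype=int))
    cand = cand.sort_values(
        ["p_value", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)

    in_ref = cand["variant_id"].isin(ld_ref.variants["variant_id"]).to_numpy()
    n_missing = int((~in_ref).sum())
    if n_missing:
        logger.warning("clump: %d variants absent from LD reference", n_missing)

    window_bp = window_kb * 1_000.0
    assigned = np.zeros(len(cand), dtype=bool)
    chroms = cand["chrom"].to_numpy()
    positions = cand["pos"].to_numpy()
    leads: list[int] = []
    for i in range(len(cand)):
        if assigned[i]:
            continue
        assigned[i] = True
        leads.append(i)
        if not in_ref[i]:
            continue
        lead_dose = ld_ref.dosage_of(cand.at[i, "variant_id"])
        near = (
            ~assigned
            & in_ref
            & (chroms == chroms[i])
            & (np.abs(positions - positions[i]) <= window_bp)
        )
        for j in np.flatnonzero(near):
            r2 = dosage_r2(lead_dose, ld_ref.dosage_of(cand.at[j, "variant_id"]))
            if np.isfinite(r2) and r2 > r2_thresh:
                assigned[j] = True
    out = cand.iloc[leads].reset_index(drop=True)
    out["clump_rank"] = np.arange(1, len(out) + 1)
    return out


def exclude_interval(
    variants: pd.DataFrame,
    chrom: str = "6",
    start_bp: float = 25e6,
    end_bp: float = 37e6,
) -> pd.DataFrame:
    """Drop variants inside [start_bp, end_bp] (inclusive) on ``chrom``.

    Default interval is the extended MHC/HLA region on chromosome 6.
    """
    inside = (
        (variants["chrom"].astype(str) == str(chrom))
        & (variants["pos"] >= start_bp)
        & (variants["pos"] <= end_bp)
    )
    n = int(inside.sum())
    if n:
        logger.info("exclude_interval: removed %d variants in %s:%d-%d",
                    n, chrom, int(start_bp), int(end_bp))
    return variants[~inside].reset_index(drop=True)


def build_regions(leads: pd.DataFrame, flank_bp: float = 1e6) -> pd.DataFrame:
    """Merge +/- flank windows around lead variants into associated regions.

    Intervals are 1-based inclusive, clipped at 1; overlapping or book-ended
    intervals on the same chromosome merge.  Output columns: region_id,
    chrom, start, end, lead_variants (comma-joined ids), sorted by
    (chrom, start).
    """
    if leads.empty:
        return pd.DataFrame(columns=["region_id", "chrom", "start", "end", "lead_variants"])
    df = leads.drop_duplicates("variant_id").copy()
    df["start"] = np.maximum(1, (df["pos"] - flank_bp).astype(int))
    df["end"] = (df["pos"] + flank_bp).astype(int)
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")

    merged: list[dict] = []
    for _, row in df.iterrows():
        if (
            merged
            and merged[-1]["chrom"] == row["chrom"]
            and row["start"] <= merged[-1]["end"] + 1
        ):
            merged[-1]["end"] = max(merged[-1]["end"], row["end"])
            merged[-1]["leads"].append(row["variant_id"])
        else:
            merged.append(
                {"chrom": row["chrom"], "start": int(row["start"]),
                 "end": int(row["end"]), "leads": [row["variant_id"]]}
            )
    out = pd.DataFrame(
        {
            "region_id": [f"region_{i+1:03d}" for i in range(len(merged))],
            "chrom": [m["chrom"] for m in merged],
            "start": [m["start"] for m in merged],
            "end": [m["end"] for m in merged],
            "lead_variants": [",".join(m["leads"]) for m in merged],
        }
    )
    return out


def candidate_genes(
    regions: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, list[str]]:
    """Genes whose [start, end] span intersects each region (inclusive ends)."""
    out: dict[str, list[str]] = {}
    for _, region in regions.iterrows():
        hit = annotation[
            (annotation["chrom"].astype(str) == str(region["chrom"]))
            & (annotation["start"] <= region["end"])
            & (annotation["end"] >= region["start"])
        ]
        out[region["region_id"]] = sorted(hit["gene_id"].tolist())
    return out


def variants_in_regions(variants: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Boolean mask / region id: which region (if any) contains each variant."""
    region_of = pd.Series(index=variants.index, dtype=object)
    for _, region in regions.iterrows():
        inside = (
            (variants["chrom"].astype(str) == str(region["chrom"]))
            & (variants["pos"] >= region["start"])
            & (variants["pos"] <= region["end"])
        )
        region_of[inside & region_of.isna()] = region["region_id"]
    return region_of
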