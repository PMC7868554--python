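"""Clumping, interval exclusion, region merging, candidate-gene mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from locus2gene import regions as R
from locus2gene.stats import dosage_r2
from locus2gene.syndata import GenotypeMatrix


def _make_geno(dosages: np.ndarray, positions, chrom="1"):
    n_ind, n_var = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(n_var)],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix([f"i{k}" for k in range(n_ind)], variants, dosages)


def _gwas_table(rows):
    return pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta", "se", "p_value", "eaf"],
    )


def brute_force_clump(gwas, geno, p_thresh, r2_thresh, window_bp):
    """Independent greedy oracle over an explicit all-pairs r2 table."""
    ids = list(geno.variants["variant_id"])
    remaining = gwas[gwas["p_value"] < p_thresh].copy()
    leads = []
    while len(remaining):
        remaining = remaining.sort_values(["p_value", "chrom", "pos", "variant_id"])
        lead = remaining.iloc[0]
        leads.append(lead["variant_id"])
        keep = []
        for _, row in remaining.iloc[1:].iterrows():
            absorb = False
            if (
                lead["variant_id"] in ids
                and row["variant_id"] in ids
                and row["chrom"] == lead["chrom"]
                and abs(row["pos"] - lead["pos"]) <= window_bp
            ):
                r2 = dosage_r2(
                    geno.dosage_of(lead["variant_id"]), geno.dosage_of(row["variant_id"])
                )
                absorb = np.isfinite(r2) and r2 > r2_thresh
            if not absorb:
                keep.append(row)
        remaining = pd.DataFrame(keep, columns=remaining.columns)
    return leads


class TestClump:
    def test_single_significant_variant_is_lead(self):
        rng = np.random.default_rng(0)
        geno = _make_geno(rng.integers(0, 3, (50, 1)).astype(float), [100])
        gwas = _gwas_table([("v0", "1", 100, "G", "A", 0.5, 0.1, 1e-9, 0.3)])
        leads = R.clump(gwas, geno)
        assert list(leads["variant_id"]) == ["v0"]

    def test_correlated_neighbor_absorbed_independent_kept(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 200).astype(float)
        b = a.copy()
        b[:20] = 2 - b[:20]  # strongly but not perfectly correlated with a
        c = rng.integers(0, 3, 200).astype(float)
        geno = _make_geno(np.column_stack([a, b, c]), [100_000, 150_000, 180_000])
        assert dosage_r2(a, b) > 0.5 and dosage_r2(a, c) < 0.5
        gwas = _gwas_table(
            [
                ("v0", "1", 100_000, "G", "A", 0.5, 0.1, 1e-9, 0.3),
                ("v1", "1", 150_000, "G", "A", 0.4, 0.1, 1e-7, 0.3),
                ("v2", "1", 180_000, "G", "A", 0.4, 0.1, 3e-7, 0.3),
            ]
        )
        leads = R.clump(gwas, geno)
        assert list(leads["variant_id"]) == ["v0", "v2"]

    def test_no_significant_variant_gives_empty(self):
        geno = _make_geno(np.zeros((10, 1)), [100])
        gwas = _gwas_table([("v0", "1", 100, "G", "A", 0.1, 0.1, 0.5, 0.3)])
        assert len(R.clump(gwas, geno)) == 0

    def test_matches_brute_force_oracle_and_row_order_invariant(self):
        rng = np.random.default_rng(7)
        n_var = 30
        base = rng.integers(0, 3, (300, 6)).astype(float)
        # columns built from 6 base haplotype patterns -> plenty of high LD
        dosages = base[:, rng.integers(0, 6, n_var)] + rng.normal(0, 0.15, (300, n_var))
        positions = np.sort(rng.choice(np.arange(1, 10**6, 1000), n_var, replace=False))
        geno = _make_geno(dosages, positions)
        gwas = _gwas_table(
            [
                (f"v{i}", "1", positions[i], "G", "A", 0.1, 0.1,
                 float(rng.uniform(1e-12, 1e-5)), 0.3)
                for i in range(n_var)
            ]
        )
        expected = brute_force_clump(gwas, geno, 5e-6, 0.5, 250_000)
        leads = R.clump(gwas, geno)
        assert list(leads["variant_id"]) == expected
        shuffled = gwas.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert list(R.clump(shuffled, geno)["variant_id"]) == expected

    def test_leads_are_mutually_unabsorbable(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 3, (200, 4)).astype(float)
        dosages = base[:, rng.integers(0, 4, 20)] + rng.normal(0, 0.1, (200, 20))
        positions = np.arange(20) * 10_000 + 1
        geno = _make_geno(dosages, positions)
        gwas = _gwas_table(
            [(f"v{i}", "1", positions[i], "G", "A", 0.1, 0.1,
              float(rng.uniform(1e-10, 1e-6)), 0.3) for i in range(20)]
        )
        leads = R.clump(gwas, geno)
        for i, a in leads.iterrows():
            for j, b in leads.iterrows():
                if i >= j:
                    continue
                if abs(a["pos"] - b["pos"]) <= 250_000:
                    assert dosage_r2(
                        geno.dosage_of(a["variant_id"]), geno.dosage_of(b["variant_id"])
                    ) <= 0.5


class TestExcludeInterval:
    def test_inside_removed_boundary_retained(self):
        df = _gwas_table(
            [
                ("v0", "6", 30_000_000, "G", "A", 0.1, 0.1, 0.5, 0.3),
                ("v1", "6", 24_999_999, "G", "A", 0.1, 0.1, 0.5, 0.3),
                ("v2", "1", 30_000_000, "G", "A", 0.1, 0.1, 0.5, 0.3),
            ]
        )
        out = R.exclude_interval(df)
        assert set(out["variant_id"]) == {"v1", "v2"}

    def test_mixed_count(self):
        rows = [(f"v{i}", "6", 20_000_000 + i * 2_000_000, "G", "A", 0.1, 0.1, 0.5, 0.3)
                for i in range(10)]  # positions 20..38 Mb; inside 25-37: 26,28,..36
        out = R.exclude_interval(_gwas_table(rows))
        assert len(out) == 4


def brute_force_union(intervals):
    """Coverage-set oracle for interval merging (1-based inclusive)."""
    covered = set()
    for chrom, start, end in intervals:
        for x in range(start, end + 1):
            covered.add((chrom, x))
    merged = []
    for chrom in sorted({c for c, _ in covered}):
        xs = sorted(x for c, x in covered if c == chrom)
        start = prev = xs[0]
        for x in xs[1:]:
            if x > prev + 1:
                merged.append((chrom, start, prev))
                start = x
            prev = x
        merged.append((chrom, start, prev))
    return merged


class TestBuildRegions:
    def test_overlapping_leads_merge(self):
        leads = _gwas_table(
            [
                ("v0", "1", 10_000_000, "G", "A", 0.1, 0.1, 1e-9, 0.3),
                ("v1", "1", 11_500_000, "G", "A", 0.1, 0.1, 1e-8, 0.3),
            ]
        )
        out = R.build_regions(leads, flank_bp=1e6)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 9_000_000
        assert out.iloc[0]["end"] == 12_500_000

    def test_different_chromosomes_never_merge(self):
        leads = _gwas_table(
            [
                ("v0", "1", 100, "G", "A", 0.1, 0.1, 1e-9, 0.3),
                ("v1", "2", 100, "G", "A", 0.1, 0.1, 1e-9, 0.3),
            ]
        )
        assert len(R.build_regions(leads, flank_bp=1e6)) == 2

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.sampled_from(["1", "2"]), st.integers(1, 500)),
            min_size=1, max_size=20, unique=True,
        )
    )
    def test_matches_interval_union_oracle(self, leads_spec):
        flank = 30
        leads = _gwas_table(
            [
                (f"v{i}", chrom, pos, "G", "A", 0.1, 0.1, 1e-9, 0.3)
                for i, (chrom, pos) in enumerate(leads_spec)
            ]
        )
        out = R.build_regions(leads, flank_bp=flank)
        expected = brute_force_union(
            [(chrom, max(1, pos - flank), pos + flank) for chrom, pos in leads_spec]
        )
        got = [(r["chrom"], r["start"], r["end"]) for _, r in out.iterrows()]
        assert sorted(got) == sorted(expected)
        total = sum(e - s + 1 for _, s, e in got)
        assert total <= len(leads_spec) * (2 * flank + 1)

    def test_merging_is_idempotent(self):
        leads = _gwas_table(
            [(f"v{i}", "1", 1_000_000 + i * 300_000, "G", "A", 0.1, 0.1, 1e-9, 0.3)
             for i in range(5)]
        )
        once = R.build_regions(leads, flank_bp=1e6)
        midpoints = _gwas_table(
            [
                (f"m{i}", row["chrom"], (row["start"] + row["end"]) // 2,
                 "G", "A", 0.1, 0.1, 1e-9, 0.3)
                for i, (_, row) in enumerate(once.iterrows())
            ]
        )
        again = R.build_regions(midpoints, flank_bp=(once.iloc[0]["end"] - once.iloc[0]["start"]) / 2)
        assert len(again) <= len(once)


class TestCandidateGenes:
    ANN = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(8)],
            "chrom": ["1", "1", "1", "1", "2", "2", "2", "2"],
            "start": [100, 900, 2000, 5000, 100, 400, 800, 3000],
            "end": [200, 1100, 2500, 6000, 300, 600, 1200, 4000],
            "strand": "+",
        }
    )
    REGIONS = pd.DataFrame(
        {
            "region_id": ["r1", "r2"],
            "chrom": ["1", "2"],
            "start": [150, 500],
            "end": [1000, 1500],
        }
    )

    def test_matches_all_pairs_oracle(self):
        got = R.candidate_genes(self.REGIONS, self.ANN)
        expected = {"r1": [], "r2": []}
        for _, g in self.ANN.iterrows():
            for _, r in self.REGIONS.iterrows():
                if (
                    g["chrom"] == r["chrom"]
                    and g["start"] <= r["end"]
                    and g["end"] >= r["start"]
                ):
                    expected[r["region_id"]].append(g["gene_id"])
        assert got == expected

    def test_one_bp_boundary_overlap_is_candidate(self):
        ann = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["1"], "start": [50], "end": [150],
             "strand": "+"}
        )
        regions = pd.DataFrame(
            {"region_id": ["r"], "chrom": ["1"], "start": [150], "end": [300]}
        )
        assert R.candidate_genes(regions, ann) == {"r": ["g"]}

    def test_gene_fully_inside_is_candidate(self):
        got = R.candidate_genes(self.REGIONS, self.ANN)
        assert "g1" in got["r1"]
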