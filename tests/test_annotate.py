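import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from sweepscan.annotate import (
    allele_count_table,
    candidate_genes,
    genes_in_regions,
    go_enrichment,
    qtl_overlap,
    region_gene_counts,
)
from sweepscan.variantio import EffectRecord, GenotypeMatrix, IntervalSet, PopulationMap


def regions_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).assign(
        name=lambda d: [f"R{i}" for i in range(len(d))]
    )


class TestGenesInRegions:
    def test_contained_gene_is_member(self):
        regions = regions_df([("chr1", 100_000, 300_000)])
        genes = IntervalSet.from_records([("chr1", 150_000, 160_000, "g1")])
        out = genes_in_regions(regions, genes)
        assert list(out["gene_id"]) == ["g1"]

    def test_one_bp_straddle_is_member(self):
        regions = regions_df([("chr1", 100_000, 300_000)])
        genes = IntervalSet.from_records([("chr1", 299_999, 310_000, "g1")])
        out = genes_in_regions(regions, genes)
        assert list(out["gene_id"]) == ["g1"]
        # but not under strict containment
        assert len(genes_in_regions(regions, genes, containment=True)) == 0

    def test_planted_membership_counts(self):
        rng = np.random.default_rng(0)
        regions = regions_df([("chr1", i * 1_000_000, i * 1_000_000 + 400_000)
                              for i in range(10)])
        gene_rows, expected = [], {}
        gi = 0
        for i in range(10):
            k = int(rng.integers(0, 8))
            expected[f"R{i}"] = k
            for j in range(k):
                s = i * 1_000_000 + j * 50_000
                gene_rows.append(("chr1", s, s + 10_000, f"g{gi}"))
                gi += 1
            # decoy gene in the gap
            gene_rows.append(("chr1", i * 1_000_000 + 500_000,
                              i * 1_000_000 + 510_000, f"g{gi}"))
            gi += 1
        out = genes_in_regions(regions, IntervalSet.from_records(gene_rows))
        counts = region_gene_counts(out, regions)
        got = dict(zip(counts["region_id"], counts["n_genes"]))
        assert got == expected


class TestQtlOverlap:
    QTLS = pd.DataFrame(
        [("chr1", 100_000, 300_000, "GL", "study1", "gA;gB")],
        columns=["chrom", "start", "end", "trait_id", "source", "candidate_genes"],
    )

    def test_exact_overlap_length(self):
        regions = regions_df([("chr1", 100_000, 300_000)])
        out = qtl_overlap(regions, self.QTLS)
        assert out.loc[0, "overlap_bp"] == 200_000

    def test_disjoint_region_listed_with_empty_traits(self):
        regions = regions_df([("chr1", 500_000, 700_000)])
        out = qtl_overlap(regions, self.QTLS)
        assert len(out) == 1 and out.loc[0, "trait_id"] == ""

    def test_enumeration(self):
        regions = regions_df([("chr1", 0, 150_000), ("chr1", 250_000, 400_000),
                              ("chr2", 0, 100_000)])
        qtls = pd.DataFrame(
            [("chr1", 100_000, 300_000, "GL", "s1", ""),
             ("chr1", 350_000, 500_000, "PBN", "s2", ""),
             ("chr2", 500_000, 600_000, "DRP", "s3", "")],
            columns=["chrom", "start", "end", "trait_id", "source", "candidate_genes"],
        )
        out = qtl_overlap(regions, qtls)
        pairs = {(r.region_id, r.trait_id) for r in out.itertuples() if r.trait_id}
        assert pairs == {("R0", "GL"), ("R1", "GL"), ("R1", "PBN")}
        # symmetric total overlap
        total = out["overlap_bp"].sum()
        assert total == 50_000 + 50_000 + 50_000

    def test_symmetry_of_total_overlap(self):
        regions = regions_df([("chr1", 0, 150_000), ("chr1", 200_000, 260_000)])
        qtls = pd.DataFrame(
            [("chr1", 100_000, 220_000, "GL", "s1", "")],
            columns=["chrom", "start", "end", "trait_id", "source", "candidate_genes"],
        )
        fwd = qtl_overlap(regions, qtls)["overlap_bp"].sum()
        flipped = qtl_overlap(
            qtls.assign(name="Q0"), regions.rename(columns={"name": "trait_id"})
            .assign(source="", candidate_genes="")
        )["overlap_bp"].sum()
        assert fwd == flipped


class TestCandidateGenes:
    MEMBERSHIP = pd.DataFrame(
        {"region_id": ["R1", "R1", "R2"], "gene_id": ["g1", "g2", "g3"],
         "overlap_bp": [100, 100, 100]}
    )

    def test_region_fst_criterion(self):
        out = candidate_genes(
            self.MEMBERSHIP, region_fst={"R1": 0.64, "R2": 0.1},
            gene_fst={}, effects=[], qtl_overlaps=qtl_overlap(
                regions_df([]), pd.DataFrame(columns=["chrom", "start", "end",
                                                      "trait_id", "source",
                                                      "candidate_genes"])),
        )
        assert {c.gene_id for c in out} == {"g1", "g2"}
        assert all(c.rationale == ["region_fst"] for c in out)

    def test_high_impact_criterion(self):
        eff = [EffectRecord("chr1", 10, "C", "T", "g3", "HIGH", "stop_gained")]
        out = candidate_genes(
            self.MEMBERSHIP, region_fst={"R1": 0.28, "R2": 0.28},
            gene_fst={}, effects=eff,
            qtl_overlaps=pd.DataFrame(columns=["region_id", "chrom", "trait_id",
                                               "source", "overlap_bp",
                                               "candidate_genes"]),
        )
        assert [c.gene_id for c in out] == ["g3"]
        assert out[0].rationale == ["high_impact"]

    def test_qtl_candidate_criterion(self):
        qov = pd.DataFrame(
            [{"region_id": "R2", "chrom": "chr1", "trait_id": "GL", "source": "s",
              "overlap_bp": 10, "candidate_genes": "g3"}]
        )
        out = candidate_genes(self.MEMBERSHIP, region_fst={}, gene_fst={},
                              effects=[], qtl_overlaps=qov)
        assert [c.gene_id for c in out] == ["g3"]
        assert out[0].qtl_traits == ["GL"]

    def test_no_criterion_no_candidate(self):
        out = candidate_genes(
            self.MEMBERSHIP, region_fst={"R1": 0.1, "R2": 0.1},
            gene_fst={"g1": 0.1}, effects=[],
            qtl_overlaps=pd.DataFrame(columns=["region_id", "chrom", "trait_id",
                                               "source", "overlap_bp",
                                               "candidate_genes"]),
        )
        assert out == []

    def test_every_candidate_has_rationale(self):
        eff = [EffectRecord("chr1", 10, "C", "T", "g1", "HIGH", "stop_gained")]
        out = candidate_genes(self.MEMBERSHIP, region_fst={"R1": 0.9},
                              gene_fst={"g1": 0.95}, effects=eff,
                              qtl_overlaps=pd.DataFrame(
                                  columns=["region_id", "chrom", "trait_id",
                                           "source", "overlap_bp", "candidate_genes"]))
        assert all(len(c.rationale) >= 1 for c in out)
        g1 = next(c for c in out if c.gene_id == "g1")
        assert set(g1.rationale) == {"region_fst", "gene_fst", "high_impact"}


class TestAlleleCountTable:
    def _gm(self):
        geno = np.array([[0, 0, 2, 2, 1, 0, 0, 0, 0, 0]], dtype=np.int8)
        gm = GenotypeMatrix(
            chrom=np.array(["chr1"], dtype=object), pos=np.array([42]),
            ref=np.array(["G"], dtype=object), alt=np.array(["A"], dtype=object),
            geno=geno, samples=[f"x{i}" for i in range(5)] + [f"y{i}" for i in range(5)],
        )
        pm = PopulationMap({s: ("X" if s.startswith("x") else "Y") for s in gm.samples})
        return gm, pm

    def test_iupac_counts(self):
        gm, pm = self._gm()
        out = allele_count_table(gm, [("chr1", 42)], pm)
        x = out[out["subpop"] == "X"].iloc[0]
        assert (x["n_ref_hom"], x["n_alt_hom"], x["n_het"]) == (2, 2, 1)
        assert x["het_code"] == "R"  # A/G ambiguity

    def test_conservation(self):
        gm, pm = self._gm()
        out = allele_count_table(gm, [("chr1", 42)], pm)
        for _, row in out.iterrows():
            n = len(pm.samples_for(row["subpop"]))
            assert row["n_ref_hom"] + row["n_het"] + row["n_alt_hom"] + row["n_missing"] == n

    def test_private_allele_pattern(self):
        # one subpopulation fixed alt, all others fixed ref
        geno = np.array([[2] * 3 + [0] * 6], dtype=np.int8)
        gm = GenotypeMatrix(
            chrom=np.array(["chr1"], dtype=object), pos=np.array([7]),
            ref=np.array(["C"], dtype=object), alt=np.array(["T"], dtype=object),
            geno=geno,
            samples=[f"s{i}" for i in range(9)],
        )
        pm = PopulationMap({f"s{i}": ("I5" if i < 3 else "I1") for i in range(9)})
        out = allele_count_table(gm, [("chr1", 7)], pm)
        i5 = out[out["subpop"] == "I5"].iloc[0]
        i1 = out[out["subpop"] == "I1"].iloc[0]
        assert i5["n_alt_hom"] == 3 and i5["n_ref_hom"] == 0
        assert i1["n_alt_hom"] == 0 and i1["n_ref_hom"] == 6

    def test_missing_snp_key(self):
        gm, pm = self._gm()
        with pytest.raises(KeyError):
            allele_count_table(gm, [("chr1", 999)], pm)

    def test_all_missing_subpop(self):
        geno = np.array([[-1, -1, 0, 1]], dtype=np.int8)
        gm = GenotypeMatrix(
            chrom=np.array(["chr1"], dtype=object), pos=np.array([7]),
            ref=np.array(["C"], dtype=object), alt=np.array(["T"], dtype=object),
            geno=geno, samples=["a1", "a2", "b1", "b2"],
        )
        pm = PopulationMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        out = allele_count_table(gm, [("chr1", 7)], pm)
        a = out[out["subpop"] == "A"].iloc[0]
        assert a["n_missing"] == 2
        assert a["n_ref_hom"] + a["n_het"] + a["n_alt_hom"] == 0


def exact_hypergeom_tail(k, N, K, n):
    """Exact upper-tail P(X >= k) via integer arithmetic."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


class TestGoEnrichment:
    def _setup(self, n_region=100, k_hit=10, n_background=10_000, k_total=100):
        background = [f"g{i}" for i in range(n_background)]
        annotated = background[:k_total]
        region = background[:k_hit] + background[k_total:k_total + (n_region - k_hit)]
        go = pd.DataFrame({"gene_id": annotated, "go_id": ["GO:1"] * k_total})
        return region, go, background

    def test_hypergeometric_oracle(self):
        region, go, background = self._setup()
        out = go_enrichment(region, go, background)
        expected = exact_hypergeom_tail(10, 10_000, 100, 100)
        assert out.loc[0, "p"] == pytest.approx(expected, abs=1e-12)

    def test_unannotated_term_not_tested(self):
        region, go, background = self._setup()
        go2 = pd.concat([go, pd.DataFrame({"gene_id": [background[-1]],
                                           "go_id": ["GO:2"]})])
        out = go_enrichment(region, go2, background)
        assert "GO:2" not in set(out["term"])

    def test_region_equals_background_p_one(self):
        region, go, background = self._setup()
        out = go_enrichment(background, go, background)
        np.testing.assert_allclose(out["p"].to_numpy(), 1.0, atol=1e-12)

    def test_region_not_subset_raises(self):
        with pytest.raises(ValueError):
            go_enrichment(["zzz"], pd.DataFrame({"gene_id": [], "go_id": []}), ["g1"])

    def test_bh_fdr_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        background = [f"g{i}" for i in range(500)]
        rows = []
        for t in range(20):
            for g in rng.choice(background, size=rng.integers(5, 50), replace=False):
                rows.append((g, f"GO:{t}"))
        go = pd.DataFrame(rows, columns=["gene_id", "go_id"])
        region = list(rng.choice(background, size=60, replace=False))
        out = go_enrichment(region, go, background)
        assert (out["p"] > 0).all() and (out["p"] <= 1).all()
        assert (np.diff(out["fdr"]) >= -1e-12).all()

    def test_bh_matches_manual_oracle(self):
        rng = np.random.default_rng(2)
        background = [f"g{i}" for i in range(300)]
        rows = []
        for t in range(15):
            for g in rng.choice(background, size=rng.integers(5, 40), replace=False):
                rows.append((g, f"GO:{t}"))
        go = pd.DataFrame(rows, columns=["gene_id", "go_id"])
        region = list(rng.choice(background, size=40, replace=False))
        out = go_enrichment(region, go, background)
        p = out["p"].to_numpy()
        m = len(p)
        # manual BH: p_(i) * m / i, cumulative min from the right
        adj = p * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        np.testing.assert_allclose(out["fdr"], np.minimum(adj, 1.0), atol=1e-12)

    def test_empty_region(self):
        out = go_enrichment([], pd.DataFrame({"gene_id": [], "go_id": []}), ["g1"])
        assert len(out) == 0
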