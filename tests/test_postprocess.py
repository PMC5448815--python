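import numpy as np
import pandas as pd
import pytest

from confeti import (
    AnnotationBundle,
    collapse_per_cytoband,
    count_replication,
    detect_broad_impact,
    label_cis_trans,
    pseudo_trans_screen,
)
from confeti.postprocess import load_cytobands, load_homology_regions

from conftest import make_expression, make_genotypes


def eqtl_table(rows):
    """rows: (gene, snp, p, p_adj[, label])"""
    recs = []
    for row in rows:
        gene, snp, p, p_adj = row[:4]
        label = row[4] if len(row) > 4 else "unlabeled"
        recs.append(
            {"gene": gene, "snp": snp, "beta": 1.0, "se": 0.1, "p": p,
             "p_adj": p_adj, "label": label, "method": "test"}
        )
    return pd.DataFrame(recs)


@pytest.fixture
def geo(rng):
    E = make_expression(
        rng.normal(size=(4, 3)),
        chrom=["chr1", "chr1", "chr2"],
        start=[1_400_000, 5_000_000, 300_000],
    )
    G = make_genotypes(
        rng.integers(0, 3, size=(4, 3)),
        chrom=["chr1", "chr1", "chr2"],
        pos=[500_000, 4_000_000, 2_000_000],
    )
    return E, G


class TestLabel:
    def test_same_chromosome_within_window_is_cis(self, geo):
        E, G = geo
        T = eqtl_table([("gene0", "snp0", 1e-8, 1e-6)])
        out = label_cis_trans(T, E, G, window=1_000_000)
        assert out["label"].iloc[0] == "cis"  # distance 900 kb

    def test_different_chromosome_is_trans(self, geo):
        E, G = geo
        T = eqtl_table([("gene2", "snp0", 1e-8, 1e-6)])
        out = label_cis_trans(T, E, G)
        assert out["label"].iloc[0] == "trans"

    def test_boundary_distance_is_inclusive(self, geo):
        E, G = geo
        T = eqtl_table([("gene1", "snp1", 1e-8, 1e-6)])  # distance exactly 1 Mb
        out = label_cis_trans(T, E, G, window=1_000_000)
        assert out["label"].iloc[0] == "cis"

    def test_unannotated_gene_stays_unlabeled(self, geo, rng):
        E, G = geo
        E2 = make_expression(rng.normal(size=(4, 3)))
        E2.gene_annotation = E2.gene_annotation.drop("gene0")
        T = eqtl_table([("gene0", "snp0", 1e-8, 1e-6)])
        out = label_cis_trans(T, E2, G)
        assert out["label"].iloc[0] == "unlabeled"


class TestCollapse:
    def test_min_p_record_kept_within_band(self, rng):
        G = make_genotypes(
            rng.integers(0, 3, size=(4, 2)), chrom=["chr1", "chr1"],
            pos=[100_000, 200_000],
        )
        T = eqtl_table(
            [("geneA", "snp0", 1e-6, 1e-4, "trans"), ("geneA", "snp1", 1e-8, 1e-6, "trans")]
        )
        out = collapse_per_cytoband(T, G, fdr_threshold=0.01)
        assert len(out) == 1
        assert out["snp"].iloc[0] == "snp1"

    def test_collapse_is_per_gene(self, rng):
        G = make_genotypes(rng.integers(0, 3, size=(4, 1)), pos=[100_000])
        T = eqtl_table(
            [("geneA", "snp0", 1e-8, 1e-6, "trans"), ("geneB", "snp0", 1e-7, 1e-5, "trans")]
        )
        out = collapse_per_cytoband(T, G, fdr_threshold=0.01)
        assert len(out) == 2

    def test_matches_groupby_oracle(self, rng):
        n_snps = 40
        pos = rng.choice(np.arange(1, 10_000_000), size=n_snps, replace=False)
        G = make_genotypes(rng.integers(0, 3, size=(4, n_snps)), pos=pos)
        genes = [f"g{i}" for i in range(6)]
        rows = []
        for _ in range(150):
            p = float(rng.uniform(0, 0.02))
            rows.append(
                (genes[rng.integers(6)], f"snp{rng.integers(n_snps)}", p, p,
                 ["cis", "trans"][rng.integers(2)])
            )
        T = eqtl_table(rows).drop_duplicates(subset=["gene", "snp"])
        out = collapse_per_cytoband(T, G, fdr_threshold=0.01)

        # oracle: explicit 1-Mb binning and per-group min-p selection
        sig = T[T["p_adj"] < 0.01].copy()
        sig["band"] = [
            f"chr1:bin{(G.snp_annotation.loc[s, 'position'] - 1) // 1_000_000}"
            for s in sig["snp"]
        ]
        expected = set()
        for (gene, band, label), grp in sig.groupby(["gene", "band", "label"]):
            grp = grp.assign(pos=[G.snp_annotation.loc[s, "position"] for s in grp["snp"]])
            best = grp.sort_values(["p", "pos"]).iloc[0]
            expected.add((gene, band, label, best["snp"]))
        got = set(zip(out["gene"], out["cytoband"], out["label"], out["snp"]))
        assert got == expected

    def test_collapse_idempotent(self, rng):
        G = make_genotypes(rng.integers(0, 3, size=(4, 5)), pos=np.arange(1, 6) * 300_000)
        rows = [(f"g{i % 3}", f"snp{i}", 0.001 * (i + 1), 0.005, "cis") for i in range(5)]
        T = eqtl_table(rows)
        once = collapse_per_cytoband(T, G, fdr_threshold=0.01)
        twice = collapse_per_cytoband(once, G, fdr_threshold=0.01)
        assert len(once) == len(twice)
        assert set(once["snp"]) == set(twice["snp"])

    def test_cytoband_file_assignment(self, tmp_path, rng):
        cyto = tmp_path / "cyto.txt"
        cyto.write_text("chr1\t0\t1000000\tp11\tgneg\nchr1\t1000000\t2000000\tq11\tgpos\n")
        bands = load_cytobands(str(cyto))
        assert bands["start"].tolist() == [1, 1000001]
        G = make_genotypes(rng.integers(0, 3, size=(4, 2)), pos=[500_000, 1_500_000])
        T = eqtl_table(
            [("geneA", "snp0", 1e-8, 1e-6, "cis"), ("geneA", "snp1", 1e-8, 1e-6, "cis")]
        )
        out = collapse_per_cytoband(T, G, A=AnnotationBundle(cytobands=bands),
                                    fdr_threshold=0.01)
        assert set(out["cytoband"]) == {"chr1:p11", "chr1:q11"}


class TestPseudoTransScreen:
    def test_snp_near_related_gene_removed(self, geo):
        E, G = geo
        # trans eQTL for gene2 (chr2); its pseudogene parent gene1... use a
        # related gene whose start is 200 kb from the SNP
        rel = pd.DataFrame({"gene_id": ["gene2"], "related_gene_id": ["geneP"]})
        E.gene_annotation.loc["geneP"] = ["chr1", 700_000]
        bundle = AnnotationBundle(gene_relations=rel)
        T = eqtl_table([("gene2", "snp0", 1e-8, 1e-6, "trans")])
        out = pseudo_trans_screen(T, E, G, bundle)
        assert len(out) == 0

    def test_unrelated_trans_retained(self, geo):
        E, G = geo
        rel = pd.DataFrame({"gene_id": ["geneX"], "related_gene_id": ["geneY"]})
        bundle = AnnotationBundle(gene_relations=rel)
        T = eqtl_table([("gene2", "snp0", 1e-8, 1e-6, "trans")])
        out = pseudo_trans_screen(T, E, G, bundle)
        assert len(out) == 1

    def test_homology_region_matches_interval_oracle(self, rng, tmp_path):
        n_snps = 30
        pos = np.sort(rng.choice(np.arange(1, 50_000_000), size=n_snps, replace=False))
        G = make_genotypes(rng.integers(0, 3, size=(4, n_snps)), pos=pos)
        E = make_expression(rng.normal(size=(4, 5)), chrom=["chr9"] * 5,
                            start=[10] * 5)
        hom_rows = []
        for i in range(5):
            start = int(rng.integers(1, 40_000_000))
            hom_rows.append(f"chr1\t{start - 1}\t{start + 50_000}\tgene{i}")
        hom_file = tmp_path / "hom.bed"
        hom_file.write_text("\n".join(hom_rows) + "\n")
        hom = load_homology_regions(str(hom_file))
        bundle = AnnotationBundle(homology_regions=hom)
        rows = [(f"gene{rng.integers(5)}", f"snp{rng.integers(n_snps)}",
                 1e-8, 1e-6, "trans") for _ in range(60)]
        T = eqtl_table(rows).drop_duplicates(subset=["gene", "snp"])
        out = pseudo_trans_screen(T, E, G, bundle, window=1_000_000)

        kept_expected = []
        for _, row in T.iterrows():
            p = G.snp_annotation.loc[row["snp"], "position"]
            regions = hom[hom["gene_id"] == row["gene"]]
            hit = any(
                r["start"] - 1_000_000 <= p <= r["end"] + 1_000_000
                for _, r in regions.iterrows()
            )
            if not hit:
                kept_expected.append((row["gene"], row["snp"]))
        assert set(zip(out["gene"], out["snp"])) == set(kept_expected)

    def test_cis_records_never_removed(self, geo):
        E, G = geo
        rel = pd.DataFrame({"gene_id": ["gene0"], "related_gene_id": ["gene1"]})
        bundle = AnnotationBundle(gene_relations=rel)
        T = eqtl_table([("gene0", "snp0", 1e-8, 1e-6, "cis")])
        out = pseudo_trans_screen(T, E, G, bundle)
        assert len(out) == 1

    def test_empty_annotation_passes_through(self, geo):
        E, G = geo
        T = eqtl_table([("gene2", "snp0", 1e-8, 1e-6, "trans")])
        out = pseudo_trans_screen(T, E, G, AnnotationBundle())
        assert len(out) == len(T)


def collapsed(rows):
    t = eqtl_table([r[:5] for r in rows])
    t["cytoband"] = [r[5] for r in rows]
    return t


class TestReplication:
    def test_set_arithmetic(self):
        T1 = collapsed([
            ("g1", "s1", 1e-8, 1e-6, "cis", "chr1:p1"),
            ("g2", "s2", 1e-8, 1e-6, "cis", "chr1:p2"),
            ("g3", "s3", 1e-8, 1e-6, "cis", "chr2:p1"),
        ])
        T2 = collapsed([
            ("g1", "s1", 1e-8, 1e-6, "cis", "chr1:p1"),
            ("g2", "s2", 1e-8, 1e-6, "cis", "chr1:p2"),
            ("g4", "s4", 1e-8, 1e-6, "cis", "chr3:p1"),
            ("g5", "s5", 1e-8, 1e-6, "cis", "chr4:p1"),
        ])
        rep = count_replication(T1, T2, fdr_threshold=0.01)
        assert rep.n_overlap["cis"] == 2
        assert rep.n_union["cis"] == 5
        assert rep.replication_ratio["cis"] == pytest.approx(0.4)

    def test_identical_tables_fully_replicate(self):
        T = collapsed([("g1", "s1", 1e-8, 1e-6, "trans", "chr1:p1")])
        rep = count_replication(T, T.copy())
        assert rep.replication_ratio["trans"] == 1.0

    def test_disjoint_tables_zero_ratio(self):
        T1 = collapsed([("g1", "s1", 1e-8, 1e-6, "cis", "chr1:p1")])
        T2 = collapsed([("g2", "s2", 1e-8, 1e-6, "cis", "chr2:p1")])
        rep = count_replication(T1, T2)
        assert rep.replication_ratio["cis"] == 0.0


class TestBroadImpact:
    def _setup(self, rng, gene_chroms):
        genes = list(gene_chroms)
        E = make_expression(
            rng.normal(size=(4, len(genes))),
            chrom=[gene_chroms[g] for g in genes],
            start=[1000] * len(genes),
        )
        E.values.columns = genes
        E.gene_annotation.index = genes
        G = make_genotypes(rng.integers(0, 3, size=(4, 1)), chrom=["chr6"], pos=[5000])
        return E, G

    def test_multi_chromosome_hotspot_reported(self, rng):
        E, G = self._setup(rng, {"gA": "chr1", "gB": "chr20"})
        T1 = collapsed([
            ("gA", "snp0", 1e-9, 1e-7, "trans", "chr6:p1"),
            ("gB", "snp0", 1e-9, 1e-7, "trans", "chr6:p1"),
        ])
        rep = count_replication(T1, T1.copy())
        out = detect_broad_impact(rep, G, E)
        assert len(out) == 1
        assert out[0]["trans_genes"] == ["gA", "gB"]

    def test_single_chromosome_not_reported(self, rng):
        E, G = self._setup(rng, {"gA": "chr3", "gB": "chr3"})
        T1 = collapsed([
            ("gA", "snp0", 1e-9, 1e-7, "trans", "chr6:p1"),
            ("gB", "snp0", 1e-9, 1e-7, "trans", "chr6:p1"),
        ])
        rep = count_replication(T1, T1.copy())
        assert detect_broad_impact(rep, G, E) == []

    def test_single_gene_not_reported(self, rng):
        E, G = self._setup(rng, {"gA": "chr1"})
        T1 = collapsed([("gA", "snp0", 1e-9, 1e-7, "trans", "chr6:p1")])
        rep = count_replication(T1, T1.copy())
        assert detect_broad_impact(rep, G, E) == []
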