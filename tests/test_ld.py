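"""LD core: super-population assignment, r2, MAF, block expansion."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirtas._errors import ConfigurationError, PanelLookupError
from mirtas.catalog import parse_catalog
from mirtas.ld import (
    HaplotypePanel,
    SnpRecord,
    SuperPopulation,
    assign_superpopulation,
    compute_maf,
    compute_r2,
    expand_ld_block,
)

from conftest import hand_panel, random_panel


def oracle_r2(a, b) -> float:
    """Independent oracle: enumerate the 2x2 haplotype table by counting."""
    a = [int(x) for x in a]
    b = [int(x) for x in b]
    n = len(a)
    n11 = sum(1 for x, y in zip(a, b) if x == 1 and y == 1)
    n1_ = sum(a)
    n_1 = sum(b)
    pa, pb, pab = n1_ / n, n_1 / n, n11 / n
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom == 0:
        return 0.0
    return (pab - pa * pb) ** 2 / denom


class TestAssignSuperpopulation:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Norwegian", SuperPopulation.EUR),
            ("Japanese individuals from Tokyo", SuperPopulation.ASN),
            ("Brazilian", SuperPopulation.EUR),  # no keyword -> fallback
            ("Yoruba in Ibadan, Nigeria", SuperPopulation.AFR),
            ("1,200 Mexican American adults", SuperPopulation.AMR),
            ("Han Chinese cases", SuperPopulation.ASN),
            ("4,000 UK individuals", SuperPopulation.EUR),
            ("", SuperPopulation.EUR),
            # keyword-order precedence: the European row is scanned first
            ("African American and Caucasian cohorts", SuperPopulation.EUR),
        ],
    )
    def test_keyword_mapping(self, text, expected):
        assert assign_superpopulation(text) is expected

    @given(st.text(max_size=60))
    def test_total_function(self, text):
        assert assign_superpopulation(text) in set(SuperPopulation)


class TestComputeR2:
    def test_identical_columns_are_perfectly_correlated(self):
        snps = [SnpRecord("1", 10, "a", "A", "G"),
                SnpRecord("1", 20, "b", "A", "G")]
        col = np.array([1, 0, 1, 0, 1, 1, 0, 0], dtype=np.int8)
        panel = HaplotypePanel(snps, np.column_stack([col, col]))
        assert compute_r2(panel, "a", "b") == pytest.approx(1.0)

    def test_complement_columns_are_perfectly_correlated(self):
        snps = [SnpRecord("1", 10, "a", "A", "G"),
                SnpRecord("1", 20, "b", "A", "G")]
        col = np.array([1, 0, 1, 0, 1, 1, 0, 0], dtype=np.int8)
        panel = HaplotypePanel(snps, np.column_stack([col, 1 - col]))
        assert compute_r2(panel, "a", "b") == pytest.approx(1.0)

    def test_hand_counted_panel_gives_exactly_0_6(self):
        panel = hand_panel()
        assert compute_r2(panel, "rsA", "rsB") == pytest.approx(0.6, abs=1e-12)

    def test_monomorphic_snp_gives_zero(self):
        snps = [SnpRecord("1", 10, "a", "A", "G"),
                SnpRecord("1", 20, "b", "A", "G")]
        mat = np.column_stack([np.ones(8, dtype=np.int8),
                               np.array([1, 0] * 4, dtype=np.int8)])
        panel = HaplotypePanel(snps, mat)
        assert compute_r2(panel, "a", "b") == 0.0

    def test_unknown_rsid_raises_lookup_error(self):
        with pytest.raises(PanelLookupError):
            compute_r2(hand_panel(), "rsA", "rsZ")

    def test_symmetry_and_oracle_agreement_all_pairs(self):
        panel = random_panel(seed=3)
        for i, j in itertools.combinations(range(len(panel)), 2):
            a, b = f"rs{i}", f"rs{j}"
            r2 = compute_r2(panel, a, b)
            assert r2 == pytest.approx(compute_r2(panel, b, a))
            assert r2 == pytest.approx(
                oracle_r2(panel.column(a), panel.column(b)), abs=1e-12)
            assert 0.0 <= r2 <= 1.0

    def test_missing_alleles_excluded_pairwise(self):
        snps = [SnpRecord("1", 10, "a", "A", "G"),
                SnpRecord("1", 20, "b", "A", "G")]
        base = hand_panel().matrix
        mat = np.vstack([base, [[-1, 1], [1, -1]]]).astype(np.int8)
        panel = HaplotypePanel(snps, mat)
        assert compute_r2(panel, "a", "b") == pytest.approx(0.6, abs=1e-12)


class TestComputeMaf:
    def test_monomorphic_reports_alt_at_zero(self):
        snps = [SnpRecord("1", 10, "a", "A", "G")]
        panel = HaplotypePanel(snps, np.zeros((8, 1), dtype=np.int8))
        assert compute_maf(panel, "a") == ("G", 0.0)

    def test_tie_at_half_reports_alt(self):
        snps = [SnpRecord("1", 10, "a", "A", "G")]
        panel = HaplotypePanel(
            snps, np.array([[1]] * 4 + [[0]] * 4, dtype=np.int8))
        assert compute_maf(panel, "a") == ("G", 0.5)

    def test_direct_count(self):
        panel = hand_panel()
        allele, maf = compute_maf(panel, "rsB")
        assert (allele, maf) == ("T", 0.375)

    def test_major_alt_reports_ref_as_minor(self):
        snps = [SnpRecord("1", 10, "a", "A", "G")]
        panel = HaplotypePanel(
            snps, np.array([[1]] * 6 + [[0]] * 2, dtype=np.int8))
        assert compute_maf(panel, "a") == ("A", 0.25)


class _Assoc:
    def __init__(self, snp, trait="t"):
        self.index_snp = snp
        self.trait = trait


class TestExpandLdBlock:
    def test_index_only_block(self):
        panel = random_panel(seed=5, n_snps=5, n_hap=200)
        block = expand_ld_block(_Assoc("rs0"), panel)
        assert block.member_rsids() == {"rs0"}
        assert block.members[0].r2 == 1.0

    def test_boundary_r2_excluded_at_strict_threshold(self):
        block = expand_ld_block(_Assoc("rsA"), hand_panel(), r2_threshold=0.6)
        assert block.member_rsids() == {"rsA"}

    def test_boundary_r2_included_below_threshold(self):
        block = expand_ld_block(_Assoc("rsA"), hand_panel(), r2_threshold=0.59)
        assert block.member_rsids() == {"rsA", "rsB"}

    def test_duplicated_column_in_perfect_ld(self):
        snps = [SnpRecord("1", 10, "a", "A", "G"),
                SnpRecord("1", 20, "b", "C", "T")]
        col = np.array([1, 0, 1, 0, 1, 1, 0, 0], dtype=np.int8)
        panel = HaplotypePanel(snps, np.column_stack([col, col]))
        block = expand_ld_block(_Assoc("a"), panel)
        by_id = {m.rsid: m for m in block.members}
        assert by_id["b"].r2 == pytest.approx(1.0)

    def test_window_excludes_distant_snps(self):
        snps = [SnpRecord("1", 10, "a", "A", "G"),
                SnpRecord("1", 5000, "b", "C", "T")]
        col = np.array([1, 0, 1, 0, 1, 1, 0, 0], dtype=np.int8)
        panel = HaplotypePanel(snps, np.column_stack([col, col]))
        block = expand_ld_block(_Assoc("a"), panel, window_bp=1000)
        assert block.member_rsids() == {"a"}

    def test_absent_index_snp_yields_unresolved_block(self, caplog):
        panel = random_panel(seed=5, n_snps=5)
        block = expand_ld_block(_Assoc("rs_missing"), panel)
        assert block.unresolved and block.members == []

    def test_block_invariants(self):
        panel = random_panel(seed=11)
        for i in range(5):
            block = expand_ld_block(_Assoc(f"rs{i}"), panel, r2_threshold=0.1)
            assert f"rs{i}" in block.member_rsids()
            for m in block.members:
                assert m.rsid == f"rs{i}" or m.r2 > 0.1
                assert 0.0 <= m.maf <= 0.5


class TestPanelIO:
    def test_odd_haplotype_count_warns(self, caplog):
        snps = [SnpRecord("1", 10, "a", "A", "G")]
        with caplog.at_level("WARNING"):
            HaplotypePanel(snps, np.array([[0], [1], [0]], dtype=np.int8))
        assert any("odd" in r.message for r in caplog.records)

    def test_matrix_file_dialect_round_trip(self, tmp_path):
        snp_path = tmp_path / "snps.tsv"
        snp_path.write_text(
            "chrom\tpos\trsid\tref\talt\nchr1\t100\trsA\tA\tG\n"
            "chr1\t150\trsB\tC\tT\n")
        mat_path = tmp_path / "haps.txt"
        mat_path.write_text("1 1\n1 1\n1 1\n1 0\n0 0\n0 0\n0 0\n0 0\n")
        panel = HaplotypePanel.from_matrix_files(snp_path, mat_path)
        assert compute_r2(panel, "rsA", "rsB") == pytest.approx(0.6, abs=1e-12)

    def test_vcf_loader_matches_engineered_ld(self, fixture_dir,
                                              fixture_manifest):
        panel = HaplotypePanel.from_vcf(str(fixture_dir / "panel.vcf"))
        for event in fixture_manifest["events"]:
            if "tas_snp" not in event:
                continue
            r2 = compute_r2(panel, event["index_snp"], event["tas_snp"])
            assert r2 == pytest.approx(event["r2_achieved"], abs=1e-9)


class TestParseCatalog:
    def _write(self, tmp_path, rows):
        path = tmp_path / "cat.tsv"
        header = "SNPS\tDISEASE/TRAIT\tINITIAL SAMPLE SIZE\tP-VALUE\tPUBMEDID"
        path.write_text("\n".join([header] + rows) + "\n")
        return str(path)

    def test_filters(self, tmp_path):
        path = self._write(tmp_path, [
            "rs10\theight\tNorwegian\t2e-6\t1",       # kept
            "rs11 x rs12\theight\tNorwegian\t2e-9\t2",  # multi-SNP
            "rs13\theight\tNorwegian\t1.0e-5\t3",      # boundary p: strict <
            "rs14\theight\tNorwegian\tNR\t4",          # malformed p
        ])
        kept = parse_catalog(path)
        assert [a.index_snp for a in kept] == ["rs10"]
        assert kept[0].p_value == pytest.approx(2e-6)

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("SNPS\tP-VALUE\nrs1\t1e-9\n")
        with pytest.raises(ConfigurationError, match="DISEASE/TRAIT"):
            parse_catalog(str(path))
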