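"""Seed-site prediction, conservation, allelic complements and diffs."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirtas._errors import DataError
from mirtas.sites import (
    MiRNA,
    TargetSite,
    UTRSnp,
    conservation_number,
    diff_sites,
    enumerate_alternate_sequences,
    find_sites,
    seed_patterns,
    snp_to_utr_strand,
)

LET7A = MiRNA("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")

_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def _rna(s):
    return s.upper().replace("T", "U")


def oracle_sites(utr: str, mirna: MiRNA) -> set[tuple[int, str]]:
    """Brute-force oracle: slide a window and test Watson-Crick pairing of
    UTR bases against miRNA seed positions directly, then collapse to the
    strongest type per seed location."""
    seq = _rna(utr)
    mir = _rna(mirna.mature_sequence)

    def pairs_core(o, upto):  # UTR o.. pairs antiparallel with miRNA 2..upto
        span = upto - 1  # number of paired bases
        if o < 0 or o + span > len(seq):
            return False
        return all((seq[o + i], mir[upto - 1 - i]) in _PAIR
                   for i in range(span))

    best: dict[int, tuple[int, int, str]] = {}
    order = {"7mer-1a": 0, "7mer-m8": 1, "8mer-1a": 2}
    for o in range(len(seq)):
        hits = []
        if pairs_core(o, 8) and o + 7 < len(seq) and seq[o + 7] == "A":
            hits.append((o, "8mer-1a", o + 1))
        if pairs_core(o, 8):
            hits.append((o, "7mer-m8", o + 1))
        if pairs_core(o, 7) and o + 6 < len(seq) and seq[o + 6] == "A":
            hits.append((o, "7mer-1a", o))
        for off, t, core in hits:
            if core not in best or order[t] > best[core][0]:
                best[core] = (order[t], off, t)
    return {(off, t) for _, off, t in best.values()}


class TestSeedPatterns:
    def test_let7a_patterns(self):
        pat = seed_patterns(LET7A)
        assert pat.eight_mer_1a == "CUACCUCA"
        assert pat.seven_mer_m8 == "CUACCUC"
        assert pat.seven_mer_1a == "UACCUCA"

    def test_short_mirna_rejected(self):
        with pytest.raises(DataError):
            MiRNA("tiny", "UGAGGUA")


class TestFindSites:
    @pytest.mark.parametrize(
        "utr,expected",
        [
            ("AACUACCUCAGG", [(2, "8mer-1a")]),
            ("AACUACCUCGG", [(2, "7mer-m8")]),
            ("GGGGGGGG", []),
            ("AAUACCUCAGG", [(2, "7mer-1a")]),
        ],
    )
    def test_worked_examples(self, utr, expected):
        sites = find_sites(utr, [LET7A])
        assert [(s.utr_offset, s.site_type) for s in sites] == expected

    def test_dna_and_rna_inputs_agree(self):
        rna_sites = find_sites("AACUACCUCAGG", [LET7A])
        dna_sites = find_sites("aactacctcagg", [LET7A])
        assert [(s.utr_offset, s.site_type) for s in rna_sites] == \
            [(s.utr_offset, s.site_type) for s in dna_sites]

    def test_n_never_matches(self):
        assert find_sites("AACUACCNCAGG", [LET7A]) == []

    def test_multiple_sites_reported(self):
        utr = "CUACCUCAGGGGGGCUACCUCA"
        sites = find_sites(utr, [LET7A])
        assert [(s.utr_offset, s.site_type) for s in sites] == \
            [(0, "8mer-1a"), (14, "8mer-1a")]

    @given(st.text(alphabet="ACGU", min_size=20, max_size=80),
           st.text(alphabet="ACGU", min_size=22, max_size=22))
    def test_matches_bruteforce_oracle(self, utr, mirseq):
        mirna = MiRNA("m", mirseq)
        got = {(s.utr_offset, s.site_type) for s in find_sites(utr, [mirna])}
        assert got == oracle_sites(utr, mirna)

    @given(st.text(alphabet="ACGU", min_size=22, max_size=22),
           st.text(alphabet="ACGU", min_size=5, max_size=20),
           st.text(alphabet="ACGU", min_size=5, max_size=20))
    def test_8mer_collapse_swallows_weaker_types(self, mirseq, left, right):
        mirna = MiRNA("m", mirseq)
        pat = seed_patterns(mirna)
        utr = left + pat.eight_mer_1a + right
        sites = find_sites(utr, [mirna])
        off = len(left)
        # the embedded 8mer location reports exactly one site, the 8mer
        claimed = [s for s in sites
                   if s.utr_offset in (off, off + 1)]
        assert len(claimed) == 1
        assert claimed[0].site_type == "8mer-1a"
        assert claimed[0].utr_offset == off


class TestConservation:
    def _site_and_utrs(self, n_with_site):
        pat = seed_patterns(LET7A).eight_mer_1a
        with_site = "GG" + pat + "GGGGGGGGGG"
        without = "G" * 20
        species = ["mouse", "rat", "dog", "chicken"]
        utrs = {sp: (with_site if i < n_with_site else without)
                for i, sp in enumerate(species)}
        site = TargetSite("let-7a", "GENE", 2, "8mer-1a")
        return site, utrs

    @pytest.mark.parametrize("n_with,expected", [(0, 1), (4, 5), (2, 3)])
    def test_species_counting(self, n_with, expected):
        site, utrs = self._site_and_utrs(n_with)
        assert conservation_number(site, LET7A, utrs) == expected

    def test_missing_ortholog_counts_as_absent(self):
        site, utrs = self._site_and_utrs(4)
        del utrs["dog"]
        assert conservation_number(site, LET7A, utrs) == 4

    def test_same_type_required(self):
        pat = seed_patterns(LET7A)
        site = TargetSite("let-7a", "GENE", 2, "8mer-1a")
        utrs = {"mouse": "GG" + pat.seven_mer_m8 + "GGGGGGGGG"}
        assert conservation_number(site, LET7A, utrs) == 1


class TestAlternateSequences:
    def test_single_snp(self):
        out = enumerate_alternate_sequences(
            "ACGTACGT", [UTRSnp("rs1", 2, "G", "A")])
        assert len(out) == 1
        label, seq, applied = out[0]
        assert seq == "ACATACGT" and label == "rs1=A"

    def test_two_close_snps_give_three_haplotypes(self):
        # the A/T pair: alternate haplotypes TA, AT... encoded as T at one,
        # T at the other, and both
        out = enumerate_alternate_sequences(
            "AACAAAAA",
            [UTRSnp("rs1", 1, "A", "T"), UTRSnp("rs2", 4, "A", "T")])
        seqs = {seq for _, seq, _ in out}
        assert seqs == {"ATCAAAAA", "AACATAAA", "ATCATAAA"}

    def test_distant_snps_form_independent_clusters(self):
        seq = "A" * 60
        out = enumerate_alternate_sequences(
            seq, [UTRSnp("rs1", 2, "A", "G"), UTRSnp("rs2", 52, "A", "G")])
        assert len(out) == 2
        for _, alt, applied in out:
            assert sum(1 for a, b in zip(seq, alt) if a != b) == 1

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_cluster_of_k_yields_2k_minus_1(self, k):
        seq = "A" * 40
        snps = [UTRSnp(f"rs{i}", 2 + 3 * i, "A", "C") for i in range(k)]
        out = enumerate_alternate_sequences(seq, snps)
        assert len(out) == 2 ** k - 1
        assert len({s for _, s, _ in out}) == 2 ** k - 1

    def test_reference_mismatch_names_the_snp(self):
        with pytest.raises(DataError, match="rsBad"):
            enumerate_alternate_sequences(
                "ACGT", [UTRSnp("rsBad", 1, "G", "A")])

    def test_cluster_cap_enforced(self):
        snps = [UTRSnp(f"rs{i}", i, "A", "C") for i in range(11)]
        with pytest.raises(DataError, match="cap"):
            enumerate_alternate_sequences("A" * 20, snps)

    def test_t_u_equivalent_reference_check(self):
        out = enumerate_alternate_sequences(
            "ACGU", [UTRSnp("rs1", 3, "T", "C")])
        assert out[0][1] == "ACGC"


class TestStrandProjection:
    def test_plus_strand_passthrough(self):
        snp = snp_to_utr_strand("rs1", 105, "A", "G", 100, 120, "+")
        assert (snp.utr_pos, snp.ref, snp.alt) == (4, "A", "G")

    def test_minus_strand_reverse_complements(self):
        snp = snp_to_utr_strand("rs1", 105, "A", "G", 100, 120, "-")
        assert (snp.utr_pos, snp.ref, snp.alt) == (15, "T", "C")

    def test_outside_utr_rejected(self):
        with pytest.raises(DataError):
            snp_to_utr_strand("rs1", 300, "A", "G", 100, 120, "+")


class TestDiffSites:
    def test_abolished_site(self):
        ref = "AACUACCUCAGG"  # 8mer-1a for let-7a at offset 2
        alt = "AACUACGUCAGG"  # core broken
        diffs = diff_sites(find_sites(ref, [LET7A]),
                           find_sites(alt, [LET7A]), "rsX=G", ("rsX",))
        assert len(diffs) == 1
        assert diffs[0].direction == "abolished"
        assert diffs[0].site.key() == ("let-7a", 2, "8mer-1a")

    def test_created_site(self):
        ref = "AACUACGUCAGG"
        alt = "AACUACCUCAGG"
        diffs = diff_sites(find_sites(ref, [LET7A]), find_sites(alt, [LET7A]))
        assert [d.direction for d in diffs] == ["created"]

    def test_type_change_is_one_abolished_one_created(self):
        ref = "AACUACCUCAGG"  # 8mer-1a at 2
        alt = "AACUACCUCGGG"  # anchor A lost -> 7mer-m8 at 2
        diffs = diff_sites(find_sites(ref, [LET7A]), find_sites(alt, [LET7A]))
        assert sorted(d.direction for d in diffs) == ["abolished", "created"]

    def test_identical_site_lists_give_empty_diff(self):
        sites = find_sites("AACUACCUCAGG", [LET7A])
        assert diff_sites(sites, sites) == []

    @given(st.text(alphabet="ACGU", min_size=20, max_size=60),
           st.text(alphabet="ACGU", min_size=20, max_size=60))
    def test_created_and_abolished_disjoint(self, a, b):
        ra = find_sites(a, [LET7A])
        rb = find_sites(b, [LET7A])
        diffs = diff_sites(ra, rb)
        created = {d.site.key() for d in diffs if d.direction == "created"}
        abolished = {d.site.key() for d in diffs if d.direction == "abolished"}
        assert not created & abolished
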