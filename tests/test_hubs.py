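"""Targeting score, length normalization and the hub Monte Carlo test."""

import numpy as np
import pytest

from mirtas._errors import ConfigurationError, DataError
from mirtas.hubs import (
    HubConfig,
    SiteIndex,
    hub_scan,
    hub_test,
    length_normalize,
    targeting_score,
)
from mirtas.sites import TargetSite


def _site(gene, offset, site_type, mirna="miR-1", conservation=5):
    return TargetSite(mirna, gene, offset, site_type, conservation)


def _index(sites, lengths=None):
    genes = {s.gene_symbol for s in sites}
    lengths = lengths or {g: 300 for g in genes}
    return SiteIndex.from_sites(sites, lengths)


CFG = HubConfig(reps=99, rng_seed=1)


class TestTargetingScore:
    def test_single_weak_site_scores_one(self):
        idx = _index([_site("G1", 10, "7mer-1a")])
        score, n, _ = targeting_score("miR-1", ["G1"], idx, CFG)
        assert (score, n) == (1.0, 1)

    def test_8mer_site_weighted(self):
        idx = _index([_site("G1", 10, "8mer-1a")])
        assert targeting_score("miR-1", ["G1"], idx, CFG)[0] == 1.5

    def test_proximal_pair_both_weighted(self):
        idx = _index([_site("G1", 10, "7mer-m8"), _site("G1", 60, "7mer-m8")])
        assert targeting_score("miR-1", ["G1"], idx, CFG)[0] == 3.0

    def test_distal_pair_unweighted(self):
        idx = _index([_site("G1", 10, "7mer-m8"), _site("G1", 100, "7mer-m8")])
        assert targeting_score("miR-1", ["G1"], idx, CFG)[0] == 2.0

    def test_conservation_filter(self):
        idx = _index([_site("G1", 10, "7mer-1a", conservation=3)])
        assert targeting_score("miR-1", ["G1"], idx, CFG)[0] == 0.0
        relaxed = HubConfig(reps=99, min_conservation=3)
        assert targeting_score("miR-1", ["G1"], idx, relaxed)[0] == 1.0

    def test_other_mirna_sites_ignored(self):
        idx = _index([_site("G1", 10, "8mer-1a", mirna="miR-2")])
        assert targeting_score("miR-1", ["G1"], idx, CFG)[0] == 0.0

    def test_gene_mode_takes_max_weight_per_gene(self):
        idx = _index([_site("G1", 10, "8mer-1a"), _site("G1", 200, "7mer-1a")])
        gene_cfg = HubConfig(reps=99, score_mode="gene")
        assert targeting_score("miR-1", ["G1"], idx, gene_cfg)[0] == 1.5

    def test_unit_weight_equals_raw_site_count(self):
        """With weight 1 and conservation 1 the score is plain counting."""
        rng = np.random.default_rng(4)
        sites = [
            _site(f"G{g}", int(rng.integers(0, 280)),
                  ["7mer-1a", "7mer-m8", "8mer-1a"][rng.integers(3)],
                  conservation=int(rng.integers(1, 6)))
            for g in range(10) for _ in range(rng.integers(0, 4))
        ]
        idx = _index(sites)
        cfg = HubConfig(reps=9, weight=1.0, min_conservation=1)
        genes = [f"G{g}" for g in range(10)]
        score, _, _ = targeting_score("miR-1", genes, idx, cfg)
        assert score == len(sites)

    def test_additive_over_disjoint_subsets(self):
        sites = [_site("G1", 10, "8mer-1a"), _site("G2", 10, "7mer-1a"),
                 _site("G3", 5, "7mer-m8"), _site("G3", 40, "7mer-m8")]
        idx = _index(sites)
        whole = targeting_score("miR-1", ["G1", "G2", "G3"], idx, CFG)[0]
        parts = sum(targeting_score("miR-1", [g], idx, CFG)[0]
                    for g in ("G1", "G2", "G3"))
        assert whole == pytest.approx(parts)


class TestLengthNormalize:
    def test_equal_lengths_identity(self):
        assert length_normalize(7.0, 400.0, 400.0) == 7.0

    def test_ratio_form(self):
        assert length_normalize(10.0, 500.0, 1000.0) == pytest.approx(5.0)

    def test_zero_score_stays_zero(self):
        assert length_normalize(0.0, 300.0, 200.0) == 0.0

    def test_nonpositive_length_rejected(self):
        with pytest.raises(DataError):
            length_normalize(1.0, 0.0, 100.0)


def _planted_universe(n_genes=60, n_targets=8, seed=0):
    rng = np.random.default_rng(seed)
    sites, lengths = [], {}
    for g in range(n_genes):
        gene = f"G{g:03d}"
        lengths[gene] = int(rng.integers(200, 400))
        if g < n_targets:
            sites.append(_site(gene, int(rng.integers(0, 150)), "8mer-1a"))
    return SiteIndex.from_sites(sites, lengths), sorted(lengths)


class TestHubTest:
    def test_add_one_smoothing_floor(self):
        """Candidates hold every target gene, so no null draw can reach the
        observed score and p hits its floor (1+0)/(reps+1)."""
        idx, universe = _planted_universe(n_genes=60, n_targets=8)
        cfg = HubConfig(reps=999, rng_seed=5)
        res = hub_test("miR-1", universe[:8], universe, idx, cfg)
        assert res.observed_score == pytest.approx(8 * 1.5)
        assert res.empirical_p == pytest.approx(1 / 1000)

    def test_zero_observed_score_gives_p_one(self):
        idx, universe = _planted_universe(n_targets=0)
        cfg = HubConfig(reps=199, rng_seed=5)
        res = hub_test("miR-1", universe[:10], universe, idx, cfg)
        assert res.observed_score == 0.0
        assert res.empirical_p == 1.0

    def test_seeded_reproducibility(self):
        idx, universe = _planted_universe()
        cfg = HubConfig(reps=500, rng_seed=11)
        a = hub_test("miR-1", universe[:12], universe, idx, cfg)
        b = hub_test("miR-1", universe[:12], universe, idx, cfg)
        assert a == b

    def test_candidates_outside_universe_dropped_with_warning(self, caplog):
        idx, universe = _planted_universe()
        cfg = HubConfig(reps=99, rng_seed=2)
        with caplog.at_level("WARNING"):
            res = hub_test("miR-1", universe[:10] + ["NOT_A_GENE"],
                           universe, idx, cfg)
        assert any("outside" in r.message for r in caplog.records)
        assert res.reps_used == 99

    def test_degenerate_inputs_rejected(self):
        idx, universe = _planted_universe()
        with pytest.raises(DataError):
            hub_test("miR-1", universe, universe, idx, HubConfig(reps=9))

    def test_p_bounds(self):
        idx, universe = _planted_universe()
        cfg = HubConfig(reps=200, rng_seed=3)
        for start in (0, 10, 30):
            res = hub_test("miR-1", universe[start:start + 10], universe,
                           idx, cfg)
            assert 0.0 < res.empirical_p <= 1.0


class TestHubScan:
    def test_identical_seed_mirnas_get_identical_results(self):
        idx, universe = _planted_universe()
        sites2 = [
            TargetSite("miR-2", s.gene_symbol, s.utr_offset, s.site_type,
                       s.conservation)
            for g in idx.sites_by_gene.values() for s in g
        ]
        for s in sites2:
            idx.sites_by_gene.setdefault(s.gene_symbol, []).append(s)
        cfg = HubConfig(reps=300, rng_seed=9)
        frame = hub_scan({"t": universe[:10]}, ["miR-1", "miR-2"], universe,
                         idx, cfg)
        a, b = frame[frame.mirna == "miR-1"], frame[frame.mirna == "miR-2"]
        assert a.iloc[0].observed == b.iloc[0].observed
        assert a.iloc[0].p == b.iloc[0].p

    def test_sorted_by_p_then_name(self):
        idx, universe = _planted_universe()
        cfg = HubConfig(reps=200, rng_seed=9)
        frame = hub_scan({"t": universe[:10]}, ["miR-9", "miR-1"], universe,
                         idx, cfg)
        assert list(frame.p) == sorted(frame.p)

    def test_siteless_mirna_p_is_one(self):
        idx, universe = _planted_universe()
        cfg = HubConfig(reps=100, rng_seed=9)
        frame = hub_scan({"t": universe[:10]}, ["miR-none"], universe, idx,
                         cfg)
        assert frame.iloc[0].p == 1.0
        assert not frame.iloc[0].significant


class TestHubConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(weight=0.5), dict(reps=0), dict(min_conservation=6),
                   dict(score_mode="banana")])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            HubConfig(**kwargs)
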