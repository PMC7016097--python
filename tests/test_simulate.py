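import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endresect import (CATEGORIES, TruthParameters, apply_enzyme_condition,
                       preset, simulate_library)
from endresect.simulate import SPECIES_BOUND, hotspot_centers


def small_params(**kw):
    base = dict(n_hotspots=50, n_cells=50, breaks_per_cell=40,
                background_rate=0.0, spike_fraction=0.0, seed=7)
    base.update(kw)
    return TruthParameters(**base)


class TestEmissionRules:
    def test_pure_ri_central_reads_mirror_the_cut_displacement(self):
        p = small_params(p_resected=0, p_ri=1, p_cc=0, displacement=30)
        track, truth = simulate_library(p)
        centers = hotspot_centers(p)
        df = track.data
        central = df[df["species"] == "spo11_ri"].copy()
        off = central["pos"].to_numpy() - centers[central["hotspot"].to_numpy()]
        top = central["strand"].to_numpy() == "+"
        assert (off[top] == -30).all()          # cut left of center: top central
        assert (off[~top] == 30).all()          # cut right of center: bottom central
        assert len(central) == len(truth)       # one blocked end per RI event

    def test_pure_doublecut_strand_modes_separated_by_spacing(self):
        p = small_params(p_resected=0, p_ri=0, p_cc=0, p_doublecut=1,
                         doublecut_low=50, doublecut_high=50, displacement=0)
        track, truth = simulate_library(p)
        centers = hotspot_centers(p)
        df = track.data
        off = df["pos"].to_numpy() - centers[df["hotspot"].to_numpy()]
        top_mode = int(pd.Series(off[df["strand"] == "+"]).mode()[0])
        bot_mode = int(pd.Series(off[df["strand"] == "-"]).mode()[0])
        assert top_mode - bot_mode == 50

    def test_pure_resected_leaves_a_readless_gap(self):
        p = small_params(p_resected=1, p_ri=0, p_cc=0, gap_mean=800,
                         gap_sd=1e-6, long_mean=200, long_sd=1.0,
                         displacement=0)
        track, _ = simulate_library(p)
        centers = hotspot_centers(p)
        off = track.data["pos"].to_numpy() - centers[track.data["hotspot"].to_numpy()]
        assert (np.abs(off) > 990).all()

    def test_two_endpoints_per_break_event(self):
        p = small_params(spike_fraction=0.02)
        track, truth = simulate_library(p)
        non_bg = track.data[track.data["species"] != "background"]
        assert len(non_bg) == 2 * len(truth)

    def test_fixed_seed_reproducible(self):
        a, ta = simulate_library(small_params(seed=123))
        b, tb = simulate_library(small_params(seed=123))
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(ta, tb)

    def test_endpoints_reproducible_from_truth_records(self):
        p = small_params(spike_fraction=0.02)
        track, truth = simulate_library(p)
        rebuilt = pd.DataFrame({
            "pos": np.concatenate([truth["top_pos"], truth["bottom_pos"]]),
            "strand": np.repeat(["+", "-"], len(truth)),
        })
        emitted = track.data[track.data["species"] != "background"]
        a = rebuilt.sort_values(["strand", "pos"]).reset_index(drop=True)
        b = emitted[["pos", "strand"]].astype({"strand": str}).sort_values(
            ["strand", "pos"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_probabilities_summing_above_one_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            small_params(p_resected=0.9, p_ri=0.2)

    def test_endpoint_distance_distribution_matches_configuration(self):
        """Under pure resection the empirical endpoint distances follow the
        configured gap+gamma distribution (two-sample KS, alpha=0.01)."""
        p = small_params(n_hotspots=200, n_cells=200, breaks_per_cell=30,
                         p_resected=1, p_ri=0, p_cc=0, displacement=0, seed=5)
        track, _ = simulate_library(p)
        centers = hotspot_centers(p)
        off = np.abs(track.data["pos"].to_numpy()
                     - centers[track.data["hotspot"].to_numpy()])
        assert len(off) >= 10_000
        ref = p.resection_distance(np.random.default_rng(99), 20_000)
        assert stats.ks_2samp(off, ref).pvalue > 0.01


class TestEnzymeConditions:
    def make_species_track(self, cat):
        p = small_params(p_resected=float(cat == "resected"),
                         p_ri=float(cat == "spo11_ri"),
                         p_cc=float(cat == "spo11_cc"),
                         p_doublecut=float(cat == "double_cut"))
        return simulate_library(p)[0]

    def test_exot_only_erases_cleavage_complex_signal(self):
        track = self.make_species_track("spo11_cc")
        out = apply_enzyme_condition(track, "ExoT_only")
        assert len(out) == 0

    def test_tdp2_inactive_on_spo11_ri(self):
        track = self.make_species_track("spo11_ri")
        out = apply_enzyme_condition(track, "TDP2_ExoT")
        assert set(out.data["species"].astype(str)) <= {"free"}
        assert (out.data["species"] == "spo11_ri").sum() == 0

    def test_tdp2_recovers_cleavage_complexes(self):
        track = self.make_species_track("spo11_cc")
        out = apply_enzyme_condition(track, "TDP2_ExoT")
        assert len(out) == len(track)

    def test_free_ends_untouched_by_every_condition(self):
        track = self.make_species_track("resected")
        for cond in ("ExoVII_ExoT", "ExoT_only", "TDP2_ExoT", "MRN_CtIP_pre"):
            out = apply_enzyme_condition(track, cond,
                                         rng=np.random.default_rng(1))
            assert len(out) == len(track)

    def test_mrn_pretreatment_removes_most_bound_ends(self):
        track = self.make_species_track("spo11_cc")
        out = apply_enzyme_condition(track, "MRN_CtIP_pre", mrn_efficiency=0.9,
                                     rng=np.random.default_rng(3))
        frac = len(out) / len(track)
        assert 0.05 < frac < 0.2

    def test_unknown_condition_rejected(self):
        track = self.make_species_track("resected")
        with pytest.raises(ValueError, match="unknown condition"):
            apply_enzyme_condition(track, "ExoIX")


class TestPresets:
    def test_wt_species_fractions(self):
        p = preset("WT")
        assert p.p_ri == pytest.approx(0.10, abs=0.02)
        assert 0.006 <= p.p_cc <= 0.017

    def test_atm_break_rate_is_4p5_fold_wt(self):
        assert preset("Atm").breaks_per_cell / preset("WT").breaks_per_cell == 4.5

    def test_no_spo11_ri_without_homolog_engagement_or_prdm9(self):
        for name in ("Dmc1", "Prdm9"):
            assert preset(name).p_ri == 0.0

    def test_dmc1_gap_widened_by_400(self):
        assert preset("Dmc1").gap_mean - preset("WT").gap_mean == 400.0

    def test_exo1_mildly_reduces_long_range_resection(self):
        wt, exo1 = preset("WT"), preset("Exo1")
        assert wt.long_mean - exo1.long_mean == pytest.approx(133, abs=1)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset("Spo11")

    def test_overrides_apply(self):
        assert preset("WT", n_hotspots=10).n_hotspots == 10
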