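import json

import numpy as np
import pytest
from scipy.signal import periodogram

from srcconn.pac import pac_mvl
from srcconn.simulate import (BASELINE_PAC_DEPTH, DirectedEdge, GroupTemplate,
                              check_edge_stability, make_group_template,
                              save_cohort, simulate_cohort, simulate_subject)


class TestTemplates:
    def test_tinnitus_loop_structure(self):
        t = make_group_template("tinnitus")
        # bidirectional to auditory, unidirectional to somatosensory
        assert t.has_edge("L_PHC", "L_AUD") and t.has_edge("L_AUD", "L_PHC")
        assert t.has_edge("L_PHC", "L_SOM") and not t.has_edge("L_SOM", "L_PHC")

    def test_pain_mirrored_loop(self):
        p = make_group_template("pain")
        assert p.has_edge("L_PHC", "L_SOM") and p.has_edge("L_SOM", "L_PHC")
        assert p.has_edge("L_PHC", "L_AUD") and not p.has_edge("L_AUD", "L_PHC")

    def test_control_is_null_template(self):
        c = make_group_template("control")
        assert c.edges == []
        assert all(m == BASELINE_PAC_DEPTH for m in c.pac_depth.values())

    def test_patients_raise_power_and_nesting(self):
        c, t = make_group_template("control"), make_group_template("tinnitus")
        assert t.node_powers["pgACC"]["theta"] > c.node_powers["pgACC"]["theta"]
        assert t.node_powers["L_AUD"]["gamma"] > c.node_powers["L_AUD"]["gamma"]
        assert t.pac_depth["L_SOM"] > c.pac_depth["L_SOM"]

    def test_unknown_condition_and_override(self):
        with pytest.raises(ValueError, match="condition"):
            make_group_template("migraine")
        with pytest.raises(ValueError, match="override"):
            make_group_template("control", {"frobnicate": 1})

    def test_pac_depth_bounds_validated(self):
        with pytest.raises(ValueError, match="pac_depth"):
            GroupTemplate("control", {"A": {"theta": 1.0}}, {"A": 1.5}, [])

    def test_edge_lag_validated(self):
        with pytest.raises(ValueError, match="lag"):
            DirectedEdge("A", "B", lag=0)


class TestSimulateSubject:
    def test_determinism(self):
        t = make_group_template("tinnitus")
        s1, r1 = simulate_subject(t, 20, 128, seed=4)
        s2, r2 = simulate_subject(t, 20, 128, seed=4)
        assert np.array_equal(r1.data, r2.data)
        for roi in s1.roi_currents:
            assert np.array_equal(s1.roi_currents[roi], s2.roi_currents[roi])

    def test_unstable_configuration_names_edge(self):
        t = make_group_template("control", {"edges": [
            DirectedEdge("L_PHC", "L_AUD", strength=1.2, lag=1),
            DirectedEdge("L_AUD", "L_PHC", strength=1.2, lag=1)]})
        assert check_edge_stability(t) >= 1.0
        with pytest.raises(ValueError, match="L_PHC->L_AUD"):
            simulate_subject(t, 20, 128, seed=0)

    def test_band_components_spectrally_confined(self):
        src, _ = simulate_subject(make_group_template("control"), 120, 128, seed=2)
        f, p = periodogram(src.components["theta"]["pgACC"], fs=128)
        assert p[(f >= 4) & (f < 7.5)].sum() / p.sum() > 0.9
        f, p = periodogram(src.components["gamma"]["pgACC"], fs=128)
        assert p[(f >= 30.5) & (f < 44)].sum() / p.sum() > 0.9

    def test_bounded_variance(self):
        src, rec = simulate_subject(make_group_template("tinnitus"), 300, 128, seed=3)
        for roi, cur in src.roi_currents.items():
            s = np.linalg.norm(cur, axis=0)
            assert np.abs(s).max() < 10 * s.std()

    def test_single_edge_cross_correlation_peaks_at_lag(self):
        t = make_group_template("control", {"edges": [
            DirectedEdge("L_PHC", "L_SOM", "theta", 0.6, 3)]})
        src, _ = simulate_subject(t, 120, 128, seed=5)
        a = src.components["theta"]["L_PHC"]
        b = src.components["theta"]["L_SOM"]
        lags = np.arange(-8, 9)
        cc = [np.corrcoef(a[: a.size - abs(l)] if l >= 0 else a[-l:],
                          b[l:] if l >= 0 else b[: b.size + l])[0, 1]
              for l in lags]
        assert lags[int(np.argmax(cc))] == 3

    def test_planted_nesting_mvl_converges_to_half_depth(self):
        t = make_group_template("control", {"pac_depth": {
            r: 0.6 for r in make_group_template("control").pac_depth}})
        src, _ = simulate_subject(t, 300, 128, seed=6)
        res = pac_mvl(src.components["theta"]["L_AUD"],
                      src.components["gamma"]["L_AUD"], 128)
        assert res.mvl == pytest.approx(0.3, rel=0.10)

    def test_lag_rescaled_with_sampling_rate(self):
        # 3 samples at 128 Hz ~ 23 ms -> 12 samples at 512 Hz
        t = make_group_template("control", {"edges": [
            DirectedEdge("L_PHC", "L_SOM", "theta", 0.6, 3)]})
        src, _ = simulate_subject(t, 60, 512, seed=7)
        a = src.components["theta"]["L_PHC"]
        b = src.components["theta"]["L_SOM"]
        lags = np.arange(-20, 21)
        cc = [np.corrcoef(a[: a.size - abs(l)] if l >= 0 else a[-l:],
                          b[l:] if l >= 0 else b[: b.size + l])[0, 1]
              for l in lags]
        # smooth narrowband autocorrelation flattens the peak; allow +/- 2
        # samples (~4 ms) around the exact rescaled lag of 12 samples
        assert abs(lags[int(np.argmax(cc))] - 12) <= 2

    def test_argument_validation(self):
        t = make_group_template("control")
        with pytest.raises(ValueError, match="fs"):
            simulate_subject(t, 60, 64)
        with pytest.raises(ValueError, match="duration"):
            simulate_subject(t, 5, 128)


class TestCohort:
    def test_seed_contract(self):
        a = simulate_cohort(2, 15, 128, seed=1, leadfield=np.eye(7), jitter_cv=0.2)
        b = simulate_cohort(2, 15, 128, seed=1, leadfield=np.eye(7), jitter_cv=0.2)
        c = simulate_cohort(2, 15, 128, seed=2, leadfield=np.eye(7), jitter_cv=0.2)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.recording.data, sb.recording.data)
        assert not np.array_equal(a.subjects[0].recording.data,
                                  c.subjects[0].recording.data)
        # same planted template structure regardless of seed
        for sa, sc in zip(a.subjects, c.subjects):
            assert sa.group == sc.group
            assert ([
                (e.source_roi, e.target_roi) for e in sa.sources.truth.edges]
                == [(e.source_roi, e.target_roi) for e in sc.sources.truth.edges])

    def test_group_sizes_and_jitter(self):
        coh = simulate_cohort(3, 15, 128, seed=0, leadfield=np.eye(7), jitter_cv=0.2)
        groups = [s.group for s in coh.subjects]
        assert groups.count("control") == groups.count("tinnitus") == 3
        powers = [s.sources.truth.node_powers["pgACC"]["theta"]
                  for s in coh.subjects if s.group == "tinnitus"]
        assert len(set(powers)) == 3  # inter-subject jitter applied

    def test_n_too_small(self):
        with pytest.raises(ValueError, match="n_per_group"):
            simulate_cohort(1, 15, 128, seed=0, leadfield=np.eye(7))

    def test_save_cohort_layout(self, tmp_path):
        coh = simulate_cohort(2, 15, 128, seed=0, leadfield=np.eye(7))
        save_cohort(coh, tmp_path)
        names = {p.name for p in tmp_path.iterdir()}
        assert "manifest.csv" in names
        assert "tinnitus_000.csv" in names and "tinnitus_000.json" in names
        sidecar = json.loads((tmp_path / "pain_001.json").read_text())
        assert sidecar["group"] == "pain"
        assert any(e["source_roi"] == "L_PHC" for e in sidecar["edges"])
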