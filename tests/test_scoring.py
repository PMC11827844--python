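"""Normative reference derivation and Splice Index composition."""

import numpy as np
import pandas as pd
import pytest

import spliceindex as si


def percentile_oracle(values, p):
    """Linear interpolation between order statistics at (n-1)p + 1."""
    v = np.sort(np.asarray(values, float))
    pos = (v.size - 1) * p
    k = int(np.floor(pos))
    frac = pos - k
    return v[k] if k + 1 >= v.size else v[k] + frac * (v[k + 1] - v[k])


def make_matrices(seed=0, n_ctrl=8, n_dm1=20):
    rng = np.random.default_rng(seed)
    events = ["up1", "up2", "down1"]
    ctrl = pd.DataFrame(
        {"up1": rng.uniform(0.05, 0.15, n_ctrl), "up2": rng.uniform(0.1, 0.2, n_ctrl),
         "down1": rng.uniform(0.8, 0.9, n_ctrl)}, columns=events)
    dm1 = pd.DataFrame(
        {"up1": rng.uniform(0.2, 0.9, n_dm1), "up2": rng.uniform(0.3, 0.95, n_dm1),
         "down1": rng.uniform(0.1, 0.7, n_dm1)}, columns=events)
    return ctrl, dm1


class TestDeriveReference:
    def test_control_median(self):
        ctrl, dm1 = make_matrices()
        ctrl.loc[:, "up1"] = np.resize([0.1, 0.2, 0.3], len(ctrl))
        ref = si.derive_reference(ctrl, dm1)
        assert ref.event("up1")[0] == pytest.approx(np.median(ctrl["up1"]))

    def test_upward_event_hits_percentile_oracle(self):
        ctrl, dm1 = make_matrices()
        dm1.loc[:, "up1"] = np.linspace(0, 1, 20)
        ref = si.derive_reference(ctrl, dm1)
        assert ref.event("up1")[1] == pytest.approx(percentile_oracle(dm1["up1"], 0.95), abs=1e-12)

    def test_downward_event_uses_lower_tail(self):
        """Events losing inclusion in disease anchor at the 5th percentile,
        below the control median."""
        ctrl, dm1 = make_matrices()
        ref = si.derive_reference(ctrl, dm1)
        med, dm95 = ref.event("down1")
        assert dm95 < med
        assert dm95 == pytest.approx(percentile_oracle(dm1["down1"], 0.05), abs=1e-12)

    def test_literal_mode_ignores_direction(self):
        ctrl, dm1 = make_matrices()
        ref = si.derive_reference(ctrl, dm1, oriented=False)
        assert ref.event("down1")[1] == pytest.approx(percentile_oracle(dm1["down1"], 0.95), abs=1e-12)

    def test_sample_size_preconditions(self):
        ctrl, dm1 = make_matrices()
        with pytest.raises(ValueError):
            si.derive_reference(ctrl.iloc[:2], dm1)
        with pytest.raises(ValueError):
            si.derive_reference(ctrl, dm1.iloc[:5])

    def test_all_missing_event_named(self):
        ctrl, dm1 = make_matrices()
        dm1.loc[:, "up2"] = np.nan
        with pytest.raises(ValueError, match="up2"):
            si.derive_reference(ctrl, dm1)

    def test_tsv_round_trip(self, tmp_path):
        ctrl, dm1 = make_matrices()
        ref = si.derive_reference(ctrl, dm1, version="v9")
        ref.to_tsv(tmp_path / "ref.tsv")
        back = si.NormativeReference.from_tsv(tmp_path / "ref.tsv")
        pd.testing.assert_frame_equal(back.values, ref.values)
        assert back.version == "v9" and back.n_dm1 == 20


class TestNormalizePsi:
    def test_zero_at_control_median_one_at_dm95(self, toy_panel):
        for e in toy_panel:
            assert si.normalize_psi(e.psi_median_control, e) == pytest.approx(0.0)
            assert si.normalize_psi(e.psi_dm95, e) == pytest.approx(1.0)

    def test_direction_symmetry(self):
        assert si.normalize_psi(0.5, (0.2, 0.8)) == pytest.approx(0.5)
        assert si.normalize_psi(0.5, (0.8, 0.2)) == pytest.approx(0.5)

    def test_out_of_range_preserved(self):
        assert si.normalize_psi(0.1, (0.2, 0.8)) == pytest.approx(-1 / 6)

    def test_zero_span_raises(self):
        with pytest.raises(ValueError):
            si.normalize_psi(0.5, (0.4, 0.4))


class TestComputeSi:
    def test_control_profile_scores_zero(self, toy_panel):
        ref = si.NormativeReference.from_panel(toy_panel)
        psi = {e.event_id: e.psi_median_control for e in toy_panel}
        res = si.compute_si(psi, ref, min_events=5)
        assert res.si == 0.0 and res.si_raw == pytest.approx(0.0)

    def test_dm95_profile_scores_one(self, toy_panel):
        ref = si.NormativeReference.from_panel(toy_panel)
        psi = {e.event_id: e.psi_dm95 for e in toy_panel}
        res = si.compute_si(psi, ref, min_events=5)
        assert res.si == 1.0 and res.si_raw == pytest.approx(1.0)

    def test_slightly_negative_raw_clamped_to_zero(self, toy_panel):
        ref = si.NormativeReference.from_panel(toy_panel)
        psi = {}
        for e in toy_panel:
            span = e.psi_dm95 - e.psi_median_control
            psi[e.event_id] = e.psi_median_control - 0.03 * span  # normalized -0.03
        res = si.compute_si(psi, ref, min_events=5)
        assert res.si_raw == pytest.approx(-0.03)
        assert res.si == 0.0

    def test_min_events_gate(self, toy_panel):
        ref = si.NormativeReference.from_panel(toy_panel)
        psi = {e.event_id: e.psi_dm95 for e in toy_panel.events[:3]}
        res = si.compute_si(psi, ref, min_events=5)
        assert not res.qc_pass and np.isnan(res.si)

    def test_monotone_in_each_event(self, toy_panel):
        """Raising one event's severity-oriented value strictly raises si_raw."""
        ref = si.NormativeReference.from_panel(toy_panel)
        base = {e.event_id: (e.psi_median_control + e.psi_dm95) / 2 for e in toy_panel}
        res0 = si.compute_si(base, ref, min_events=5)
        for e in toy_panel:
            bumped = dict(base)
            bumped[e.event_id] = base[e.event_id] + 0.05 * (e.psi_dm95 - e.psi_median_control)
            res1 = si.compute_si(bumped, ref, min_events=5)
            assert res1.si_raw > res0.si_raw

    def test_qc_failing_events_excluded(self, toy_panel):
        ref = si.NormativeReference.from_panel(toy_panel)
        ests = [
            si.PsiEstimate(e.event_id, e.psi_dm95, 1000, None, None, qc_pass=(i != 0))
            for i, e in enumerate(toy_panel)
        ]
        res = si.compute_si(ests, ref, min_events=3)
        assert res.events_used == 4 and res.si == 1.0


class TestDeltaPsi:
    def _result(self, toy_panel, offset):
        ref = si.NormativeReference.from_panel(toy_panel)
        psi = {
            e.event_id: e.psi_median_control + offset * (e.psi_dm95 - e.psi_median_control)
            for e in toy_panel
        }
        return si.compute_si(psi, ref, min_events=5)

    def test_identity_gives_zero_deltas(self, toy_panel):
        a = self._result(toy_panel, 0.4)
        deltas = si.normalized_delta_psi(a, a)
        assert all(d == 0.0 for d in deltas.values())

    def test_shift_arithmetic(self, toy_panel):
        a = self._result(toy_panel, 0.2)
        b = self._result(toy_panel, 0.3)
        for d in si.normalized_delta_psi(a, b).values():
            assert d == pytest.approx(0.1)

    def test_version_mismatch_raises(self, toy_panel):
        a = self._result(toy_panel, 0.2)
        b = self._result(toy_panel, 0.3)
        b.reference_version = "other"
        with pytest.raises(ValueError, match="version"):
            si.normalized_delta_psi(a, b)


class TestSpliceIndexScorer:
    def test_fit_matches_derive_reference(self):
        ctrl, dm1 = make_matrices()
        X = pd.concat([ctrl, dm1], ignore_index=True)
        y = np.r_[np.zeros(len(ctrl)), np.ones(len(dm1))]
        scorer = si.SpliceIndexScorer(min_events=3).fit(X, y)
        ref = si.derive_reference(ctrl, dm1)
        pd.testing.assert_frame_equal(scorer.reference_.values, ref.values)

    def test_transform_and_score(self, toy_panel):
        ref = si.NormativeReference.from_panel(toy_panel)
        scorer = si.SpliceIndexScorer(min_events=5).set_reference(ref)
        X = pd.DataFrame(
            [{e.event_id: e.psi_dm95 for e in toy_panel},
             {e.event_id: e.psi_median_control for e in toy_panel}],
            index=["severe", "healthy"],
        )
        norm = scorer.transform(X)
        assert np.allclose(norm.loc["severe"], 1.0) and np.allclose(norm.loc["healthy"], 0.0)
        scores = scorer.score_samples(X)
        assert scores.loc["severe", "si"] == 1.0 and scores.loc["healthy", "si"] == 0.0

    def test_sklearn_param_interface(self):
        from sklearn.base import clone

        scorer = si.SpliceIndexScorer(min_events=10, oriented=False)
        assert clone(scorer).get_params()["min_events"] == 10


def test_si_round_trip_at_depth(panel22):
    """Simulate 40 DM1 + 10 controls at depth 10,000/event with no
    amplification bias: scored SI tracks generative SI within 0.02."""
    cfg = si.SimulationConfig(seed=101, n_dm1=40, n_controls=10, depth=10_000, bias=None)
    cohort = si.simulate_cohort(cfg, panel22)
    ref = si.NormativeReference.from_panel(panel22)
    errors = []
    for sid in cohort.samples.index:
        res = si.compute_si(cohort.psi_obs.loc[sid].to_dict(), ref, min_events=18, sample_id=sid)
        errors.append(abs(res.si - cohort.samples.loc[sid, "si_true"]))
    errors = np.array(errors)
    assert np.median(errors) <= 0.02
    assert np.mean(errors <= 0.02) >= 0.95
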