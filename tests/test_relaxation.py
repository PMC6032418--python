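"""Inversion-recovery T1 fitting and ferric/ferrous-CO pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemedist import (
    InputError,
    InversionRecoverySeries,
    T1Estimate,
    fit_inversion_recovery,
    gen_inversion_recovery,
    pair_states,
)


def make_series(t1=1.54, h_inf=100.0, b=1.0, delays=None, **kw):
    if delays is None:
        delays = np.linspace(0.0, 15.0, 10)
    heights = h_inf * (1.0 - 2.0 * b * np.exp(-delays / t1))
    return InversionRecoverySeries(
        proton_label=kw.pop("proton_label", "p"),
        delays=delays,
        heights=heights,
        enzyme_state=kw.pop("enzyme_state", "ferric"),
        **kw,
    )


class TestFitInversionRecovery:
    def test_noiseless_recovery_is_exact(self):
        est = fit_inversion_recovery(make_series(t1=1.54))
        assert est.t1 == pytest.approx(1.54, rel=1e-6)
        assert est.fit_diagnostics["n_points"] == 10
        assert est.fit_diagnostics["rss"] < 1e-12

    def test_noisy_fit_covers_generating_value(self):
        series, spec = gen_inversion_recovery(
            t1=1.54, noise_sd=1.0, seed=11,
            delays=np.linspace(0.0, 15.0, 10),
        )
        est = fit_inversion_recovery(series)
        assert abs(est.t1 - spec.ground_truth["t1"]) < 3.0 * est.se

    def test_three_delays_rejected(self):
        with pytest.raises(InputError, match="4 distinct delays"):
            make_series(delays=np.array([0.0, 1.0, 5.0]))

    def test_scale_invariance_of_t1(self):
        series = make_series(t1=2.3, b=0.9)
        scaled = InversionRecoverySeries(
            proton_label="p",
            delays=series.delays,
            heights=7.5 * series.heights,
            enzyme_state="ferric",
        )
        t1_a = fit_inversion_recovery(series).t1
        t1_b = fit_inversion_recovery(scaled).t1
        assert t1_b == pytest.approx(t1_a, rel=1e-8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        h_inf=st.floats(1.0, 1e4),
        b=st.floats(0.5, 1.0),
        t1=st.floats(0.1, 50.0),
    )
    def test_noiseless_round_trip_property(self, h_inf, b, t1):
        """Any noiseless series over [0, 5*T1] returns T1 to < 1e-4 rel."""
        delays = np.linspace(0.0, 5.0 * t1, 8)
        est = fit_inversion_recovery(
            make_series(t1=t1, h_inf=h_inf, b=b, delays=delays)
        )
        assert est.t1 == pytest.approx(t1, rel=1e-4)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InputError):
            InversionRecoverySeries(
                proton_label="p",
                delays=np.array([0.0, 1.0, 2.0, 4.0]),
                heights=np.array([1.0, 2.0, 3.0]),
                enzyme_state="ferric",
            )

    def test_negative_delay_rejected(self):
        with pytest.raises(InputError, match="negative delay"):
            InversionRecoverySeries(
                proton_label="p",
                delays=np.array([-0.1, 1.0, 2.0, 4.0]),
                heights=np.zeros(4),
                enzyme_state="ferric",
            )


def _estimate(label, t1=1.0, state="ferric"):
    return T1Estimate(proton_label=label, t1=t1, se=0.1, enzyme_state=state)


class TestPairStates:
    def test_shared_labels_become_pairs(self):
        res = pair_states(
            [_estimate("2,6"), _estimate("3,5")],
            [_estimate("2,6", 2.0, "ferrous_CO"),
             _estimate("3,5", 2.0, "ferrous_CO")],
        )
        assert len(res.pairs) == 2
        assert res.unpaired_ferric == ()
        assert res.unpaired_ferrous_co == ()

    def test_partial_overlap_reports_unpaired(self):
        res = pair_states(
            [_estimate("a"), _estimate("b")],
            [_estimate("b", 2.0, "ferrous_CO"),
             _estimate("c", 2.0, "ferrous_CO")],
        )
        assert [p.proton_label for p in res.pairs] == ["b"]
        assert res.unpaired_ferric == ("a",)
        assert res.unpaired_ferrous_co == ("c",)

    def test_empty_intersection_is_error(self):
        with pytest.raises(InputError, match="no proton label"):
            pair_states([_estimate("-OCH2-")], [])
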