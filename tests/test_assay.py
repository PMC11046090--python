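"""Instrument-parameter equations, transition building, scheduling."""

import numpy as np
import pytest

import mrmquant as mq
from mrmquant.assay import (
    AssaySettings,
    frame_to_transitions,
    schedule,
    transitions_to_frame,
)
from mrmquant.chem import Label


class TestVoltageRamps:
    @pytest.mark.parametrize("q1, expected", [(500, 67.1), (1000, 91.6)])
    def test_declustering_potential(self, q1, expected):
        assert mq.declustering_potential(q1) == pytest.approx(expected, abs=1e-6)

    def test_dp_intercept(self):
        assert mq.declustering_potential(1e-12) == pytest.approx(42.6, abs=1e-9)

    @pytest.mark.parametrize("q1, charge, expected", [(600, 2, 28.5), (500, 3, 24.6)])
    def test_collision_energy(self, q1, charge, expected):
        assert mq.collision_energy(q1, charge) == pytest.approx(expected, abs=1e-6)

    def test_ce_crossover_point(self):
        # the 2+ and 3+ ramps intersect at q1 = 9.3/0.018
        q1 = 9.3 / 0.018
        assert mq.collision_energy(q1, 2) == pytest.approx(mq.collision_energy(q1, 3))
        assert mq.collision_energy(q1, 2) == pytest.approx(25.5, abs=1e-9)

    @pytest.mark.parametrize("charge", [1, 4])
    def test_ce_undefined_charges_rejected(self, charge):
        with pytest.raises(ValueError, match="charges 2 and 3"):
            mq.collision_energy(500, charge)

    # 57.04 sits just above the ramp's zero crossing at q3 = 2.23/0.0391
    @pytest.mark.parametrize("q3, expected", [(400, 13.41), (57.04, 0.000264)])
    def test_cxp(self, q3, expected):
        assert mq.collision_cell_exit_potential(q3) == pytest.approx(expected, abs=1e-6)

    def test_cxp_composed_with_fragment_mass(self):
        q3 = mq.fragment_mz(mq.Peptide("PEPTIDEK"), "y", 1)
        assert mq.collision_cell_exit_potential(q3) == pytest.approx(3.522, abs=1e-3)

    def test_cxp_warns_but_returns_below_ramp_zero(self):
        with pytest.warns(UserWarning, match="non-positive"):
            val = mq.collision_cell_exit_potential(50.0)
        assert val < 0

    @pytest.mark.parametrize("fn", [mq.declustering_potential, mq.collision_cell_exit_potential])
    def test_nonpositive_mz_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.0)


class TestBuildTransitions:
    def test_counts_and_fragment_choice(self):
        trans = mq.build_transitions(mq.Peptide("LVNELTEFAK"), predicted_rt=10.0)
        light = [t for t in trans if t.label is Label.LIGHT]
        # 7 candidate y-ions (y3..y9); the 3 highest-index kept, per label
        assert len(light) == 3 and len(trans) == 6
        assert [t.fragment_ion for t in light] == [("y", 9, 1), ("y", 8, 1), ("y", 7, 1)]

    def test_heavy_partner_mass_shifts(self):
        trans = mq.build_transitions(mq.Peptide("LVNELTEFAK"), predicted_rt=10.0)
        shift = mq.default_mass_table().label_shifts["K"]
        by_id = {}
        for t in trans:
            by_id.setdefault(t.transition_id, {})[t.label] = t
        for pair in by_id.values():
            l, h = pair[Label.LIGHT], pair[Label.HEAVY]
            assert h.q1 - l.q1 == pytest.approx(shift / 2, abs=1e-9)
            assert h.q3 - l.q3 == pytest.approx(shift / 1, abs=1e-9)
            assert l.predicted_rt == h.predicted_rt  # co-elution assumption

    def test_parameters_recompute_bit_for_bit(self, small_assay):
        for t in small_assay:
            assert t.dp == mq.declustering_potential(t.q1)
            assert t.ce == mq.collision_energy(t.q1, t.precursor_charge)
            assert t.cxp == mq.collision_cell_exit_potential(t.q3)
            assert t.ep == 10.0

    def test_heavy_precursor_charge_three_for_large_peptides(self):
        big = mq.Peptide("W" * 13 + "K")  # 2+ m/z > 1250
        trans = mq.build_transitions(big, predicted_rt=10.0)
        assert all(t.precursor_charge == 3 for t in trans)

    def test_too_short_peptide_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            mq.build_transitions(mq.Peptide("AAAK"))


class TestSchedule:
    def test_window_is_symmetric_half_width(self):
        trans = mq.build_transitions(mq.Peptide("LVNELTEFAK"), predicted_rt=10.0)
        scheduled, _ = schedule(trans)
        assert all(t.window == (9.0, 11.0) for t in scheduled)

    def test_concurrency_of_overlapping_windows(self):
        a = mq.build_transitions(mq.Peptide("LVNELTEFAK"), predicted_rt=10.0)
        b = mq.build_transitions(mq.Peptide("SAMPLEPTIDEK"), predicted_rt=10.5)
        _, report = schedule(a[:1] + b[:1])
        assert report.max_concurrent == 2  # overlap on [9.5, 11.0]

    def test_dwell_arithmetic(self):
        # 100 concurrent transitions, 1-s cycle, 2-ms overhead -> 8 ms each
        trans = []
        for i in range(100):
            t = mq.build_transitions(mq.Peptide("LVNELTEFAK"), predicted_rt=10.0)[0]
            trans.append(t)
        _, report = schedule(trans)
        assert report.max_concurrent == 100
        assert report.min_dwell_ms == pytest.approx((1000 - 100 * 2) / 100)
        assert not report.crowded_windows

    def test_missing_rt_rejected(self):
        trans = mq.build_transitions(mq.Peptide("LVNELTEFAK"))
        with pytest.raises(ValueError, match="predicted_rt"):
            schedule(trans)


class TestAcylcarnitineCE:
    @pytest.mark.parametrize(
        "species, ce",
        [("C0", -20), ("C4", -20), ("C8", -20),
         ("C10:1", -25), ("C12:1", -25), ("C14-OH", -25), ("C14:OH", -25),
         ("C16", -35), ("C18-OH", -35)],
    )
    def test_class_mapping(self, species, ce):
        assert mq.acylcarnitine_ce(species) == (85.05, ce)

    @pytest.mark.parametrize("bad", ["C20", "C9", "C15", "X4", "carnitine"])
    def test_rejections(self, bad):
        with pytest.raises(ValueError):
            mq.acylcarnitine_ce(bad)


def test_transition_csv_round_trip(small_assay):
    scheduled, _ = schedule(small_assay)
    df = transitions_to_frame(scheduled)
    assert list(df.columns) == [
        "protein_id", "peptide", "label", "precursor_charge", "q1", "fragment",
        "q3", "dp", "ce", "cxp", "ep", "rt", "window_start", "window_end",
    ]
    back = frame_to_transitions(df)
    for a, b in zip(scheduled, back):
        assert a.transition_id == b.transition_id and a.label == b.label
        assert a.q1 == b.q1 and a.q3 == b.q3 and a.window == b.window
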