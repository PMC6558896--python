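"""Event segmentation, exposure/dose summaries, cross-species dose."""

import math

import numpy as np
import pytest

from aerodose.deposition import regional_deposition
from aerodose.dosimetry import (HUMAN_LIGHT_EXERCISE, MOUSE, EventWindow,
                                LabeledSeries, inhaled_dose_rates,
                                mouse_alveolar_dose, segment,
                                summarize_exposure, workday_equivalents)
from aerodose.size_distribution import NumberSizeDistribution, SizeGrid
from aerodose.synthetic import LognormalMode


def _series(grid, conc_rows, t0=0.0, step=10.0):
    return [NumberSizeDistribution(grid, c, timestamp=t0 + i * step)
            for i, c in enumerate(conc_rows)]


@pytest.fixture
def toy_grid():
    # geometric midpoints exactly 1e-8, 6.324555e-8 (=sqrt 4e-15), 6.324555e-7
    return SizeGrid([5e-9, 2e-8, 2e-7, 2e-6])


class TestSegment:
    def test_whole_span_window_is_identity(self, airfield_series):
        w = EventWindow("all", 0.0, 3600.0)
        [sub] = segment(airfield_series, [w])
        assert len(sub.snapshots) == len(airfield_series)

    def test_window_outside_span_errors_with_label(self, airfield_series):
        with pytest.raises(ValueError, match="nowhere"):
            segment(airfield_series, [EventWindow("nowhere", 9000.0, 9100.0)])

    def test_half_open_assignment(self, toy_grid):
        series = _series(toy_grid, [np.ones(3)] * 5, step=10.0)  # t=0..40
        [sub] = segment(series, [EventWindow("w", 10.0, 30.0)])
        assert [s.timestamp for s in sub.snapshots] == [10.0, 20.0]

    def test_event_window_mean_exceeds_background(self, airfield_series):
        subs = segment(airfield_series, [EventWindow("PL", 120.0, 420.0),
                                         EventWindow("background", 1560.0, 1800.0)])
        mean = {s.label: np.mean([x.total() for x in s.snapshots]) for s in subs}
        assert mean["PL"] > 10 * mean["background"]


class TestSummarizeExposure:
    def test_monodisperse_regional_shares_equal_df_ratios(self, monodisperse_dist):
        sub = LabeledSeries(EventWindow("mono", 0.0, 600.0),
                            [monodisperse_dist])
        r = summarize_exposure(sub)
        df = regional_deposition(0.1)
        total = df.head_airways + df.tracheobronchial + df.alveolar
        assert r.ha_n_pct == pytest.approx(100 * df.head_airways / total, rel=1e-12)
        assert r.tb_n_pct == pytest.approx(100 * df.tracheobronchial / total, rel=1e-12)
        assert r.al_n_pct == pytest.approx(100 * df.alveolar / total, rel=1e-12)
        assert r.ha_n_pct + r.tb_n_pct + r.al_n_pct == pytest.approx(100.0, abs=1e-9)
        # monodisperse: number and mass shares coincide
        assert r.ha_m_pct == pytest.approx(r.ha_n_pct, rel=1e-12)

    def test_zero_concentration_series_gives_zero_doses(self, toy_grid):
        sub = LabeledSeries(EventWindow("z", 0.0, 60.0),
                            _series(toy_grid, [np.zeros(3)] * 3))
        r = summarize_exposure(sub)
        assert r.n_cm3 == r.m_ug_m3 == r.dr_n_per_min == r.dr_m_ug_min == 0.0
        assert r.particles_per_event == r.mass_per_event_ug == 0.0

    def test_three_bin_hand_expanded_oracle(self, toy_grid):
        """Every summary field recomputed with hand-expanded scalar
        arithmetic (math module), independent of the pipeline internals."""
        conc = [1.0e5, 2.0e4, 3.0e2]
        sub = LabeledSeries(EventWindow("toy", 0.0, 900.0),
                            _series(toy_grid, [np.array(conc)] * 3))
        r = summarize_exposure(sub)

        mids = [1e-8, math.sqrt(2e-8 * 2e-7), math.sqrt(2e-7 * 2e-6)]
        vent = 25.0 * 1000.0  # cm3/min
        n_tot = sum(conc)
        masses, dep_n, dep_m = [], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]
        for c, d in zip(conc, mids):
            rho = 11.92 * d ** (2.76 - 3.0)
            mass = c * (math.pi / 6.0) * d ** 3 * rho * 1e15
            masses.append(mass)
            d_um = d * 1e6
            ln = math.log(d_um)
            inhal = 1 - 0.5 * (1 - 1 / (7.6e-4 * d_um ** 2.8 + 1))
            ha = inhal * (1 / (1 + math.exp(6.84 + 1.183 * ln))
                          + 1 / (1 + math.exp(0.924 - 1.885 * ln)))
            tb = (0.00352 / d_um) * (math.exp(-0.234 * (ln + 3.40) ** 2)
                                     + 63.9 * math.exp(-0.819 * (ln - 1.61) ** 2))
            al = (0.0155 / d_um) * (math.exp(-0.416 * (ln + 2.84) ** 2)
                                    + 19.11 * math.exp(-0.482 * (ln - 1.362) ** 2))
            for k, f in enumerate((ha, tb, al)):
                dep_n[k] += c * vent * f
                dep_m[k] += mass * 1e-6 * vent * f
        dr_n, dr_m = sum(dep_n), sum(dep_m)
        t_min = 15.0

        assert r.n_cm3 == pytest.approx(n_tot, rel=1e-9)
        assert r.m_ug_m3 == pytest.approx(sum(masses), rel=1e-9)
        assert r.dr_n_per_min == pytest.approx(dr_n, rel=1e-9)
        assert r.dr_m_ug_min == pytest.approx(dr_m, rel=1e-9)
        assert r.ha_n_pct == pytest.approx(100 * dep_n[0] / dr_n, rel=1e-9)
        assert r.tb_n_pct == pytest.approx(100 * dep_n[1] / dr_n, rel=1e-9)
        assert r.al_n_pct == pytest.approx(100 * dep_n[2] / dr_n, rel=1e-9)
        assert r.ha_m_pct == pytest.approx(100 * dep_m[0] / dr_m, rel=1e-9)
        assert r.particles_per_event == pytest.approx(dr_n * t_min, rel=1e-9)
        assert r.mass_per_event_ug == pytest.approx(dr_m * t_min, rel=1e-9)

    def test_dose_rate_linearity_and_invariant_shares(self, toy_grid):
        c = np.array([1e5, 2e4, 3e2])
        mk = lambda scale: LabeledSeries(EventWindow("w", 0.0, 300.0),
                                         _series(toy_grid, [scale * c] * 2))
        r1, r5 = summarize_exposure(mk(1.0)), summarize_exposure(mk(5.0))
        assert r5.dr_n_per_min == pytest.approx(5 * r1.dr_n_per_min, rel=1e-12)
        assert r5.dr_m_ug_min == pytest.approx(5 * r1.dr_m_ug_min, rel=1e-12)
        assert r5.particles_per_event == pytest.approx(
            5 * r1.particles_per_event, rel=1e-12)
        assert r5.ha_n_pct == pytest.approx(r1.ha_n_pct, rel=1e-12)
        assert r5.al_m_pct == pytest.approx(r1.al_m_pct, rel=1e-12)

    def test_single_snapshot_equals_per_snapshot_computation(self, toy_grid):
        c = np.array([1e4, 1e3, 1e1])
        one = LabeledSeries(EventWindow("w", 0.0, 60.0), _series(toy_grid, [c]))
        many = LabeledSeries(EventWindow("w", 0.0, 60.0),
                             _series(toy_grid, [c, c, c], step=20.0))
        ra, rb = summarize_exposure(one), summarize_exposure(many)
        assert ra.dr_n_per_min == pytest.approx(rb.dr_n_per_min, rel=1e-12)
        assert ra.m_pm4_ug_m3 == pytest.approx(rb.m_pm4_ug_m3, rel=1e-12)

    def test_ultrafine_number_deposits_alveolar_coarse_mass_head_airways(self):
        grid = SizeGrid.default()
        soot = LognormalMode(1e6, 20e-9, 1.7)   # ultrafine soot mode
        coarse = LognormalMode(10.0, 3e-6, 1.5)  # coarse mass-carrying mode
        conc = soot.bin_concentrations(grid) + coarse.bin_concentrations(grid)
        sub = LabeledSeries(EventWindow("mix", 0.0, 60.0),
                            [NumberSizeDistribution(grid, conc, timestamp=0.0)])
        r = summarize_exposure(sub)
        assert r.al_n_pct > r.ha_n_pct   # number: alveolar dominates
        assert r.ha_m_pct > r.al_m_pct   # mass: head airways dominate

    def test_empty_subseries_rejected(self):
        sub = LabeledSeries(EventWindow("e", 0.0, 60.0), [])
        with pytest.raises(ValueError):
            summarize_exposure(sub)

    def test_inhaled_rates_exceed_deposited(self, toy_grid):
        c = np.array([1e5, 2e4, 3e2])
        sub = LabeledSeries(EventWindow("w", 0.0, 300.0),
                            _series(toy_grid, [c] * 2))
        r = summarize_exposure(sub)
        inh_n, inh_m = inhaled_dose_rates(sub)
        assert inh_n > r.dr_n_per_min
        assert inh_m > r.dr_m_ug_min


class TestMouseDose:
    def test_workday_worked_example(self):
        # 1000 ug/m3 x 8 h x 1.8 L/h x 0.096
        dose = mouse_alveolar_dose(1000.0, 8.0, MOUSE, 0.096)
        assert round(dose, 2) == 1.38

    def test_zero_concentration(self):
        assert mouse_alveolar_dose(0.0, 8.0) == 0.0

    def test_unit_identity_one_m3_at_unit_fraction(self):
        # breathing exactly 1 m3 of 1 ug/m3 with full deposition -> 1 ug
        from aerodose.dosimetry import BreathingPattern
        bp = BreathingPattern("custom", 1000.0 / 60.0)  # 1000 L/h
        assert mouse_alveolar_dose(1.0, 1.0, bp, 1.0) == pytest.approx(1.0)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mouse_alveolar_dose(1000.0, 8.0, MOUSE, 1.5)


class TestWorkdayEquivalents:
    @pytest.mark.parametrize("dose,expected", [(6.0, 4), (54.0, 39)])
    def test_instilled_bolus_equivalents(self, dose, expected):
        per_day = mouse_alveolar_dose(1000.0, 8.0, MOUSE, 0.096)
        assert workday_equivalents(dose, per_day).workdays == expected

    def test_equal_doses_give_one_workday(self):
        eq = workday_equivalents(1.38, 1.38)
        assert eq.workdays == 1 and eq.ratio == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            workday_equivalents(0.0, 1.38)
        with pytest.raises(ValueError):
            workday_equivalents(6.0, 0.0)
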