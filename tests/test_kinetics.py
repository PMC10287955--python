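import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aretools import (
    DecayTimeCourse,
    QpcrMeasurement,
    bootstrap_half_life,
    fit_one_phase_decay,
    fold_enrichment,
    normalize_timecourse,
)
from aretools.errors import NonDecayWarning, PairingError, ValidationError
from aretools.kinetics import read_ct_table, write_ct_table

GRID = (0.0, 0.5, 1.0, 3.0, 6.0, 24.0)

finite_ct = st.floats(min_value=5.0, max_value=40.0)


def course_from(half_life, times=GRID, reps=1):
    ab = tuple(
        tuple(2.0 ** (-t / half_life) for _ in range(reps)) for t in times
    )
    return DecayTimeCourse(times_h=times, abundance=ab)


class TestFoldEnrichment:
    def test_equal_ct(self):
        assert fold_enrichment(20.0, 20.0) == 1.0

    def test_one_cycle_doubling(self):
        assert fold_enrichment(21.0, 20.0) == 2.0

    def test_overwrite_magnitude(self):
        # 14.61-cycle separation -> ~2.5e4-fold
        fe = fold_enrichment(28.61, 14.00)
        assert fe == pytest.approx(2.0**14.61)
        assert fe == pytest.approx(2.5e4, rel=0.01)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            fold_enrichment(float("nan"), 20.0)
        with pytest.raises(ValidationError):
            fold_enrichment(20.0, float("inf"))

    @given(finite_ct, finite_ct, finite_ct)
    def test_multiplicativity(self, a, b, c):
        lhs = fold_enrichment(a, b) * fold_enrichment(b, c)
        assert lhs == pytest.approx(fold_enrichment(a, c), rel=1e-9)


def _table(ct_by_time, reps=2, ref_ct=20.0):
    rows = []
    for t, ct in ct_by_time.items():
        for r in range(1, reps + 1):
            rows.append(QpcrMeasurement(f"t{t}r{r}", "GENE", t, r, ct))
            rows.append(QpcrMeasurement(f"t{t}r{r}", "ACTB", t, r, ref_ct))
    return rows


class TestNormalizeTimecourse:
    def test_one_cycle_per_hour_halves(self):
        rows = _table({0.0: 20.0, 1.0: 21.0, 2.0: 22.0, 3.0: 23.0})
        tc = normalize_timecourse(rows, "GENE", "ACTB")
        means = [np.mean(a) for a in tc.abundance]
        assert means == pytest.approx([1.0, 0.5, 0.25, 0.125])

    def test_constant_delta_ct_flat(self):
        rows = _table({t: 25.0 for t in (0.0, 1.0, 5.0)})
        tc = normalize_timecourse(rows, "GENE", "ACTB")
        assert all(v == pytest.approx(1.0) for a in tc.abundance for v in a)

    def test_missing_reference_pairing_error(self):
        rows = _table({0.0: 20.0, 1.0: 21.0, 2.0: 22.0})
        rows = [m for m in rows if not (m.target == "ACTB" and m.time_h == 1.0)]
        with pytest.raises(PairingError):
            normalize_timecourse(rows, "GENE", "ACTB")

    def test_spreadsheet_recomputation(self, rng):
        # independent recount on a random 6x3 Ct table
        times = GRID
        tgt = {(t, r): float(rng.uniform(15, 30)) for t in times for r in (1, 2, 3)}
        ref = {(t, r): float(rng.uniform(18, 22)) for t in times for r in (1, 2, 3)}
        rows = []
        for (t, r), ct in tgt.items():
            rows.append(QpcrMeasurement(f"{t}{r}", "GENE", t, r, ct))
            rows.append(QpcrMeasurement(f"{t}{r}", "ACTB", t, r, ref[(t, r)]))
        tc = normalize_timecourse(rows, "GENE", "ACTB")
        raw = {
            t: [2.0 ** (ref[(t, r)] - tgt[(t, r)]) for r in (1, 2, 3)]
            for t in times
        }
        scale = sum(raw[0.0]) / 3
        for i, t in enumerate(times):
            assert list(tc.abundance[i]) == pytest.approx(
                [v / scale for v in raw[t]]
            )

    def test_fewer_than_three_times_rejected(self):
        rows = _table({0.0: 20.0, 1.0: 21.0})
        with pytest.raises(ValidationError):
            normalize_timecourse(rows, "GENE", "ACTB")

    def test_ct_table_round_trip(self, tmp_path):
        rows = _table({0.0: 20.0, 1.0: 21.0, 2.0: 22.0})
        p = tmp_path / "ct.tsv"
        write_ct_table(rows, p)
        back = read_ct_table(p)
        assert back == rows


class TestFitOnePhaseDecay:
    @pytest.mark.parametrize("half_life", [1.5, 6.0])
    def test_noiseless_exact_recovery(self, half_life):
        fit = fit_one_phase_decay(course_from(half_life))
        assert fit.converged
        assert fit.half_life_h == pytest.approx(half_life, abs=1e-6)
        assert fit.k == pytest.approx(math.log(2) / half_life, rel=1e-6)
        assert fit.half_life_h * fit.k == pytest.approx(math.log(2), rel=1e-12)

    def test_constant_data_non_decay(self):
        tc = DecayTimeCourse(GRID, tuple((1.0,) for _ in GRID))
        with pytest.warns(NonDecayWarning):
            fit = fit_one_phase_decay(tc)
        assert not fit.converged
        assert math.isnan(fit.half_life_h)

    def test_free_plateau_recovers_offset(self):
        hl, plateau = 2.0, 0.25
        k = math.log(2) / hl
        raw = [(1.0 - plateau) * math.exp(-k * t) + plateau for t in GRID]
        scale = raw[0]
        ab = tuple((v / scale,) for v in raw)
        fit = fit_one_phase_decay(
            DecayTimeCourse(GRID, ab), fix_plateau_zero=False
        )
        assert fit.converged
        assert fit.plateau == pytest.approx(plateau / scale, rel=1e-4)
        assert fit.half_life_h == pytest.approx(hl, rel=1e-4)

    def test_half_life_decreasing_in_k(self):
        fits = [fit_one_phase_decay(course_from(hl)) for hl in (0.5, 2.0, 8.0)]
        ks = [f.k for f in fits]
        hls = [f.half_life_h for f in fits]
        assert ks == sorted(ks, reverse=True)
        assert hls == sorted(hls)

    def test_scale_equivariance(self, rng):
        # shifting every target Ct by a constant scales raw abundance but
        # leaves the normalized course, k, and half-life unchanged
        from aretools import simulate_pulse_chase

        rows = simulate_pulse_chase(2.5, noise_cv=0.1, seed=11)
        shifted = [
            QpcrMeasurement(m.sample_id, m.target, m.time_h, m.replicate,
                            m.ct - 3.0 if m.target == "construct" else m.ct)
            for m in rows
        ]
        fit_a = fit_one_phase_decay(
            normalize_timecourse(rows, "construct", "ACTB")
        )
        fit_b = fit_one_phase_decay(
            normalize_timecourse(shifted, "construct", "ACTB")
        )
        assert fit_b.k == pytest.approx(fit_a.k, rel=1e-9)
        assert fit_b.half_life_h == pytest.approx(fit_a.half_life_h, rel=1e-9)

    def test_weighted_fit_runs(self):
        fit = fit_one_phase_decay(course_from(3.0), weighting="1/y2")
        assert fit.converged
        assert fit.half_life_h == pytest.approx(3.0, abs=1e-5)

    def test_unknown_weighting_rejected(self):
        with pytest.raises(ValidationError):
            fit_one_phase_decay(course_from(3.0), weighting="huber")

    def test_noisy_recovery_within_ten_percent_median(self):
        from aretools import simulate_pulse_chase

        for true_hl in (0.5, 1.5, 6.0, 10.0):
            errs = []
            for seed in range(200):
                rows = simulate_pulse_chase(
                    true_hl, noise_cv=0.10, replicates=3, seed=seed
                )
                tc = normalize_timecourse(rows, "construct", "ACTB")
                fit = fit_one_phase_decay(tc)
                errs.append(abs(fit.half_life_h - true_hl) / true_hl)
            assert np.median(errs) < 0.10


class TestBootstrap:
    def _noisy_tc(self, seed=5):
        from aretools import simulate_pulse_chase

        rows = simulate_pulse_chase(1.5, noise_cv=0.1, replicates=3, seed=seed)
        return normalize_timecourse(rows, "construct", "ACTB")

    def test_deterministic_given_seed(self):
        tc = self._noisy_tc()
        a = bootstrap_half_life(tc, n_boot=50, seed=42)
        b = bootstrap_half_life(tc, n_boot=50, seed=42)
        assert a == b

    def test_zero_noise_degenerate_interval(self):
        tc = course_from(2.0, reps=3)
        lo, hi = bootstrap_half_life(tc, n_boot=25, seed=1)
        point = fit_one_phase_decay(tc).half_life_h
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(point, rel=1e-6)

    def test_interval_contains_point_estimate(self):
        for seed in (0, 1, 2):
            tc = self._noisy_tc(seed)
            point = fit_one_phase_decay(tc).half_life_h
            lo, hi = bootstrap_half_life(tc, n_boot=200, seed=seed)
            assert lo <= point <= hi

    def test_single_replicate_rejected(self):
        tc = course_from(2.0, reps=1)
        with pytest.raises(ValidationError, match="replicates"):
            bootstrap_half_life(tc, n_boot=10, seed=0)


class TestTimeCourseInvariants:
    def test_unsorted_times_rejected(self):
        with pytest.raises(ValidationError):
            DecayTimeCourse((1.0, 0.0, 2.0), ((1.0,), (1.0,), (1.0,)))

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(ValidationError):
            DecayTimeCourse((0.0, 1.0, 2.0), ((1.0,), (0.0,), (1.0,)))

    def test_mean_at_t0_must_be_one(self):
        with pytest.raises(ValidationError):
            DecayTimeCourse((0.0, 1.0, 2.0), ((2.0,), (1.0,), (1.0,)))
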