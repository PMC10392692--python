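"""Trace normalization, median traces and seeded k2k+ recovery."""

import math

import numpy as np
import pytest

from asynsalt.fitting import (
    NormalizedTrace,
    ThTTrace,
    fit_seeded_series,
    median_trace,
    normalize,
    t_half_vs_salt,
)
from asynsalt.kinetics import KineticParams, closed_form_mass
from asynsalt.synthetic import make_salt_series, simulate_plate

T = np.arange(0.0, 64.25, 0.25)


def make_trace(F, salt=0.0, seed=0.05, monomer=5.0, rep="r1", t=T):
    return ThTTrace(t=t, F=np.asarray(F, float), monomer_uM=monomer,
                    seed_uM=seed, salt_mM=salt, replicate_id=rep)


def seeded_curve(k2kplus, seed_uM=0.05, t=T):
    M0 = seed_uM * 1e-6
    p = KineticParams(k_n=0.0, k_2=k2kplus, k_plus=1.0, m0=5e-6,
                      M0=M0, P0=M0 / 500.0)
    return closed_form_mass(p, t).M_frac


class TestTraceValidation:
    def test_non_monotone_time_rejected(self):
        t = T.copy()
        t[5] = t[4]
        with pytest.raises(ValueError, match="strictly increasing"):
            make_trace(np.ones_like(t), t=t)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="10 time points"):
            make_trace(np.ones(5), t=np.arange(5.0))


class TestNormalize:
    def test_already_normalized_unchanged(self):
        y = 1.0 / (1.0 + np.exp(-(T - 10.0) / 1.5))  # baseline ~0, amp ~1
        nt = normalize(make_trace(y))
        assert nt.aggregating
        assert np.allclose(nt.y, y, atol=1e-3)

    def test_recovers_baseline_and_amplitude(self):
        y = 100.0 + 900.0 * (1.0 / (1.0 + np.exp(-(T - 10.0) / 1.5)))
        nt = normalize(make_trace(y))
        assert nt.baseline == pytest.approx(100.0, abs=2.0)
        assert nt.amplitude == pytest.approx(900.0, rel=0.02)

    def test_seeded_trace_baseline_includes_seed_signal(self):
        # seeds contribute fluorescence from t=0: the observable baseline is
        # b + a*M_frac(0), not the generator's b
        m = seeded_curve(1e16)
        y = 100.0 + 900.0 * m
        nt = normalize(make_trace(y))
        assert nt.baseline == pytest.approx(100.0 + 900.0 * m[0], abs=5.0)
        assert nt.amplitude == pytest.approx(900.0 * (1 - m[0]), rel=0.03)

    def test_constant_trace_flagged_non_aggregating(self):
        nt = normalize(make_trace(np.full(len(T), 50.0)))
        assert not nt.aggregating
        assert math.isnan(nt.amplitude)


class TestMedianTrace:
    def test_identical_replicates(self):
        y = seeded_curve(1e16)
        reps = [normalize(make_trace(y, rep=f"r{i}")) for i in range(3)]
        med = median_trace(reps)
        assert np.array_equal(med.y, reps[0].y)

    def test_constant_replicates(self):
        reps = [
            NormalizedTrace(T, np.full(len(T), v), 0.0, 1.0, True)
            for v in (0.0, 1.0, 2.0)
        ]
        assert np.allclose(median_trace(reps).y, 1.0)

    def test_outlier_rejected_pointwise(self, rng):
        y = seeded_curve(1e16)
        reps = [NormalizedTrace(T, y.copy(), 0.0, 1.0, True) for _ in range(4)]
        reps.append(NormalizedTrace(T, y + 0.5, 0.0, 1.0, True))
        med = median_trace(reps)
        # brute-force pointwise median over the stacked replicate values
        stack = np.vstack([r.y for r in reps])
        assert np.array_equal(med.y, np.median(stack, axis=0))

    def test_needs_at_least_one(self):
        with pytest.raises(ValueError):
            median_trace([])


class TestFitSeededSeries:
    def test_noiseless_recovery_within_1_percent(self):
        true = {0.0: 1e17, 40.0: 1e16, 120.0: 1.5e15}
        traces = []
        for salt, k in true.items():
            y = 100 + 900 * seeded_curve(k)
            for rep in range(3):
                traces.append(make_trace(y, salt=salt, rep=f"r{rep}"))
        res = fit_seeded_series(traces)
        for f in res.fits:
            assert f.converged
            assert f.k2kplus == pytest.approx(true[f.salt_mM], rel=0.01)
            assert f.ci_low <= f.k2kplus <= f.ci_high

    def test_decreasing_products_recovered_in_order(self, rng):
        salts = [0.0, 20.0, 40.0, 80.0, 120.0]
        traces = []
        for salt in salts:
            k = 1e17 * 10 ** (-0.015 * salt)
            y0 = seeded_curve(k)
            for rep in range(3):
                noise = 1 + 0.01 * rng.standard_normal(len(T))
                traces.append(make_trace(100 + 900 * y0 * noise, salt=salt,
                                         rep=f"r{rep}"))
        res = fit_seeded_series(traces)
        ks = [f.k2kplus for f in res.fits]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_flat_high_salt_condition_excluded(self, rng):
        traces = []
        y = seeded_curve(1e17)
        for rep in range(3):
            traces.append(make_trace(100 + 900 * y, salt=0.0, rep=f"r{rep}"))
            flat = 100 + 2.0 * rng.standard_normal(len(T))
            traces.append(make_trace(flat, salt=500.0, rep=f"r{rep}"))
        res = fit_seeded_series(traces)
        by_salt = {f.salt_mM: f for f in res.fits}
        assert by_salt[0.0].aggregating and by_salt[0.0].converged
        assert not by_salt[500.0].aggregating
        assert math.isnan(by_salt[500.0].k2kplus)

    def test_mixed_seed_levels_rejected(self):
        y = 100 + 900 * seeded_curve(1e16)
        traces = [make_trace(y, seed=0.05), make_trace(y, seed=0.005)]
        with pytest.raises(ValueError, match="one .* series"):
            fit_seeded_series(traces)

    def test_identifiability_only_product_and_kplus_p0_matter(self):
        """Different k+/k2 splits with fixed product and k+*P0 coincide."""
        M0 = 0.05e-6
        P0 = M0 / 500.0
        product = 1e16
        base = None
        for k_plus in (1.0, 10.0, 1000.0):
            p = KineticParams(k_n=0.0, k_2=product / k_plus, k_plus=k_plus,
                              m0=5e-6, M0=M0, P0=P0 / k_plus)
            y = closed_form_mass(p, T).M_frac
            if base is None:
                base = y
            else:
                assert np.max(np.abs(y - base)) < 1e-9

    def test_residuals_white_on_generator_matched_data(self, rng):
        y0 = seeded_curve(1e16)
        traces = [
            make_trace(100 + 900 * y0 * (1 + 0.01 * rng.standard_normal(len(T))),
                       rep=f"r{i}")
            for i in range(3)
        ]
        res = fit_seeded_series(traces)
        fit = res.fits[0]
        model = seeded_curve(fit.k2kplus)
        lag1 = []
        for tr in traces:
            nt = normalize(tr)
            r = nt.y - model
            r = r - r.mean()
            lag1.append(np.corrcoef(r[:-1], r[1:])[0, 1])
        assert abs(np.mean(lag1)) < 0.2


class TestTHalfVsSalt:
    def test_increases_with_salt_and_censors_flat(self, rng):
        traces = []
        for salt in (0.0, 40.0, 120.0):
            y = seeded_curve(1e17 * 10 ** (-0.015 * salt))
            for rep in range(3):
                traces.append(make_trace(100 + 900 * y, salt=salt,
                                         rep=f"r{rep}"))
        for rep in range(3):
            flat = 100 + 2.0 * rng.standard_normal(len(T))
            traces.append(make_trace(flat, salt=500.0, rep=f"r{rep}"))
        table = t_half_vs_salt(traces)
        live = table[~table.censored].sort_values("salt_mM")
        assert live.t_half_h.is_monotonic_increasing
        censored = table[table.censored]
        assert list(censored.salt_mM) == [500.0]
        assert censored.horizon_h.iloc[0] == pytest.approx(64.0)

    def test_single_replicate_median_is_itself(self):
        y = seeded_curve(1e16)
        table = t_half_vs_salt([make_trace(100 + 900 * y)])
        from asynsalt.kinetics import half_time

        expected = half_time(T, y, 0.0, 1.0)
        assert table.t_half_h.iloc[0] == pytest.approx(expected, abs=0.05)


class TestEndToEndRecovery:
    def test_fig2_style_plate_recovers_truth_within_10_percent(self):
        """Default synthetic salt series: 1% noise, 3 replicates."""
        spec = make_salt_series(rng_seed=42)
        plate, meta, truth = simulate_plate(spec)
        t = plate["time_h"].to_numpy()
        for seed_uM in (0.005, 0.05):
            traces = [
                make_trace(plate[row.well].to_numpy(), salt=row.salt_mM,
                           seed=row.seed_uM, rep=row.well, t=t)
                for _, row in meta.iterrows() if row.seed_uM == seed_uM
            ]
            res = fit_seeded_series(traces)
            tt = truth[truth.seed_uM == seed_uM].groupby("salt_mM").k2kplus.first()
            live = [f for f in res.fits if f.aggregating]
            assert len(live) == 5  # salts below the inhibition threshold
            for f in live:
                assert f.k2kplus == pytest.approx(tt[f.salt_mM], rel=0.10)
            ks = [f.k2kplus for f in sorted(live, key=lambda f: f.salt_mM)]
            assert all(a > b for a, b in zip(ks, ks[1:]))
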