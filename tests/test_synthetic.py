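"""Generator contracts: compensation model, phase simulator, phantoms, cohorts."""

import numpy as np
import pytest

from mipscsf.processing import block_smooth
from mipscsf.schedule import InjectionSchedule
from mipscsf.synthetic import (
    LABELS,
    CompensationModelParams,
    MIPSModelParams,
    PhantomSpec,
    csf_of_blood,
    csf_pool_mask,
    generate_cohort,
    generate_phantom,
    generate_template,
    simulate_csf_compensation,
    simulate_mips,
)


def fit_breakpoint_oracle(blood, csf):
    """Grid-search least-squares fit of the single-breakpoint model."""
    best = None
    for b0 in np.linspace(blood[0] + 0.05, blood[-1] - 0.05, 241):
        X = np.column_stack(
            [np.ones_like(blood), np.minimum(blood, b0), np.maximum(0.0, blood - b0)]
        )
        coef, *_ = np.linalg.lstsq(X, csf, rcond=None)
        sse = float(((csf - X @ coef) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, b0, coef)
    return best[1], best[2]


class TestSchedule:
    def test_rate_times_duration_equals_total(self, schedule):
        assert schedule.rate * schedule.duration == pytest.approx(3.0, abs=1e-9)

    def test_blood_is_nondecreasing_and_capped(self, schedule):
        t = np.linspace(-5, 80, 400)
        b = schedule.blood_at(t)
        assert np.all(np.diff(b) >= 0)
        assert b[0] == 0.0 and b[-1] == schedule.total_volume

    def test_invalid_sample_times_rejected(self):
        with pytest.raises(ValueError):
            InjectionSchedule(sample_times=(6.0, 6.0, 12.0))
        with pytest.raises(ValueError):
            InjectionSchedule(sample_times=(6.0, 60.0))


class TestCompensation:
    def test_no_injection_returns_baseline_exactly(self, schedule):
        p = CompensationModelParams(noise_sd=0.0)
        assert csf_of_blood(p, 0.0) == pytest.approx(p.csf_baseline, abs=0)

    def test_zero_slopes_give_constant_series(self, schedule):
        p = CompensationModelParams(slope_pre=0.0, slope_post=0.0, noise_sd=0.0)
        noisy, clean = simulate_csf_compensation(p, schedule, seed=0)
        assert np.all(clean == p.csf_baseline)
        assert np.all(noisy == clean)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CompensationModelParams(csf_baseline=-1.0)
        with pytest.raises(ValueError):
            CompensationModelParams(slope_pre=0.1)
        with pytest.raises(ValueError):
            CompensationModelParams(slope_pre=-0.05, slope_post=-0.2)

    def test_noise_free_trajectory_nonincreasing(self, schedule):
        _, clean = simulate_csf_compensation(CompensationModelParams(), schedule, seed=1)
        assert np.all(np.diff(clean) <= 0)

    def test_breakpoint_recovered_from_table_mean_fit(self, schedule, tables):
        # fit the model to the packaged mean CSF trajectory, resimulate
        # noise-free, re-fit: the breakpoint must survive the round trip
        blood = schedule.sample_blood
        csf_mean = tables.table2[[f"rabbit_{j}" for j in range(1, 9)]].mean(axis=1).to_numpy()
        b0, coef = fit_breakpoint_oracle(blood, csf_mean)
        params = CompensationModelParams(
            csf_baseline=coef[0], inflection_blood=b0,
            slope_pre=min(coef[1], 0.0), slope_post=min(coef[2], 0.0), noise_sd=0.0,
        )
        _, clean = simulate_csf_compensation(params, schedule, seed=0)
        b0_rec, _ = fit_breakpoint_oracle(blood, clean)
        assert abs(b0_rec - b0) <= 0.33


class TestMIPS:
    def test_protocol_yields_2700_samples(self, schedule):
        raw = simulate_mips(MIPSModelParams(), csf_of_blood(CompensationModelParams(), schedule.sample_blood), schedule, seed=0)
        assert raw.time_s.size == 2700

    def test_all_zero_terms_give_constant_baseline(self, schedule):
        mp = MIPSModelParams(coef_csf=1e-12, coef_blood=0.0, resp_amp=0.0,
                             cardiac_amp=0.0, noise_sd=0.0)
        csf = np.full(9, 0.8)
        raw = simulate_mips(mp, csf, schedule, seed=0)
        assert np.allclose(raw.phase_deg, mp.baseline_phase, atol=1e-9)

    def test_mismatched_series_length_rejected(self, schedule):
        with pytest.raises(ValueError):
            simulate_mips(MIPSModelParams(), np.ones(5), schedule, seed=0)

    def test_noise_free_block_means_are_v_shaped(self, schedule):
        comp = CompensationModelParams(noise_sd=0.0)
        mp = MIPSModelParams(resp_amp=0.0, cardiac_amp=0.0, noise_sd=0.0)
        _, clean = simulate_csf_compensation(comp, schedule, seed=0)
        raw = simulate_mips(mp, clean, schedule, seed=0)
        blocks = block_smooth(raw)
        d = np.diff(blocks.value)
        pivot = int(np.searchsorted(blocks.blood_ml, comp.inflection_blood))
        # the block straddling the inflection is transitional; strict
        # monotonicity holds on either side of it
        assert np.all(d[: pivot - 1] < 0)
        assert np.all(d[pivot + 1 :] > 0)
        assert abs(int(np.argmin(blocks.value)) - pivot) <= 1


class TestPhantom:
    def test_ground_truth_count_matches_voxel_arithmetic(self):
        spec = PhantomSpec(seed=0)
        _, truth = generate_phantom(spec, 1.10, 0.0)
        expected = round(1100.0 / 0.1455)
        assert int(truth.mask_of(LABELS["CSF"]).sum()) == expected == 7560

    def test_zero_blood_yields_no_hematoma(self):
        spec = PhantomSpec(seed=0)
        _, truth = generate_phantom(spec, 0.8, 0.0)
        assert int(truth.mask_of(LABELS["blood"]).sum()) == 0

    def test_noise_and_smoothing_off_give_exact_class_means(self):
        spec = PhantomSpec(grid_shape=(32, 32, 24), noise_sd=0.0, smoothing_fwhm=0.0, seed=0)
        vol, truth = generate_phantom(spec, 0.3, 0.1)
        for name, code in LABELS.items():
            sel = truth.mask_of(code)
            if sel.any():
                assert np.all(vol.intensity[sel] == spec.tissue_means[name])

    def test_over_capacity_request_rejected(self):
        spec = PhantomSpec(grid_shape=(32, 32, 24), seed=0)
        with pytest.raises(ValueError):
            generate_phantom(spec, 50.0, 0.0)

    def test_template_contains_every_phantom_mask(self):
        spec = PhantomSpec(grid_shape=(48, 48, 32), seed=1)
        tpl = generate_template(spec, dilation_mm=1.0)
        for v in (0.2, 0.5, 0.9):
            _, truth = generate_phantom(spec, v, 0.0)
            csf = truth.mask_of(LABELS["CSF"])
            assert np.array_equal(tpl & csf, csf)

    def test_zero_dilation_template_equals_full_pool_mask(self):
        spec = PhantomSpec(grid_shape=(48, 48, 32), seed=1)
        pool = csf_pool_mask(spec)
        capacity = pool.sum() * spec.voxel_volume_mm3 / 1000.0
        _, truth = generate_phantom(spec, capacity, 0.0)
        tpl = generate_template(spec, dilation_mm=0.0)
        assert np.array_equal(tpl, truth.mask_of(LABELS["CSF"]))

    def test_dilation_grows_template_monotonically(self):
        spec = PhantomSpec(grid_shape=(48, 48, 32), seed=1)
        counts = [generate_template(spec, d).sum() for d in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(counts) > 0)


class TestCohort:
    def test_table_shapes_match_protocol(self, schedule):
        b = generate_cohort(n_rabbits=8, seed=0)
        assert b.mips_table.shape == (9, 8)
        assert b.csf_table.shape == (9, 8)

    def test_same_seed_reproduces_identically(self):
        a = generate_cohort(n_rabbits=3, seed=42)
        b = generate_cohort(n_rabbits=3, seed=42)
        assert np.array_equal(a.mips_table, b.mips_table)
        assert np.array_equal(a.csf_table, b.csf_table)
        assert np.array_equal(a.mips_raw[0].phase_deg, b.mips_raw[0].phase_deg)

    def test_noise_free_csf_columns_nonincreasing(self):
        b = generate_cohort(n_rabbits=4, seed=3, noisy=False)
        assert np.all(np.diff(b.csf_truth, axis=0) <= 0)
        assert np.all(np.diff(b.csf_table, axis=0) <= 0)

    def test_fewer_than_two_rabbits_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(n_rabbits=1, seed=0)
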