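import numpy as np
import pandas as pd
import pytest

from relaxo.multi_fit import fit_multi_volume
from relaxo.roi_stats import tissue_volumes, roi_mean_curve
from relaxo.signal_models import predict_multi
from relaxo.synthetic_cohort import (
    calibrate_free_water_fraction,
    default_cohort_spec,
    effective_mono_t2,
    generate_cohort,
    iterate_cohort,
    render_subject,
    sample_subject,
    sample_truth_table,
    volume_mediated_cohort,
)


@pytest.fixture(scope="module")
def spec():
    return default_cohort_spec(seed=1)


def _zero_sd_spec(spec):
    from dataclasses import replace

    strata = tuple(
        replace(
            st,
            volume_sd_l={t: 0.0 for t in st.volume_sd_l},
            wm_mwf_sd=0.0,
            wm_t2_sd_ms=0.0,
        )
        for st in spec.strata
    )
    return replace(spec, strata=strata)


class TestDefaultSpec:
    def test_strata_sizes(self, spec):
        sizes = {st.name: st.n_subjects for st in spec.strata}
        assert sizes == {
            "preterm_male": 16,
            "preterm_female": 27,
            "term_male": 10,
            "term_female": 10,
        }
        assert spec.n_subjects == 63

    def test_acquisition_defaults(self, spec):
        np.testing.assert_array_equal(
            spec.echo_times, [13, 16, 20, 25, 30, 40, 50, 85, 100, 150]
        )
        assert spec.voxel_dims == (2.5, 2.5, 3.0)
        np.testing.assert_array_equal(spec.basis.t2_values, [20, 80, 2000])


class TestCalibration:
    def test_calibrated_mixture_hits_target_t2(self, spec):
        for mwf, target in ((0.25, 69.5), (0.26, 67.3), (0.26, 66.8)):
            c = calibrate_free_water_fraction(mwf, target, spec.basis, spec.echo_times)
            got = effective_mono_t2((mwf, 1 - mwf - c, c), spec.basis, spec.echo_times)
            if c > 0:
                assert got == pytest.approx(target, abs=1e-4)
            else:  # clamped at the attainable floor
                assert got >= target - 0.5

    def test_effective_t2_monotone_in_free_water(self, spec):
        t2s = [
            effective_mono_t2((0.25, 0.75 - c, c), spec.basis, spec.echo_times)
            for c in (0.0, 0.02, 0.05)
        ]
        assert t2s == sorted(t2s)


class TestSampleSubject:
    def test_zero_sd_spec_reproduces_stratum_means(self, spec):
        zspec = _zero_sd_spec(spec)
        rng = np.random.default_rng(0)
        st = zspec.strata[0]
        a = sample_subject(zspec, st, rng)
        b = sample_subject(zspec, st, np.random.default_rng(99))
        assert a.fractions == b.fractions
        assert a.volumes_l == b.volumes_l
        assert a.fractions["wm"][0] == pytest.approx(st.wm_mwf_mean, abs=1e-9)
        assert a.effective_t2_ms["wm"] == pytest.approx(st.wm_t2_mean_ms, abs=0.01)

    def test_deterministic_under_fixed_seed(self, spec):
        a = sample_subject(spec, spec.strata[1], np.random.default_rng(5))
        b = sample_subject(spec, spec.strata[1], np.random.default_rng(5))
        assert a == b

    def test_volume_draws_satisfy_clt_bound(self, spec):
        st = next(s for s in spec.strata if s.name == "preterm_female")
        rng = np.random.default_rng(10)
        draws = np.array([sample_subject(spec, st, rng).volumes_l["wm"] for _ in range(1000)])
        # Truncation at 0 is ~9 SDs away, so the plain CLT bound applies.
        assert abs(draws.mean() - 0.35) < 3 * 0.04 / np.sqrt(1000)

    def test_mwf_and_t2_marginals_on_target(self, spec):
        st = next(s for s in spec.strata if s.name == "preterm_female")
        rng = np.random.default_rng(11)
        truths = [sample_subject(spec, st, rng) for _ in range(1500)]
        mwf = np.array([t.fractions["wm"][0] for t in truths])
        t2 = np.array([t.effective_t2_ms["wm"] for t in truths])
        assert mwf.mean() == pytest.approx(st.wm_mwf_mean, abs=3 * st.wm_mwf_sd / np.sqrt(1500))
        assert mwf.std(ddof=1) == pytest.approx(st.wm_mwf_sd, rel=0.15)
        assert t2.mean() == pytest.approx(st.wm_t2_mean_ms, abs=3 * st.wm_t2_sd_ms / np.sqrt(1500))

    def test_grid_overflow_names_required_size(self, spec):
        from dataclasses import replace

        tiny = replace(spec, grid_shape=(4, 4, 4))
        with pytest.raises(ValueError, match="grid"):
            sample_subject(tiny, tiny.strata[0], np.random.default_rng(0))


class TestRenderSubject:
    def test_label_counts_match_truth_ledger(self, spec):
        rng = np.random.default_rng(3)
        truth = sample_subject(spec, spec.strata[0], rng)
        labels, echoes = render_subject(truth, spec, rng)
        vols = tissue_volumes(labels)
        for tissue, code in (("csf", 1), ("gm", 2), ("wm", 3)):
            assert int((labels.labels == code).sum()) == truth.voxel_counts[tissue]
            assert vols[f"{tissue}_volume_l"] == pytest.approx(truth.volumes_l[tissue], abs=1e-12)

    def test_noiseless_roundtrip_recovers_wm_fractions(self, spec):
        from dataclasses import replace

        quiet = replace(_zero_sd_spec(spec), snr_first_echo=np.inf)
        rng = np.random.default_rng(4)
        truth = sample_subject(quiet, quiet.strata[0], rng)
        labels, echoes = render_subject(truth, quiet, rng)
        wm_mask = labels.labels == 3
        mwf_map, fraction_maps, _ = fit_multi_volume(
            echoes, quiet.echo_times, wm_mask, basis=quiet.basis
        )
        expected = np.broadcast_to(
            np.asarray(truth.fractions["wm"]), fraction_maps[wm_mask].shape
        )
        np.testing.assert_allclose(fraction_maps[wm_mask], expected, atol=1e-6)

    def test_roi_mean_curve_within_averaging_noise_bound(self, spec):
        rng = np.random.default_rng(6)
        truth = sample_subject(spec, spec.strata[0], rng)
        labels, echoes = render_subject(truth, spec, rng)
        curve = roi_mean_curve(echoes, spec.echo_times, labels, "wm")
        clean = predict_multi(spec.s0, np.asarray(truth.fractions["wm"]), spec.basis, spec.echo_times)
        n_wm = truth.voxel_counts["wm"]
        bound = 3.0 * truth.noise_sd / np.sqrt(n_wm)
        np.testing.assert_array_less(np.abs(curve.signals - clean), bound)


class TestCohortGeneration:
    def test_iterate_covers_all_strata(self, spec):
        from dataclasses import replace

        small = replace(
            spec,
            strata=tuple(replace(st, n_subjects=1) for st in spec.strata),
        )
        out = list(iterate_cohort(small))
        assert len(out) == 4
        assert {t.stratum for t, _, _ in out} == {st.name for st in spec.strata}

    def test_truth_tables_identical_across_runs(self, spec):
        a = sample_truth_table(spec)
        b = sample_truth_table(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_generate_cohort_writes_tree(self, spec, tmp_path):
        from dataclasses import replace

        small = replace(spec, strata=tuple(replace(st, n_subjects=1) for st in spec.strata))
        table = generate_cohort(small, tmp_path / "cohort")
        assert len(table) == 4
        files = list((tmp_path / "cohort").iterdir())
        names = {f.name for f in files}
        assert "truth.csv" in names and "manifest.json" in names
        assert sum(n.endswith("_echoes.nii.gz") for n in names) == 4
        with pytest.raises(FileExistsError):
            generate_cohort(small, tmp_path / "cohort")

    def test_group_labels_do_not_leak_into_geometry(self, spec):
        # Identical stratum parameters under different group names must give
        # identical images for the same RNG stream.
        from dataclasses import replace

        st = spec.strata[0]
        st2 = replace(st, name="term_male")
        t1 = sample_subject(spec, st, np.random.default_rng(8))
        t2 = sample_subject(spec, st2, np.random.default_rng(8))
        l1, e1 = render_subject(t1, spec, np.random.default_rng(9))
        l2, e2 = render_subject(t2, spec, np.random.default_rng(9))
        np.testing.assert_array_equal(l1.labels, l2.labels)
        np.testing.assert_array_equal(e1, e2)


class TestVolumeMediatedCohort:
    def test_groups_differ_only_through_volume(self):
        table = volume_mediated_cohort(seed=0)
        assert set(table.group) == {"preterm", "term"}
        resid = table.wm_t2_ms - (52.0 + 40.0 * table.wm_volume_l)
        by_group = resid.groupby(table.group).mean()
        # Residual noise is independent of group membership.
        assert abs(by_group["preterm"] - by_group["term"]) < 1.0
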