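import numpy as np
import pandas as pd
import pytest

from holterhrv import (
    BandNoise,
    CohortSpec,
    EctopySpec,
    FiducialLaws,
    GroupEffects,
    RSA,
    Sinusoid,
    SyntheticSpec,
    clean_to_nn,
    detect_bigeminy,
    detect_r_on_t,
    gen_beats,
    gen_cohort,
    inject_ectopy,
    read_beats,
    summarize_arrhythmia,
    write_beats,
)


def _plain_spec(duration_min=10.0, base_rr=1000.0, **kw):
    kw.setdefault("fiducials", None)
    return SyntheticSpec(duration_min=duration_min, base_rr_ms=base_rr, **kw)


class TestGenBeats:
    def test_unmodulated_beat_count(self):
        s = gen_beats(_plain_spec())
        assert abs(len(s) - 600) <= 1
        nn = clean_to_nn(s)
        assert np.allclose(nn.rr_ms, 1000.0, atol=0.01)

    def test_ipfm_count_invariant_various_rates(self):
        for base in (400.0, 750.0, 1200.0):
            s = gen_beats(_plain_spec(duration_min=5.0, base_rr=base))
            expected = int(5 * 60_000.0 // base)
            assert abs(len(s) - expected) <= 1

    def test_determinism_byte_level(self, tmp_path):
        spec = SyntheticSpec(
            duration_min=3.0, base_rr_ms=600.0,
            modulators=(Sinusoid(0.1, 40.0), BandNoise(0.004, 0.04, 400.0)),
            seed=42,
        )
        p1 = write_beats(gen_beats(spec), tmp_path / "a.csv")
        p2 = write_beats(gen_beats(spec), tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        spec1 = _plain_spec(modulators=(BandNoise(0.004, 0.04, 400.0),), seed=1)
        spec2 = _plain_spec(modulators=(BandNoise(0.004, 0.04, 400.0),), seed=2)
        assert not np.array_equal(gen_beats(spec1).t_r, gen_beats(spec2).t_r)

    def test_modulation_too_deep_rejected(self):
        with pytest.raises(ValueError, match="too deep"):
            SyntheticSpec(duration_min=1.0, base_rr_ms=600.0,
                          modulators=(Sinusoid(0.1, 600.0),))

    def test_tachogram_variance_matches_planted(self):
        spec = _plain_spec(
            duration_min=30.0, base_rr=500.0,
            modulators=(Sinusoid(0.05, 40.0), Sinusoid(0.22, 25.0)),
        )
        nn = clean_to_nn(gen_beats(spec))
        planted = (40.0**2 + 25.0**2) / 2.0
        assert np.var(nn.rr_ms) == pytest.approx(planted, rel=0.05)

    def test_fiducial_laws_applied(self):
        spec = SyntheticSpec(
            duration_min=2.0, base_rr_ms=800.0,
            fiducials=FiducialLaws(), seed=0,
        )
        s = gen_beats(spec)
        qt = s.t_end[2] - s.qrs_on[2]
        assert qt == pytest.approx(230.0 + 87.0 * (0.8 - 1.0), abs=0.01)
        pr = s.qrs_on[2] - s.p_on[2]
        assert pr == pytest.approx(40.0 + 0.08 * 800.0, abs=0.01)

    def test_output_passes_reader_validation(self, tmp_path):
        spec = SyntheticSpec(
            duration_min=2.0, base_rr_ms=700.0,
            modulators=(Sinusoid(0.1, 30.0),), rsa=RSA(amp_ms=25.0), seed=5,
        )
        s = gen_beats(spec)
        s2 = read_beats(write_beats(s, tmp_path / "dogfood.csv"))
        assert len(s2) == len(s)


class TestInjectEctopy:
    def _base(self, duration_min=60.0, fiducials=FiducialLaws()):
        return gen_beats(
            SyntheticSpec(duration_min=duration_min, base_rr_ms=600.0,
                          fiducials=fiducials, seed=3)
        )

    def test_isolated_rate_gives_lown_2(self):
        out, log = inject_ectopy(self._base(), EctopySpec(rate_per_hr=45.0), seed=1)
        res = summarize_arrhythmia(out)
        assert res.n_pvb == 45
        assert res.n_isolated == 45
        assert res.lown == "2"
        assert len(log) == 45

    def test_low_rate_gives_lown_1(self):
        out, _ = inject_ectopy(self._base(), EctopySpec(rate_per_hr=10.0), seed=1)
        assert summarize_arrhythmia(out).lown == "1"

    def test_run_of_five_is_vt(self):
        espec = EctopySpec(rate_per_hr=1.0, run_length_probs={5: 1.0})
        out, log = inject_ectopy(self._base(), espec, seed=2)
        res = summarize_arrhythmia(out)
        assert res.max_run_len == 5
        assert res.lown == "4b"
        assert log.loc[0, "run_length"] == 5

    def test_r_on_t_detected_and_graded(self):
        espec = EctopySpec(rate_per_hr=5.0, r_on_t=True)
        out, log = inject_ectopy(self._base(), espec, seed=4)
        assert detect_r_on_t(out).present is True
        assert summarize_arrhythmia(out).lown == "5"
        assert (log["type"] == "r_on_t").sum() == 1

    def test_r_on_t_without_fiducials_uses_heuristic(self):
        base = self._base(fiducials=None)
        out, _ = inject_ectopy(base, EctopySpec(rate_per_hr=2.0, r_on_t=True), seed=4)
        res = detect_r_on_t(out)
        assert res.present is True
        assert res.heuristic is True

    def test_bigeminy_toggle(self):
        espec = EctopySpec(bigeminy=True, n_bigeminy_pairs=6)
        out, log = inject_ectopy(self._base(duration_min=10.0), espec, seed=5)
        assert detect_bigeminy(out) is True
        assert summarize_arrhythmia(out).lown == "3b"
        assert (log["type"] == "bigeminy").sum() == 6

    def test_polymorphic_morphs(self):
        espec = EctopySpec(rate_per_hr=40.0, morph_ids=(1, 2, 3))
        out, _ = inject_ectopy(self._base(), espec, seed=6)
        res = summarize_arrhythmia(out)
        assert res.polymorphic is True
        assert res.lown == "3a"

    def test_rate_too_high_errors(self):
        base = gen_beats(
            SyntheticSpec(duration_min=60.0, base_rr_ms=2500.0, fiducials=None, seed=0)
        )
        with pytest.raises(ValueError, match="too high"):
            inject_ectopy(base, EctopySpec(rate_per_hr=900.0), seed=0)

    def test_requires_all_normal_input(self):
        out, _ = inject_ectopy(self._base(), EctopySpec(rate_per_hr=5.0), seed=1)
        with pytest.raises(ValueError, match="all-N"):
            inject_ectopy(out, EctopySpec(rate_per_hr=5.0), seed=1)

    def test_output_monotonic_and_readable(self, tmp_path):
        out, _ = inject_ectopy(
            self._base(), EctopySpec(rate_per_hr=30.0, run_length_probs={1: 0.6, 2: 0.3, 5: 0.1}),
            seed=7,
        )
        assert (np.diff(out.t_r) > 0).all()
        read_beats(write_beats(out, tmp_path / "ect.csv"))

    def test_non_compensatory_pause(self):
        base = self._base(duration_min=5.0)
        espec = EctopySpec(rate_per_hr=12.0, compensatory_factor=1.5)
        out, log = inject_ectopy(base, espec, seed=8)
        i = int(log.loc[0, "index"])
        rr_after = out.t_r[i + 1] - out.t_r[i]
        # pause = (factor - coupling) * local NN = 0.9 * 600
        assert rr_after == pytest.approx(0.9 * 600.0, rel=0.05)


class TestGenCohort:
    def _spec(self, **kw):
        kw.setdefault("n_per_group", 2)
        kw.setdefault("timepoints", (4.0,))
        kw.setdefault("duration_min", 2.0)
        kw.setdefault("seed", 11)
        return CohortSpec(**kw)

    def test_files_and_tables_written(self, tmp_path):
        manifest, truth = gen_cohort(self._spec(), tmp_path)
        assert len(manifest) == 4
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "truth.csv").exists()
        for p in manifest["recording_path"]:
            s = read_beats(tmp_path / p)
            assert len(s) > 50

    def test_determinism_manifest_hash(self, tmp_path):
        import hashlib

        m1, _ = gen_cohort(self._spec(), tmp_path / "a")
        m2, _ = gen_cohort(self._spec(), tmp_path / "b")
        h1 = hashlib.sha256((tmp_path / "a" / "manifest.csv").read_bytes()).hexdigest()
        h2 = hashlib.sha256((tmp_path / "b" / "manifest.csv").read_bytes()).hexdigest()
        assert h1 == h2
        pd.testing.assert_frame_equal(m1, m2)

    def test_group_effects_in_truth(self, tmp_path):
        spec = self._spec(
            n_per_group=3,
            group_effects=GroupEffects(delta_hr_bpm=25.0, vlf_factor=0.3),
            hr_subject_sd=0.0,
            power_subject_sigma=0.0,
        )
        _, truth = gen_cohort(spec, tmp_path)
        g = truth[truth["group"] == "GRMD"]
        h = truth[truth["group"] == "healthy"]
        assert g["hr_true_bpm"].mean() - h["hr_true_bpm"].mean() == pytest.approx(25.0)
        assert g["vlf_true_ms2"].mean() / h["vlf_true_ms2"].mean() == pytest.approx(0.3)

    def test_outcome_law_planted(self, tmp_path):
        spec = self._spec(n_per_group=4, power_subject_sigma=0.6)
        manifest, truth = gen_cohort(spec, tmp_path)
        g = truth[truth["group"] == "GRMD"].drop_duplicates("subject")
        pred = spec.outcome.alpha + spec.outcome.beta_per_ms2 * g["vlf_true_ms2"]
        resid = g["lvfs_24m"] - pred
        assert resid.abs().max() < 4 * spec.outcome.eps_sd + 1e-9
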