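"""Signal models, noise model, image-series simulators and cohort generator."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from hepafe import phantom as ph
from hepafe.stats import icc_two_way, rating_matrix


def second_opinion_gre(pd_, t1, t2s, tr, flip_deg, te):
    """Independent re-evaluation of the spoiled-GRE steady state (math module)."""
    e1 = math.exp(-tr / t1)
    a = math.radians(flip_deg)
    return pd_ * math.sin(a) * (1 - e1) / (1 - math.cos(a) * e1) * math.exp(-te / t2s)


class TestSpoiledGRESignal:
    def test_ernst_limit_te0_flip90_long_tr(self):
        # TR >> T1 and TE -> 0: signal saturates at the proton density
        t = ph.TissueParams(123.0, 500.0, 20.0)
        acq = ph.GREAcquisition(tr_ms=500 * 500.0, echo_times_ms=(1e-9,), flip_deg=90.0)
        s = ph.spoiled_gre_signal(t, acq, te_ms=1e-9)
        assert s == pytest.approx(123.0, rel=1e-6)

    def test_linear_in_proton_density(self):
        acq = ph.GREAcquisition(200.0, (4.0,), 20.0)
        s1 = ph.spoiled_gre_signal(ph.TissueParams(50.0, 576.0, 20.0), acq, te_ms=4.0)
        s2 = ph.spoiled_gre_signal(ph.TissueParams(100.0, 576.0, 20.0), acq, te_ms=4.0)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_against_independent_closed_form(self):
        t = ph.TissueParams(100.0, 576.0, 20.0)
        acq = ph.GREAcquisition(200.0, (1.3,), 20.0)
        got = ph.spoiled_gre_signal(t, acq, te_ms=1.3)
        assert got == pytest.approx(second_opinion_gre(100, 576, 20, 200, 20, 1.3), rel=1e-12)

    def test_strictly_decreasing_in_te(self):
        t = ph.TissueParams(100.0, 576.0, 10.0)
        acq = ph.GREAcquisition(200.0, tuple(np.linspace(1, 20, 10)), 20.0)
        s = ph.spoiled_gre_signal(t, acq)
        assert np.all(np.diff(s) < 0) and np.all(s > 0)

    def test_model_limits(self):
        # TE -> 0 removes the T2* dependence; TR = 50 T1 removes T1 dependence
        acq0 = ph.GREAcquisition(200.0, (1e-12,), 20.0)
        sa = ph.spoiled_gre_signal(ph.TissueParams(80, 500, 2.0), acq0, te_ms=1e-12)
        sb = ph.spoiled_gre_signal(ph.TissueParams(80, 500, 50.0), acq0, te_ms=1e-12)
        assert sa == pytest.approx(sb, rel=1e-9)
        long_tr = ph.GREAcquisition(50 * 900.0, (4.0,), 30.0)
        sc = ph.spoiled_gre_signal(ph.TissueParams(80, 900.0, 20.0), long_tr, te_ms=4.0)
        sd = ph.spoiled_gre_signal(ph.TissueParams(80, 300.0, 20.0), long_tr, te_ms=4.0)
        assert sc == pytest.approx(sd, rel=1e-6)

    def test_nonpositive_relaxation_times_rejected(self):
        with pytest.raises(ValueError):
            ph.TissueParams(100.0, -1.0, 20.0)
        with pytest.raises(ValueError):
            ph.TissueParams(100.0, 500.0, 0.0)


class TestMolliSignal:
    def test_ti_zero_gives_a_minus_b(self):
        assert ph.molli_signal(500.0, 300.0, 600.0, 0.0) == pytest.approx(-300.0)

    def test_asymptote_reaches_a(self):
        s = ph.molli_signal(500.0, 300.0, 600.0, 10 * 500.0)
        assert abs(s - 300.0) < 1e-4 * 300.0

    def test_against_independent_evaluation(self):
        got = ph.molli_signal(500.0, 300.0, 600.0, 500.0)
        assert got == pytest.approx(300.0 - 600.0 * math.exp(-1.0), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ph.molli_signal(-5.0, 300.0, 600.0, 100.0)
        with pytest.raises(ValueError):
            ph.molli_signal(500.0, 300.0, 600.0, -1.0)


class TestRicianNoise:
    def test_sigma_zero_is_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        out = ph.add_rician_noise(img, 0.0, 1)
        assert np.array_equal(out, img)

    def test_zero_signal_mean_matches_rayleigh(self):
        # at zero SNR the magnitude is Rayleigh with mean sigma*sqrt(pi/2)
        out = ph.add_rician_noise(np.zeros(100_000), 3.0, 42)
        expect = 3.0 * math.sqrt(math.pi / 2)
        assert out.mean() == pytest.approx(expect, rel=0.02)

    def test_seeded_determinism(self):
        img = np.ones((16, 16))
        a = ph.add_rician_noise(img, 0.5, 7)
        b = ph.add_rician_noise(img, 0.5, 7)
        assert np.array_equal(a, b)


class TestMGRESeries:
    def test_default_schedule_endpoints(self, mgre_acq):
        te = mgre_acq.echo_times_ms
        assert len(te) == 12
        assert te[0] == pytest.approx(1.3) and te[-1] == pytest.approx(16.9)

    def test_noiseless_log_signal_is_linear_in_te(self):
        scene = ph.build_scene(shape=(48, 48), noise_sigma=0.0)
        stack, meta = ph.simulate_mgre_series(scene)
        liver = scene.mask("liver")
        means = np.array([img[liver].mean() for img in stack])
        te = np.array(meta["echo_times_ms"])
        slope = np.polyfit(te, np.log(means), 1)[0]
        assert -1.0 / slope == pytest.approx(scene.tissues["liver"].t2star_ms, rel=1e-9)

    def test_iron_loaded_liver_is_darker_at_every_echo(self):
        low = ph.build_scene(liver=ph.TissueParams(100, 576, 20.0), shape=(48, 48), noise_sigma=0.0)
        high = ph.build_scene(liver=ph.TissueParams(100, 576, 3.0), shape=(48, 48), noise_sigma=0.0)
        sl, _ = ph.simulate_mgre_series(low)
        sh, _ = ph.simulate_mgre_series(high)
        m = low.mask("liver")
        assert all(sh[k][m].mean() < sl[k][m].mean() for k in range(12))

    def test_determinism_same_seed(self, small_scene):
        a, _ = ph.simulate_mgre_series(small_scene)
        b, _ = ph.simulate_mgre_series(small_scene)
        assert np.array_equal(a, b)


class TestURennesSet:
    def test_metadata_matches_protocol(self, small_scene):
        _, metas = ph.simulate_urennes_set(small_scene)
        triples = [(m["tr_ms"], m["te_ms"], m["flip_deg"]) for m in metas]
        assert triples == [
            (120.0, 4.0, 90.0),
            (120.0, 4.0, 20.0),
            (120.0, 9.0, 20.0),
            (120.0, 14.0, 20.0),
            (120.0, 21.0, 20.0),
        ]

    def test_identical_tissues_give_unit_ratio(self):
        same = ph.TissueParams(100.0, 600.0, 25.0)
        scene = ph.build_scene(liver=same, muscle=same, shape=(48, 48), noise_sigma=0.0)
        stack, _ = ph.simulate_urennes_set(scene)
        liver, mus = scene.mask("liver"), scene.mask("muscle_right")
        for img in stack:
            assert img[liver].mean() / img[mus].mean() == pytest.approx(1.0, rel=1e-9)

    def test_iron_load_ratio_decreases_with_t2_weighting(self):
        scene = ph.build_scene(
            liver=ph.liver_tissue_for_lic(8.0), shape=(48, 48), noise_sigma=0.0
        )
        stack, _ = ph.simulate_urennes_set(scene)
        liver, mus = scene.mask("liver"), scene.mask("muscle_right")
        ratios = [img[liver].mean() / img[mus].mean() for img in stack]
        assert ratios[1] > ratios[2] > ratios[3] > ratios[4]

    def test_missing_muscle_region_rejected(self):
        labels = np.zeros((32, 32), dtype=np.int8)
        labels[4:20, 4:20] = ph.LABEL_LIVER
        scene = ph.PhantomScene(labels=labels, tissues={"liver": ph.LIVER_BASE})
        with pytest.raises(ValueError, match="muscle"):
            ph.simulate_urennes_set(scene)


class TestMOLLISeries:
    def test_ti_ladder_5_3_3_at_60bpm(self):
        acq = ph.MOLLIAcquisition()
        assert acq.ti_ms == (100.0, 180.0, 1100.0, 1180.0, 2100.0, 2180.0, 3100.0, 4100.0)

    def test_magnitude_output_loses_polarity(self):
        scene = ph.build_scene(shape=(48, 48), noise_sigma=0.0)
        stack, meta = ph.simulate_molli_series(scene)
        assert np.all(stack >= 0)
        # earliest TI is pre-null for any liver-like T1, so the signed model is negative
        t1 = scene.tissues["liver"].t1_ms
        t1star = t1 / 0.9
        signed = ph.molli_signal(t1star, 100.0, 1.9 * 100.0, meta["ti_ms"][0])
        assert signed < 0


class TestCohort:
    def test_zero_rater_noise_makes_raters_identical(self):
        noise = {m: ph.MethodNoise(0.0, 0.0) for m in ph.DEFAULT_METHOD_NOISE}
        spec = ph.CohortSpec(n_patients=10, n_controls=5, method_noise=noise, seed=3)
        with pytest.warns(UserWarning):
            df = ph.simulate_cohort(spec)
        mat = rating_matrix(df, "manual_t2s", by="rater")
        assert np.array_equal(mat[:, 0], mat[:, 1])
        assert icc_two_way(mat).icc == pytest.approx(1.0)

    def test_patients_have_higher_true_lic(self):
        df = ph.simulate_cohort(ph.CohortSpec(seed=5))
        per_subj = df.drop_duplicates("subject_id")
        pats = per_subj[per_subj.group == "patient"]["true_lic_mg_g"]
        ctrl = per_subj[per_subj.group == "control"]["true_lic_mg_g"]
        assert pats.mean() > ctrl.mean()
        assert ctrl.between(0.2, 2.0).all()

    def test_true_lic_auc_matches_mann_whitney_oracle(self):
        # AUC of the generating LIC against group computed two independent ways
        df = ph.simulate_cohort(ph.CohortSpec(seed=11)).drop_duplicates("subject_id")
        x = df[df.group == "patient"]["true_lic_mg_g"].to_numpy()
        y = df[df.group == "control"]["true_lic_mg_g"].to_numpy()
        u = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
        auc_mw = u / (len(x) * len(y))
        from hepafe.stats import roc_auc

        scores = df["true_lic_mg_g"].to_numpy()
        labels = (df["group"] == "patient").astype(int).to_numpy()
        assert roc_auc(scores, labels).auc == pytest.approx(auc_mw, abs=1e-12)

    def test_generator_is_pure_function_of_spec(self):
        a = ph.simulate_cohort(ph.CohortSpec(seed=9))
        b = ph.simulate_cohort(ph.CohortSpec(seed=9))
        assert a.equals(b)
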