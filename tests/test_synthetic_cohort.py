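import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinscan import (
    AttritionModel,
    CohortConfig,
    MotionModel,
    ValidationError,
    default_protocol,
    generate_cohort,
    generate_twin_phenotypes,
    read_cohort_table,
    read_motion_par,
)
from twinscan.io_formats import cohort_to_frame, distress_column
from twinscan.motion_metrics import framewise_displacement
from twinscan.synthetic_cohort import generate_run_trace


class TestTwinPhenotypes:
    def test_unique_environment_only_gives_independence(self):
        tab = generate_twin_phenotypes(5000, 5000, 0.0, 0.0, 1.0, seed=1)
        assert abs(np.corrcoef(tab.mz.T)[0, 1]) < 0.05
        assert abs(np.corrcoef(tab.dz.T)[0, 1]) < 0.05

    def test_pure_shared_environment_duplicates_twins(self):
        tab = generate_twin_phenotypes(50, 50, 0.0, 1.0, 0.0, seed=2)
        np.testing.assert_allclose(tab.mz[:, 0], tab.mz[:, 1])
        np.testing.assert_allclose(tab.dz[:, 0], tab.dz[:, 1])

    def test_implied_correlations_at_large_n(self):
        # three MC standard errors at n = 1e4: ~0.02
        tab = generate_twin_phenotypes(10000, 10000, 0.65, 0.0, 0.35, seed=3)
        assert np.corrcoef(tab.mz.T)[0, 1] == pytest.approx(0.65, abs=0.02)
        assert np.corrcoef(tab.dz.T)[0, 1] == pytest.approx(0.325, abs=0.02)

    def test_mean_and_variance_respected(self):
        tab = generate_twin_phenotypes(20000, 1000, 0.3, 0.3, 0.4,
                                       mu=5.0, total_var=4.0, seed=4)
        vals = tab.values()
        assert vals.mean() == pytest.approx(5.0, abs=0.05)
        assert vals.var() == pytest.approx(4.0, rel=0.05)

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValidationError):
            generate_twin_phenotypes(10, 10, 0.5, 0.5, 0.5)
        with pytest.raises(ValidationError):
            generate_twin_phenotypes(10, 10, -0.1, 0.4, 0.7)


class TestRunTraces:
    def test_zero_scale_gives_zero_trace(self, rng):
        run = default_protocol().runs[0]
        t = generate_run_trace(rng, run, 0.0, MotionModel())
        assert not t.translations.any() and not t.rotations.any()

    def test_doubling_scale_doubles_fd(self):
        run = default_protocol().runs[0]
        m = MotionModel()
        t1 = generate_run_trace(np.random.default_rng(7), run, 1.0, m)
        t2 = generate_run_trace(np.random.default_rng(7), run, 2.0, m)
        np.testing.assert_allclose(
            framewise_displacement(t2), 2.0 * framewise_displacement(t1), rtol=1e-9
        )

    def test_volume_count_matches_protocol(self, rng):
        for run in default_protocol().runs:
            if run.modality in ("task_fmri", "rs_fmri"):
                t = generate_run_trace(rng, run, 1.0, MotionModel())
                assert t.n_volumes == run.nominal_volumes

    def test_later_runs_move_more_on_average(self):
        """The within-session amplitude slope raises FD for later runs."""
        cfg = CohortConfig(n_pairs=60)
        sim = generate_cohort(cfg, seed=13)
        fd = {"snat1": [], "rs": []}
        for (sid, lab), trace in sim.traces.items():
            if lab in fd:
                fd[lab].append(framewise_displacement(trace).mean())
        assert len(fd["rs"]) >= 80
        assert np.mean(fd["rs"]) > np.mean(fd["snat1"])


class TestCohortGeneration:
    def test_mz_count_rounding(self):
        cfg = CohortConfig(n_pairs=256, prop_mz=0.55)
        assert cfg.n_mz_pairs == 141  # 140.8 rounds half-up to 141
        sim = generate_cohort(CohortConfig(n_pairs=20, prop_mz=0.55), seed=0)
        assert sum(r.zygosity == "MZ" for r in sim.cohort.records) == 22

    def test_same_seed_reproduces_files_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_pairs=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(cfg, seed=42, out_dir=d1)
        generate_cohort(cfg, seed=42, out_dir=d2)
        assert (d1 / "cohort.tsv").read_bytes() == (d2 / "cohort.tsv").read_bytes()
        pars1 = sorted(p.name for p in (d1 / "par").iterdir())
        pars2 = sorted(p.name for p in (d2 / "par").iterdir())
        assert pars1 == pars2 and pars1
        for name in pars1:
            assert (d1 / "par" / name).read_bytes() == (d2 / "par" / name).read_bytes()

    def test_different_seed_differs(self, tmp_path):
        cfg = CohortConfig(n_pairs=5)
        a = generate_cohort(cfg, seed=1)
        b = generate_cohort(cfg, seed=2)
        assert not cohort_to_frame(a.cohort).equals(cohort_to_frame(b.cohort))

    def test_round_trip_through_cohort_reader(self, tmp_path):
        sim = generate_cohort(CohortConfig(n_pairs=6), seed=9, out_dir=tmp_path)
        back = read_cohort_table(tmp_path / "cohort.tsv")
        assert len(back) == len(sim.cohort)
        for orig, re in zip(sim.cohort.records, back.records):
            assert orig.subject_id == re.subject_id
            assert orig.zygosity == re.zygosity
            assert orig.completed == re.completed
            assert orig.rating_t1 == re.rating_t1
            for key, val in orig.distress.items():
                assert re.distress[key] == pytest.approx(val, abs=1e-4)

    def test_par_files_parse_back(self, tmp_path):
        sim = generate_cohort(CohortConfig(n_pairs=3), seed=9, out_dir=tmp_path)
        (sid, lab), trace = next(iter(sim.traces.items()))
        back = read_motion_par(tmp_path / "par" / f"{sid}_{lab}.par")
        np.testing.assert_allclose(back.translations, trace.translations, rtol=1e-4, atol=1e-7)


class TestDistressAndAttrition:
    @pytest.fixture(scope="class")
    def big_cohort(self):
        return generate_cohort(CohortConfig(n_pairs=300), seed=21)

    def _frame(self, sim):
        return cohort_to_frame(sim.cohort)

    def test_tension_falls_and_excitement_rises(self, big_cohort):
        df = self._frame(big_cohort)
        tension = [df[distress_column("tension", "child", tp)].mean()
                   for tp in ("pre_sim", "pre_mri", "post_mri")]
        excite = [df[distress_column("excitement", "child", tp)].mean()
                  for tp in ("pre_sim", "pre_mri", "post_mri")]
        assert tension[0] > tension[1] > tension[2]
        assert excite[1] > excite[0] and excite[2] > excite[0]

    def test_distress_quantity_sign_structure(self, big_cohort):
        df = self._frame(big_cohort)
        quantity = df[[f"completed_{lab}" for lab in default_protocol().run_labels]].sum(axis=1)
        r_exc = np.corrcoef(df[distress_column("excitement", "child", "pre_mri")], quantity)[0, 1]
        r_ten = np.corrcoef(df[distress_column("tension", "child", "pre_mri")], quantity)[0, 1]
        assert r_exc > 0
        assert r_ten < 0

    def test_raters_track_child_scores(self, big_cohort):
        df = self._frame(big_cohort)
        col = distress_column("tension", "child", "pre_mri")
        col_r = distress_column("tension", "researcher", "pre_mri")
        assert np.corrcoef(df[col], df[col_r])[0, 1] > 0.5

    def test_no_parent_rating_after_scan(self, big_cohort):
        rec = big_cohort.cohort.records[0]
        assert distress_column("tension", "parent", "post_mri") not in rec.distress
        assert distress_column("tension", "parent", "pre_mri") in rec.distress

    def test_zero_hazards_complete_everything(self):
        cfg = CohortConfig(
            n_pairs=30,
            attrition=AttritionModel(never_start_prob=0.0, base_hazard=0.0,
                                     post_t1_hazard=0.0, tension_effect=0.0),
        )
        sim = generate_cohort(cfg, seed=5)
        for rec in sim.cohort.records:
            assert all(rec.completed.values()) and len(rec.completed) == 9

    def test_no_tension_effect_decouples_completion(self):
        cfg = CohortConfig(
            n_pairs=400,
            attrition=AttritionModel(never_start_prob=0.05, base_hazard=0.02,
                                     post_t1_hazard=0.08, tension_effect=0.0),
        )
        sim = generate_cohort(cfg, seed=6)
        df = cohort_to_frame(sim.cohort)
        quantity = df[[f"completed_{lab}" for lab in default_protocol().run_labels]].sum(axis=1)
        r = np.corrcoef(df[distress_column("tension", "child", "pre_mri")], quantity)[0, 1]
        assert abs(r) < 0.1

    def test_zygosity_blind_mechanics_without_genetics(self):
        """With a2 = 0, MZ and DZ within-pair differences are exchangeable."""
        cfg = CohortConfig(
            n_pairs=400,
            motion=MotionModel(a2=0.0, c2=0.65, e2=0.35),
        )
        sim = generate_cohort(cfg, seed=8)
        diffs = {"MZ": [], "DZ": []}
        for i in range(cfg.n_pairs):
            pid = f"P{i + 1:04d}"
            zyg = "MZ" if i < cfg.n_mz_pairs else "DZ"
            diffs[zyg].append(
                abs(sim.propensities[f"{pid}T1"] - sim.propensities[f"{pid}T2"])
            )
        _, p = stats.ks_2samp(diffs["MZ"], diffs["DZ"])
        assert p > 0.01
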