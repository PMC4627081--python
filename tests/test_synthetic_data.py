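from collections import Counter

import numpy as np
import pytest
from scipy import stats

from dnadistort import io_formats as iof
from dnadistort import synthetic_data as sd
from dnadistort import trajectory_stats as ts
from dnadistort.hbond_quality import ih_series


class TestMutationTable:
    def test_reproducible_from_seed(self):
        cfg = sd.MutationSimConfig(seed=5)
        assert sd.gen_mutation_table(cfg) == sd.gen_mutation_table(cfg)

    def test_zero_mutations_gives_empty_table(self):
        assert sd.gen_mutation_table(sd.MutationSimConfig(m_total=0)) == []

    def test_total_count_preserved(self):
        records = sd.gen_mutation_table(sd.MutationSimConfig(seed=1))
        assert len(records) == 421

    def test_unknown_enriched_site_rejected(self):
        with pytest.raises(ValueError, match="unknown site"):
            sd.gen_mutation_table(sd.MutationSimConfig(enriched={"bogus": 5.0}))

    def test_enrichment_below_one_rejected(self):
        key = sd.MutationSimConfig().site_keys()[0]
        with pytest.raises(ValueError, match="factor"):
            sd.MutationSimConfig(enriched={key: 0.5}).validate()

    def test_flat_allocation_consistent_with_uniform_null(self):
        # chi-square goodness of fit against the uniform multinomial;
        # non-rejection at 5% in at least 90 of 100 seeds
        keys = sd.MutationSimConfig().site_keys()
        index = {k: i for i, k in enumerate(keys)}
        non_rejections = 0
        for seed in range(100):
            records = sd.gen_mutation_table(sd.MutationSimConfig(seed=seed))
            counts = np.zeros(len(keys))
            for r in records:
                counts[index[r.site_key]] += 1
            non_rejections += stats.chisquare(counts).pvalue >= 0.05
        assert non_rejections >= 90

    def test_planted_enriched_sites_have_largest_counts(self):
        keys = sd.MutationSimConfig().site_keys()
        planted = set(keys[:3])
        hits = 0
        for seed in range(30):
            cfg = sd.MutationSimConfig(enriched={k: 20.0 for k in planted}, seed=seed)
            counter = Counter(r.site_key for r in sd.gen_mutation_table(cfg))
            top3 = {k for k, _ in counter.most_common(3)}
            hits += top3 == planted
        assert hits >= 29

    def test_enriched_sites_use_panel_contexts(self, panel):
        keys = sd.MutationSimConfig().site_keys()
        cfg = sd.MutationSimConfig(enriched={keys[0]: 50.0}, seed=2)
        records = [r for r in sd.gen_mutation_table(cfg) if r.site_key == keys[0]]
        fx = panel[0]
        c5, _, c3 = fx.adduct_context
        assert all((r.context5, r.context3) == (c5, c3) for r in records)
        assert all(r.ref == "G" and r.alt == "T" for r in records)


class TestHelicalTrajectory:
    def test_frame_accounting_matches_protocol(self):
        cfg = sd.TrajectorySimConfig(seed=0)
        assert cfg.n_frames() == 5001
        series = sd.gen_helical_trajectory(
            sd.TrajectorySimConfig(t_total=1000.0, seed=0), adducted=False
        )["twist"]
        assert series.n_frames == 501

    def test_seventeen_parameters_with_correct_widths(self):
        out = sd.gen_helical_trajectory(
            sd.TrajectorySimConfig(t_total=100.0), adducted=False
        )
        assert set(out) == iof.PARAMETER_NAMES
        assert out["buckle"].n_levels == 11   # intra-base-pair
        assert out["twist"].n_levels == 10    # step
        assert out["xdisp"].n_levels == 11    # axis

    def test_zero_noise_gives_exact_target_medians(self):
        cfg = sd.TrajectorySimConfig(
            t_total=20.0, iqrs={n: 0.0 for n in iof.PARAMETER_NAMES}
        )
        out = sd.gen_helical_trajectory(cfg, adducted=False)
        for name, series in out.items():
            expected = cfg.medians.get(name, 0.0)
            np.testing.assert_array_equal(series.values, expected)

    def test_adduct_effect_shifts_and_flips(self):
        cfg = sd.TrajectorySimConfig(
            t_total=20.0, iqrs={n: 0.0 for n in iof.PARAMETER_NAMES}
        )
        out = sd.gen_helical_trajectory(cfg, adducted=True)
        buckle = out["buckle"].values[0]
        base = cfg.medians["buckle"]
        # level 5: sign flip then rotation shift; level 6: shift only
        assert buckle[4] == -base + cfg.rotation_shift
        assert buckle[5] == base + cfg.rotation_shift
        assert buckle[1] == base
        shear = out["shear"].values[0]
        assert shear[4] == cfg.medians["shear"] + cfg.translation_shift

    def test_nonstationary_ar1_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            sd.gen_helical_trajectory(sd.TrajectorySimConfig(ar1=1.0), adducted=False)

    def test_roundtrip_through_ser_files(self, tmp_path):
        out = sd.gen_helical_trajectory(
            sd.TrajectorySimConfig(t_total=50.0, seed=3), adducted=True
        )
        for name in ("buckle", "twist"):
            path = tmp_path / f"{name}.ser"
            iof.write_ser(out[name], path)
            back = iof.read_ser(path)
            np.testing.assert_array_equal(back.values, out[name].values)


class TestBondGeometry:
    def test_zero_perturbation_gives_zero_index_every_frame(self):
        series = sd.gen_bond_geometry(n_frames=10)
        np.testing.assert_array_equal(ih_series(series).values, np.zeros(10))

    def test_single_bond_shift_gives_exact_index(self):
        series = sd.gen_bond_geometry(distance_shift=(0.1, 0, 0), n_frames=7)
        np.testing.assert_allclose(ih_series(series).values, 0.01, atol=1e-12)

    def test_angles_clipped_to_valid_range(self):
        series = sd.gen_bond_geometry(angle_sd=60.0, n_frames=500, seed=1)
        assert series.angles.max() <= 180.0 and series.angles.min() >= 0.0

    def test_reproducible_and_roundtrips(self, tmp_path):
        a = sd.gen_bond_geometry(distance_sd=0.1, angle_sd=5, n_frames=20, seed=9)
        b = sd.gen_bond_geometry(distance_sd=0.1, angle_sd=5, n_frames=20, seed=9)
        np.testing.assert_array_equal(a.distances, b.distances)
        path = tmp_path / "g.tsv"
        iof.write_geometry(a, path)
        back = iof.read_geometry(path)
        np.testing.assert_array_equal(back.angles, a.angles)


class TestRmsdSeries:
    def test_zero_sd_gives_step_function(self):
        series = sd.gen_rmsd_series(
            [(0.0, 300.0, 0.18, 0.0), (300.0, 1000.0, 0.26, 0.0)], dt=2.0
        )
        early = series.values[series.times < 300]
        late = series.values[series.times >= 300]
        assert set(np.unique(early)) == {0.18}
        assert set(np.unique(late)) == {0.26}

    def test_single_window_constant_mean(self):
        series = sd.gen_rmsd_series([(0.0, 100.0, 0.2, 0.0)], dt=2.0)
        assert np.all(series.values == 0.2) and series.times[-1] == 100.0

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sd.gen_rmsd_series([(0.0, 300.0, 0.18, 0.0), (200.0, 500.0, 0.2, 0.0)])

    def test_gapped_windows_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            sd.gen_rmsd_series([(0.0, 300.0, 0.18, 0.0), (400.0, 500.0, 0.2, 0.0)])

    def test_two_plateau_config_recovered_by_windowed_stats(self):
        means = {(0.0, 300.0): 0.18, (300.0, 10000.0): 0.26}
        per_window = {w: [] for w in means}
        for seed in range(50):
            series = sd.gen_rmsd_series(
                [(0.0, 300.0, 0.18, 0.02), (300.0, 10000.0, 0.26, 0.03)],
                dt=2.0, seed=seed,
            )
            for w in ts.windowed_stats(series, list(means)):
                per_window[(w.t0, w.t1)].append(w.mean)
        for window, estimates in per_window.items():
            est = np.asarray(estimates)
            se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - means[window]) <= 3 * se + 1e-12

    def test_roundtrip_through_xvg(self, tmp_path):
        series = sd.gen_rmsd_series([(0.0, 100.0, 0.2, 0.02)], dt=2.0, seed=4)
        path = tmp_path / "r.xvg"
        iof.write_xvg(series, path)
        back = iof.read_xvg(path)
        np.testing.assert_array_equal(back.values, series.values)


class TestMfaPanel:
    def test_shapes_and_labels(self):
        groups, labels = sd.gen_mfa_panel(seed=0)
        assert len(groups) == 17
        assert labels.sum() == 11 and labels.size == 22
        widths = {g.name: g.matrix.shape[1] for g in groups}
        assert widths["buckle"] == 9 and widths["twist"] == 8

    def test_reproducible(self):
        a, _ = sd.gen_mfa_panel(seed=3)
        b, _ = sd.gen_mfa_panel(seed=3)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.matrix, gb.matrix)


class TestSignatureRecords:
    def test_weighted_channel_dominates(self):
        records = sd.gen_signature_records(500, {("ACG", "C>A"): 96.0}, seed=0)
        from dnadistort.signature_builder import to_pyrimidine_channel

        hits = sum(
            to_pyrimidine_channel(r.context5, r.ref, r.context3, r.alt)
            == ("ACG", "C>A")
            for r in records
        )
        assert hits > 200

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            sd.gen_signature_records(5, {("XXX", "C>A"): 2.0})
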