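import json

import numpy as np
import pytest

from smdiv import chemdiv, effective_sm, incidence, richness, synthetic
from smdiv.synthetic import (
    RATIO_TARGET,
    SINGLETON_TARGET,
    IncidenceModel,
    calibrate_duplication,
    calibrate_occupancy,
    gen_bgc_sm_table,
    gen_fingerprints,
    gen_incidence,
    gen_incidence_homogeneous,
    write_dataset,
)


class TestCalibration:
    def test_closed_loop_singleton_fraction(self):
        # realized singleton fraction of a large draw sits near the target
        alpha = calibrate_occupancy(135)
        model = IncidenceModel(T=135, s_true=4000, occupancy_alpha=alpha,
                               duplication_rate=0.0, seed=5)
        _, _, truth = gen_incidence(model)
        assert truth.singleton_fraction == pytest.approx(SINGLETON_TARGET, abs=0.03)

    def test_alpha_monotone_in_target(self):
        a_low = calibrate_occupancy(50, 0.6)
        a_high = calibrate_occupancy(50, 0.9)
        assert a_high > a_low

    def test_small_T_extreme_target_gives_large_alpha(self):
        assert calibrate_occupancy(2, 0.999) > 5

    def test_unattainable_target_reports_feasible_range(self):
        with pytest.raises(ValueError, match="feasible range"):
            calibrate_occupancy(10, 0.05)  # below the uniform floor 1/T
        with pytest.raises(ValueError):
            calibrate_occupancy(10, 1.5)

    def test_duplication_rate_closed_form(self):
        alpha = calibrate_occupancy(135)
        lam = calibrate_duplication(alpha, 135)
        from scipy.stats import zipfian
        ey = zipfian.mean(alpha, 135)
        assert 1.0 / (ey * (1 + lam)) == pytest.approx(RATIO_TARGET, abs=1e-12)

    def test_unattainable_ratio_rejected(self):
        alpha = calibrate_occupancy(135)
        with pytest.raises(ValueError, match="unattainable"):
            calibrate_duplication(alpha, 135, target_ratio=0.99)


class TestGenIncidence:
    def test_seed_determinism(self):
        m = IncidenceModel(T=25, s_true=150, seed=42)
        r1 = gen_incidence(m)
        r2 = gen_incidence(m)
        assert [x.bgc_id for x in r1[0]] == [x.bgc_id for x in r2[0]]
        assert np.array_equal(r1[1].cells, r2[1].cells)
        assert r1[2] == r2[2]

    def test_no_duplication_means_counts_match_occupancy(self):
        m = IncidenceModel(T=30, s_true=200, duplication_rate=0.0, seed=1)
        records, matrix, truth = gen_incidence(m)
        assert len(records) == int(matrix.cells.sum())
        assert truth.n_bgcs == len(records)

    def test_ground_truth_matches_reanalysis(self):
        records, matrix, truth = gen_incidence(IncidenceModel(T=20, s_true=120, seed=8))
        summary = incidence.summarize(records, matrix)
        freqs = richness.frequencies(matrix)
        assert summary.n_bgcs == truth.n_bgcs
        assert summary.n_gcfs == truth.S_obs == freqs.S_obs
        assert (freqs.Q1, freqs.Q2) == (truth.Q1, truth.Q2)
        assert summary.singleton_count == truth.Q1

    def test_contig_edge_bookkeeping(self):
        m = IncidenceModel(T=20, s_true=300, contig_edge_prob=0.2, seed=3)
        records, _, truth = gen_incidence(m)
        kept = incidence.filter_bgcs(records, drop_contig_edge=True)
        assert len(kept) == len(records) - truth.n_contig_edge
        assert truth.n_contig_edge / len(records) == pytest.approx(0.2, abs=0.05)

    def test_default_model_calibration_over_seeds(self):
        # averaged over a handful of seeds the defaults hit both study targets
        sf, ratio = [], []
        for seed in range(5):
            _, _, truth = gen_incidence(IncidenceModel(seed=seed))
            sf.append(truth.singleton_fraction)
            ratio.append(truth.gcf_bgc_ratio)
        assert np.mean(sf) == pytest.approx(SINGLETON_TARGET, abs=0.05)
        assert np.mean(ratio) == pytest.approx(RATIO_TARGET, abs=0.05)


class TestGenIncidenceHomogeneous:
    def test_undetected_families_exist(self):
        matrix, truth = gen_incidence_homogeneous(40, 300, 0.05, seed=2)
        assert truth.S_obs < truth.s_true
        assert matrix.n_gcfs == truth.S_obs

    def test_determinism(self):
        a = gen_incidence_homogeneous(30, 100, 0.1, seed=9)
        b = gen_incidence_homogeneous(30, 100, 0.1, seed=9)
        assert np.array_equal(a[0].cells, b[0].cells) and a[1] == b[1]

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            gen_incidence_homogeneous(10, 50, 0.0, seed=0)


class TestGenBgcSmTable:
    def test_no_sharing_means_no_down_weighting(self):
        t, truth = gen_bgc_sm_table(80, mean_sms_per_bgc=1.5, sharing_prob=0.0, seed=4)
        r = effective_sm.effective_sm_per_bgc(t)
        assert r.mean_effective == pytest.approx(len(t.links) / r.n_bgcs)
        assert set(truth.sm_multiplicity.values()) == {1}

    def test_full_sharing_single_sm_bgcs(self):
        t, _ = gen_bgc_sm_table(50, mean_sms_per_bgc=1.0, sharing_prob=1.0, seed=4)
        r = effective_sm.effective_sm_per_bgc(t)
        assert r.n_distinct_sms == 1
        assert r.mean_effective == pytest.approx(1 / 50)

    def test_identity_against_ground_truth(self):
        t, truth = gen_bgc_sm_table(120, mean_sms_per_bgc=1.7, sharing_prob=0.35, seed=11)
        r = effective_sm.effective_sm_per_bgc(t)
        assert r.n_distinct_sms == truth.n_distinct_sms
        assert r.mean_effective == pytest.approx(truth.n_distinct_sms / 120)
        assert effective_sm.sm_multiplicity(t) == truth.sm_multiplicity

    def test_determinism(self):
        assert gen_bgc_sm_table(30, 1.6, 0.2, seed=7)[0] == \
            gen_bgc_sm_table(30, 1.6, 0.2, seed=7)[0]


class TestGenFingerprints:
    def test_single_family_full_overlap_is_homogeneous(self):
        fps, _ = gen_fingerprints(1, 6, bits_per_fp=64, within_family_overlap=1.0, seed=1)
        assert chemdiv.diversity(fps).d == 0.0

    def test_diversity_grows_with_family_count(self):
        ds = []
        for n_fam in (1, 3, 6):
            fps, _ = gen_fingerprints(n_fam, 6, bits_per_fp=240,
                                      within_family_overlap=1.0, seed=5)
            ds.append(chemdiv.diversity(fps).d)
        assert ds[0] < ds[1] < ds[2]

    def test_within_family_similarity_exceeds_between(self):
        fps, truth = gen_fingerprints(4, 8, bits_per_fp=128,
                                      within_family_overlap=0.7, seed=6)
        fam_of = {cid: f for f, members in truth.fingerprint_families.items()
                  for cid in members}
        within, between = [], []
        for i in range(fps.n):
            for j in range(i + 1, fps.n):
                s = chemdiv.tanimoto(fps.bits[i], fps.bits[j])
                (within if fam_of[fps.ids[i]] == fam_of[fps.ids[j]] else between).append(s)
        assert np.mean(within) > np.mean(between)

    def test_determinism(self):
        a, _ = gen_fingerprints(3, 4, seed=2)
        b, _ = gen_fingerprints(3, 4, seed=2)
        assert np.array_equal(a.bits, b.bits)


class TestWriteDataset:
    def test_emitted_files_reproduce_ground_truth(self, tmp_path):
        model = IncidenceModel(T=15, s_true=80, seed=13)
        paths = write_dataset(tmp_path, model, sm_kwargs={"n_bgcs": 40})
        truth = json.loads(paths["ground_truth"].read_text())

        records = incidence.read_clustering_table(paths["clustering"],
                                                  metadata=paths["metadata"])
        matrix = incidence.build_incidence(records)
        summary = incidence.summarize(records, matrix)
        assert summary.n_bgcs == truth["n_bgcs"]
        assert summary.n_gcfs == truth["S_obs"]
        assert summary.singleton_count == truth["Q1"]

        disk_matrix = incidence.IncidenceMatrix.read_tsv(paths["incidence"])
        assert np.array_equal(disk_matrix.cells, matrix.cells)

        table = effective_sm.read_links(paths["links"])
        r = effective_sm.effective_sm_per_bgc(table)
        assert r.n_distinct_sms == truth["n_distinct_sms"]
        assert effective_sm.sm_multiplicity(table) == truth["sm_multiplicity"]

        fps = chemdiv.FingerprintSet.read_tsv(paths["fingerprints"])
        families = truth["fingerprint_families"]
        assert sorted(fps.ids) == sorted(cid for fam in families.values() for cid in fam)
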