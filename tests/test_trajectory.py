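import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, strategies as st
from sklearn.metrics import adjusted_rand_score

from glomscape.exceptions import DegenerateInputError, ValidationError
from glomscape.synthetic import truth_labeling
from glomscape.trajectory import (
    CrescentTrajectory,
    cluster_rois,
    compute_pseudotime,
    correlate_with_clinical,
    de_between_clusters,
    jenks_breaks,
    median_pc1_per_patient,
    pseudobulk_rois,
    quadrant_breaks,
)


@pytest.fixture(scope="module")
def roi_profiles(default_cohort):
    _, table, truth = default_cohort
    lab = truth_labeling(truth)
    raw, norm, meta = pseudobulk_rois(table, lab)
    return table, truth, raw, norm, meta


class TestPseudobulk:
    def test_two_cell_additivity(self, small_cohort):
        _, table, truth = small_cohort
        lab = truth_labeling(truth)
        raw, _, _ = pseudobulk_rois(table, lab)
        roi0 = raw.index[0]
        rows = np.flatnonzero(lab.roi_id == roi0)
        manual = np.asarray(table.counts[rows].sum(axis=0)).ravel()
        np.testing.assert_array_equal(raw.loc[roi0].to_numpy(), manual)

    def test_total_count_conservation(self, small_cohort):
        _, table, truth = small_cohort
        lab = truth_labeling(truth)
        raw, _, _ = pseudobulk_rois(table, lab)
        member = lab.roi_id >= 0
        assert raw.to_numpy().sum() == table.counts[np.flatnonzero(member)].sum()

    def test_normalized_rows_sum_to_ten_thousand(self, roi_profiles):
        _, _, _, norm, _ = roi_profiles
        sums = np.expm1(norm.to_numpy()).sum(axis=1)
        np.testing.assert_allclose(sums, 10000.0, atol=1e-4)


class TestCrescentTrajectory:
    def test_pc1_tracks_latent_severity(self, roi_profiles):
        _, truth, _, norm, meta = roi_profiles
        traj = CrescentTrajectory().fit(norm, meta["condition"])
        sev = truth.rois["severity"].reindex(meta.index)
        rho = scipy.stats.spearmanr(traj.pc1_, sev).statistic
        assert rho >= 0.8

    def test_orientation_control_below_disease(self, roi_profiles):
        _, _, _, norm, meta = roi_profiles
        traj = CrescentTrajectory().fit(norm, meta["condition"])
        ctrl = (meta["condition"] == "control").to_numpy()
        assert np.median(traj.pc1_[ctrl]) <= np.median(traj.pc1_[~ctrl])

    def test_duplicating_rois_preserves_pc1(self, roi_profiles):
        _, _, _, norm, meta = roi_profiles
        traj1 = CrescentTrajectory().fit(norm, meta["condition"])
        doubled = pd.concat([norm, norm])
        conds = np.concatenate([meta["condition"], meta["condition"]])
        traj2 = CrescentTrajectory().fit(doubled, conds)
        n = len(norm)
        # same PC1 per original ROI up to a global scale
        ratio = traj2.pc1_[:n] / np.where(traj1.pc1_ == 0, 1, traj1.pc1_)
        corr = np.corrcoef(traj1.pc1_, traj2.pc1_[:n])[0, 1]
        assert abs(corr) > 0.9999
        np.testing.assert_allclose(traj2.pc1_[:n], traj2.pc1_[n:], atol=1e-8)

    def test_degenerate_matrix_rejected(self):
        X = np.ones((5, 4))
        with pytest.raises(DegenerateInputError):
            CrescentTrajectory().fit(X, ["control", "control", "SLE", "SLE", "SLE"])


class TestClusterROIs:
    def test_three_blobs_elbow_and_membership(self):
        rng = np.random.default_rng(0)
        blobs = [rng.normal(c, 0.3, size=(30, 2)) for c in ([0, 0], [10, 0], [0, 10])]
        X = np.vstack(blobs)
        truth = np.repeat([0, 1, 2], 30)
        conds = np.array(["SLE"] * 90, dtype=object)  # no control merge
        labels = cluster_rois(X, conds, seed=0)
        assert pd.Series(labels).nunique() == 3
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_control_dominated_clusters_merge(self):
        rng = np.random.default_rng(1)
        blobs = [rng.normal(c, 0.3, size=(30, 2)) for c in ([0, 0], [5, 0], [20, 0])]
        X = np.vstack(blobs)
        conds = np.array(["control"] * 60 + ["anti-GBM"] * 30, dtype=object)
        labels = cluster_rois(X, conds, seed=0)
        # both control blobs collapse into C1 (lowest PC1)
        assert pd.Series(labels).nunique() == 2
        assert (labels[:60] == "C1").all()

    def test_cluster_names_ordered_by_median_pc1(self, roi_profiles):
        _, _, _, norm, meta = roi_profiles
        traj = CrescentTrajectory().fit(norm, meta["condition"])
        labels = cluster_rois(traj.pc_, meta["condition"].to_numpy(), seed=0)
        meds = pd.Series(traj.pc1_).groupby(pd.Series(labels)).median()
        assert list(meds.sort_index().index) == sorted(meds.index)
        assert meds.sort_index().is_monotonic_increasing

    def test_few_rois_lowers_kmax_with_warning(self):
        X = np.random.default_rng(2).normal(size=(6, 2))
        conds = np.array(["SLE"] * 6, dtype=object)
        with pytest.warns(UserWarning, match="lowering k_max"):
            cluster_rois(X, conds, k_max=10, seed=0)


class TestPseudotime:
    def test_root_has_pseudotime_zero_and_unit_range(self, roi_profiles):
        _, _, _, norm, meta = roi_profiles
        pt = compute_pseudotime(norm, meta["condition"].to_numpy(), seed=5)
        assert pt.min() == 0.0 and pt.max() == 1.0
        ctrl = np.flatnonzero(meta["condition"].to_numpy() == "control")
        root = int(np.random.default_rng(5).choice(ctrl))
        assert pt[root] == 0.0

    def test_correlates_with_pc1(self, roi_profiles):
        _, _, _, norm, meta = roi_profiles
        traj = CrescentTrajectory().fit(norm, meta["condition"])
        pt = compute_pseudotime(norm, meta["condition"].to_numpy(), seed=5)
        assert scipy.stats.spearmanr(traj.pc1_, pt).statistic >= 0.7

    def test_stable_across_control_roots(self, roi_profiles):
        _, _, _, norm, meta = roi_profiles
        pt1 = compute_pseudotime(norm, meta["condition"].to_numpy(), seed=5)
        pt2 = compute_pseudotime(norm, meta["condition"].to_numpy(), seed=17)
        assert scipy.stats.spearmanr(pt1, pt2).statistic >= 0.9

    def test_no_control_root_is_an_error(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValidationError):
            compute_pseudotime(X, np.array(["SLE"] * 10), seed=0)


def _brute_force_jenks(values, k):
    """Exhaustive search over all ordered break placements."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    best, best_cuts = np.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = (0,) + cuts + (n,)
        ssd = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            seg = x[a:b]
            ssd += ((seg - seg.mean()) ** 2).sum()
        if ssd < best - 1e-12:
            best, best_cuts = ssd, edges
    return best, best_cuts, x


class TestJenks:
    def test_four_triplet_groups_split_exactly(self):
        vals = [1, 2, 3, 11, 12, 13, 21, 22, 23, 31, 32, 33]
        labels = quadrant_breaks(vals)
        assert list(labels) == ["Q1"] * 3 + ["Q2"] * 3 + ["Q3"] * 3 + ["Q4"] * 3

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=6,
                    max_size=14).filter(lambda v: len(set(v)) >= 4))
    def test_matches_exhaustive_enumeration(self, vals):
        breaks = jenks_breaks(vals, 4)
        x = np.sort(np.asarray(vals, dtype=float))
        edges = np.asarray(breaks[1:-1])
        classes = np.searchsorted(edges, x, side="left")
        ssd = sum(((x[classes == c] - x[classes == c].mean()) ** 2).sum()
                  for c in np.unique(classes))
        best, _, _ = _brute_force_jenks(vals, 4)
        assert ssd <= best + 1e-9

    def test_affine_transform_preserves_classes(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, size=20)
        l1 = quadrant_breaks(vals)
        l2 = quadrant_breaks(3.5 * vals + 11.0)
        np.testing.assert_array_equal(l1, l2)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            quadrant_breaks(np.ones(10))


class TestClinicalCorrelation:
    def test_egfr_inversely_correlated_with_severity_proxy(self, roi_profiles):
        _, truth, _, norm, meta = roi_profiles
        from glomscape.synthetic import generate_clinical

        traj = CrescentTrajectory().fit(norm, meta["condition"])
        med = median_pc1_per_patient(traj.pc1_, meta)
        clinical = generate_clinical(truth, seed=0)
        out = correlate_with_clinical(med, clinical)
        assert out.loc["eGFR", "rho"] < 0
        assert out.loc["albuminuria", "rho"] > 0

    def test_perfect_monotone_pair(self):
        med = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                        index=[f"p{i}" for i in range(5)])
        clin = pd.DataFrame({"eGFR": [10, 20, 30, 40, 50]}, index=med.index)
        out = correlate_with_clinical(med, clin, covariates=("eGFR",))
        assert out.loc["eGFR", "rho"] == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.normal(size=8), index=[f"p{i}" for i in range(8)])
        b = pd.DataFrame({"eGFR": rng.normal(size=8) + 50}, index=a.index)
        r1 = correlate_with_clinical(a, b, covariates=("eGFR",)).loc["eGFR", "rho"]
        swapped = correlate_with_clinical(
            b["eGFR"], pd.DataFrame({"eGFR": a}), covariates=("eGFR",))
        assert np.isclose(r1, swapped.loc["eGFR", "rho"])

    def test_constant_covariate_flagged(self):
        med = pd.Series(np.arange(6.0), index=[f"p{i}" for i in range(6)])
        clin = pd.DataFrame({"age": [50] * 6}, index=med.index)
        out = correlate_with_clinical(med, clin, covariates=("age",))
        assert out.loc["age", "flag"] == "undefined"
        assert np.isnan(out.loc["age", "rho"])

    def test_anca_risk_ordinal_encoding(self):
        med = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                        index=[f"p{i}" for i in range(6)])
        clin = pd.DataFrame(
            {"anca_risk": ["low", "low", "medium", "medium", "high", "high"]},
            index=med.index)
        out = correlate_with_clinical(med, clin, covariates=("anca_risk",))
        assert out.loc["anca_risk", "rho"] > 0.8


def _de_fixture(n_per_group=20, n_genes=30, shift_genes=3, shift=2.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    Y = rng.normal(0, 1, size=(n, n_genes))
    groups = np.array(["C1"] * n_per_group + ["C2"] * n_per_group, dtype=object)
    Y[n_per_group:, :shift_genes] += shift
    slides = np.array(["s1", "s2"] * n_per_group, dtype=object)
    cols = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(Y, columns=cols), groups, slides


class TestDifferentialExpression:
    def test_planted_shift_detected(self):
        Y, groups, slides = _de_fixture()
        out = de_between_clusters(Y, groups, slides)
        assert (out.iloc[:3]["q"] < 0.05).all()
        assert (out.iloc[:3]["effect"] > 0).all()

    def test_type_one_error_calibrated_under_permutation(self):
        Y, groups, slides = _de_fixture(shift=0.0, n_genes=40)
        rng = np.random.default_rng(1)
        hits, total = 0, 0
        for _ in range(200):
            perm = rng.permutation(groups)
            out = de_between_clusters(Y, perm, slides)
            hits += (out["p"] < 0.05).sum()
            total += out["p"].notna().sum()
        rate = hits / total
        assert abs(rate - 0.05) <= 0.02

    def test_zero_variance_gene_flagged_and_excluded(self):
        Y, groups, slides = _de_fixture(n_genes=5)
        Y["g4"] = 7.0
        out = de_between_clusters(Y, groups, slides)
        assert out.loc["g4", "flag"] == "zero_variance"
        assert np.isnan(out.loc["g4", "q"])

    def test_confounded_slide_dropped_with_warning(self):
        Y, groups, _ = _de_fixture()
        slides = np.where(groups == "C1", "s1", "s2")
        with pytest.warns(UserWarning, match="confounded"):
            out = de_between_clusters(Y, groups, slides)
        assert out["p"].notna().all()

    def test_small_groups_rejected(self):
        Y, groups, slides = _de_fixture(n_per_group=2)
        with pytest.raises(ValidationError):
            de_between_clusters(Y, groups, slides)
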