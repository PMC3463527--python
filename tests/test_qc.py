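"""Preanalytic QC: KS distance and filters, paired-draw filter, PCA screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mesopanel.data import RfuMatrix
from mesopanel.normalize import calibrate_plates, median_normalize
from mesopanel.qc import (
    QcReport,
    apply_qc,
    filter_ks_control_sets,
    filter_paired_draws,
    ks_distance,
    pca_artifact_screen,
)
from mesopanel.simulate import CohortSpec, generate_cohort, generate_paired_draws

from conftest import make_annotation


def brute_force_ks(x, y):
    """Oracle: evaluate both ECDFs at every pooled point, take the sup."""
    best = 0.0
    for t in list(x) + list(y):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


class TestKsDistance:
    def test_identical_samples(self):
        assert ks_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_fully_separated(self):
        assert ks_distance([1, 2, 3], [4, 5, 6]) == 1.0

    def test_hand_example_against_ecdf_oracle(self):
        x, y = [1, 2, 3, 4], [3, 4, 5, 6]
        assert ks_distance(x, y) == pytest.approx(brute_force_ks(x, y))
        assert ks_distance(x, y) == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_distance([], [1.0])

    # values on a 0.1 grid so the monotone transform below is injective in
    # float arithmetic
    _grid = st.lists(
        st.integers(-500, 500).map(lambda v: v / 10.0), min_size=1, max_size=50
    )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(x=_grid, y=_grid)
    def test_matches_oracle_and_invariances(self, x, y):
        d = ks_distance(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(brute_force_ks(x, y))
        assert d == pytest.approx(ks_distance(y, x))
        # invariant under a joint strictly monotone transform
        f = lambda v: np.exp(np.asarray(v) / 25.0)
        assert d == pytest.approx(ks_distance(f(x), f(y)))


def _two_site_controls(rng, n_per_site, n_analytes, shift=0.0):
    log2 = rng.normal(10, 0.7, size=(2 * n_per_site, n_analytes))
    log2[n_per_site:, :] += shift
    ids = [f"S{i}" for i in range(2 * n_per_site)]
    m = RfuMatrix(pd.DataFrame(np.exp2(log2), index=ids, columns=[f"A{j}" for j in range(n_analytes)]))
    ann = make_annotation(
        [(s, "CONTROL", "SYNTH-S1" if i < n_per_site else "SYNTH-S2",
          "CLINIC", s, "PL1") for i, s in enumerate(ids)]
    )
    return m, ann


class TestKsControlSetFilter:
    def test_null_sites_rarely_excluded(self):
        """Two control sites from the same distribution: exclusions near the
        null rate of P(D > 0.45) at n=30 per site."""
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m, ann = _two_site_controls(rng, n_per_site=30, n_analytes=500)
            rep = filter_ks_control_sets(m, ann)
            fracs.append(len(rep.excluded_analytes) / 500)
        assert np.mean(fracs) <= 0.02

    def test_shifted_analyte_excluded(self):
        rng = np.random.default_rng(1)
        m, ann = _two_site_controls(rng, n_per_site=30, n_analytes=5)
        shifted = m.values.copy()
        shifted.iloc[30:, 0] *= 2.0 ** 2  # +2 log2 site shift on analyte A0
        rep = filter_ks_control_sets(RfuMatrix(shifted), ann)
        assert "A0" in set(rep.excluded_analytes["analyte_id"])
        assert rep.ks_table.set_index("analyte_id").loc["A0", "max_ks_distance"] > 0.9

    def test_threshold_one_excludes_nothing(self):
        rng = np.random.default_rng(2)
        m, ann = _two_site_controls(rng, n_per_site=10, n_analytes=50, shift=5.0)
        rep = filter_ks_control_sets(m, ann, threshold=1.0)
        assert len(rep.excluded_analytes) == 0

    def test_requires_two_eligible_sites(self):
        rng = np.random.default_rng(3)
        m, ann = _two_site_controls(rng, n_per_site=3, n_analytes=5)
        with pytest.raises(ValueError, match="2 control sites"):
            filter_ks_control_sets(m, ann)

    def test_ignores_case_sample_values(self):
        """The filter reads control rows only: perturbing case values leaves
        the report unchanged (no leakage of the discovery contrast)."""
        rng = np.random.default_rng(4)
        m, ann = _two_site_controls(rng, n_per_site=15, n_analytes=30)
        case = make_annotation([("MM1", "CASE", "SYNTH-S1", "PRE_OP", "MM1", "PL1", "II")])
        ann = pd.concat([ann, case], ignore_index=True)
        v1 = m.values.copy()
        v1.loc["MM1"] = 1e6
        v2 = m.values.copy()
        v2.loc["MM1"] = 1.0
        r1 = filter_ks_control_sets(RfuMatrix(v1), ann)
        r2 = filter_ks_control_sets(RfuMatrix(v2), ann)
        pd.testing.assert_frame_equal(r1.ks_table, r2.ks_table)


def _paired(rng, n_subjects, n_analytes, shifted_cols=(), shift=0.0):
    ids, rows, ann_rows = [], [], []
    subj_base = rng.normal(10, 0.7, size=(n_subjects, n_analytes))
    for s in range(n_subjects):
        for draw in ("PRE_OP", "INTRA_OP"):
            row = subj_base[s] + rng.normal(0, 0.5, n_analytes)
            if draw == "INTRA_OP" and len(shifted_cols):
                row = row.copy()
                row[list(shifted_cols)] += shift
            sid = f"P{s}-{draw}"
            ids.append(sid)
            rows.append(row)
            ann_rows.append((sid, "CONTROL", "SYNTH-S1", draw, f"SUBJ{s}", "PL1"))
    m = RfuMatrix(pd.DataFrame(np.exp2(np.vstack(rows)), index=ids,
                               columns=[f"A{j}" for j in range(n_analytes)]))
    return m, make_annotation(ann_rows)


class TestPairedDrawFilter:
    def test_type_i_error_below_alpha(self):
        """On null paired data the joint rule excludes at most alpha."""
        rng = np.random.default_rng(0)
        m, ann = _paired(rng, n_subjects=12, n_analytes=1000)
        rep = filter_paired_draws(m, ann, alpha=0.05, min_abs_log2_shift=0.5)
        assert len(rep.excluded_analytes) / 1000 <= 0.05

    def test_artifact_analytes_excluded(self):
        """1.5-log2 draw shifts are excluded with high sensitivity."""
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m, ann = _paired(rng, 12, 60, shifted_cols=range(20), shift=1.5)
            rep = filter_paired_draws(m, ann)
            hit = set(rep.excluded_analytes["analyte_id"]) & {f"A{j}" for j in range(20)}
            rates.append(len(hit) / 20)
        assert np.mean(rates) >= 0.95

    def test_identical_paired_values_not_excluded(self):
        ids = [f"P{s}-{d}" for s in range(3) for d in ("PRE_OP", "INTRA_OP")]
        vals = pd.DataFrame({"A0": [5.0] * 6}, index=ids)
        ann = make_annotation(
            [(i, "CONTROL", "SYNTH-S1", i.split("-")[1], i.split("-")[0], "PL1") for i in ids]
        )
        rep = filter_paired_draws(RfuMatrix(vals), ann)
        assert len(rep.excluded_analytes) == 0
        row = rep.paired_table.iloc[0]
        assert row["p_value"] == 1.0 and row["median_paired_log2_ratio"] == 0.0

    def test_generator_artifacts_recovered(self):
        """Sensitivity >= 0.9 on true artifacts, false exclusions <= 0.05."""
        sens, fps = [], []
        for seed in range(5):
            spec = CohortSpec(n_analytes=300, seed=seed)
            m, ann = generate_paired_draws(spec)
            truth = generate_cohort(spec)[2]
            rep = filter_paired_draws(m, ann)
            excluded = set(rep.excluded_analytes["analyte_id"])
            art = set(truth.artifact_analyte_ids)
            sens.append(len(excluded & art) / len(art))
            fps.append(len(excluded - art) / (spec.n_analytes - len(art)))
        assert np.median(sens) >= 0.9
        assert np.median(fps) <= 0.05

    def test_requires_paired_subjects(self):
        rng = np.random.default_rng(1)
        m, ann = _paired(rng, 1, 5)
        with pytest.raises(ValueError, match="subjects"):
            filter_paired_draws(m, ann)


class TestPcaScreen:
    def test_degraded_samples_flagged(self):
        """The degraded control subcohort is caught on a site-correlated
        component in at least 18 of 20 seeds."""
        hits = 0
        for seed in range(20):
            spec = CohortSpec(seed=seed)
            m, ann, truth = generate_cohort(spec)
            m = median_normalize(calibrate_plates(m, ann).calibrated).normalized
            study = ann[ann["class_label"].isin(["CASE", "CONTROL"])]
            m = m.subset(samples=list(study["sample_id"]))
            rep = pca_artifact_screen(m, ann, covariates=("site", "plate_id"))
            flagged = set(rep.excluded_samples["sample_id"])
            deg = set(truth.degraded_sample_ids)
            if len(flagged & deg) >= 0.9 * len(deg):
                hits += 1
        assert hits >= 18

    def test_null_cohort_rarely_flags_components(self):
        clean = 0
        for seed in range(20):
            spec = CohortSpec(
                n_analytes=300, effect_size=0.0, weak_effect_size=0.0,
                site_offset_sd=0.0, plate_bias_sd=0.0, degraded_fraction=0.0,
                draw_shift=0.0, seed=seed,
            )
            m, ann, _ = generate_cohort(spec)
            study = ann[ann["class_label"].isin(["CASE", "CONTROL"])]
            m = m.subset(samples=list(study["sample_id"]))
            rep = pca_artifact_screen(m, ann, covariates=("site", "plate_id"))
            if not rep.pca_summary["flagged"].any():
                clean += 1
        assert clean >= 19

    def test_duplicated_samples_flagged_symmetrically(self, rng):
        log2 = rng.normal(10, 0.5, size=(24, 40))
        log2[:6, :10] += 3.0  # artifact block at site B
        log2[1] = log2[0]  # exact duplicates within the artifact group
        ids = [f"S{i}" for i in range(24)]
        m = RfuMatrix(pd.DataFrame(np.exp2(log2), index=ids,
                                   columns=[f"A{j}" for j in range(40)]))
        ann = make_annotation(
            [(s, "CONTROL", "SYNTH-S2" if i < 6 else "SYNTH-S1", "CLINIC", s, "PL1")
             for i, s in enumerate(ids)]
        )
        rep = pca_artifact_screen(m, ann, covariates=("site",))
        flagged = set(rep.excluded_samples["sample_id"])
        assert ("S0" in flagged) == ("S1" in flagged)

    @pytest.mark.parametrize("degraded_fraction", [0.0, 1.0])
    def test_case_samples_not_flagged(self, degraded_fraction):
        """Covariate association is judged on controls, so disease signal is
        never mistaken for an artifact: cases are not flagged for removal."""
        spec = CohortSpec(degraded_fraction=degraded_fraction, seed=5)
        m, ann, truth = generate_cohort(spec)
        m = median_normalize(calibrate_plates(m, ann).calibrated).normalized
        study = ann[ann["class_label"].isin(["CASE", "CONTROL"])]
        m = m.subset(samples=list(study["sample_id"]))
        rep = pca_artifact_screen(m, ann, covariates=("site", "plate_id"))
        flagged = set(rep.excluded_samples["sample_id"])
        cases = set(study.loc[study["class_label"] == "CASE", "sample_id"])
        # isolated >3-MAD outliers are tolerable; the class as a whole never is
        assert len(flagged & cases) <= 0.05 * len(cases)

    def test_constant_matrix_rejected(self):
        m = RfuMatrix(pd.DataFrame(np.full((12, 5), 7.0),
                                   index=[f"S{i}" for i in range(12)],
                                   columns=[f"A{j}" for j in range(5)]))
        ann = make_annotation(
            [(f"S{i}", "CONTROL", "SYNTH-S1", "CLINIC", f"S{i}", "PL1") for i in range(12)]
        )
        with pytest.raises(ValueError, match="degenerate"):
            pca_artifact_screen(m, ann)


class TestApplyQc:
    def test_empty_report_is_identity(self, small_matrix):
        out = apply_qc(small_matrix, QcReport())
        pd.testing.assert_frame_equal(out.values, small_matrix.values)

    def test_excluded_analyte_count(self, small_matrix):
        excl = pd.DataFrame(
            {"analyte_id": [f"A{j:02d}" for j in range(14)],
             "reason": "KS_CONTROL_SETS", "statistic": 0.5}
        )
        out = apply_qc(small_matrix, QcReport(excluded_analytes=excl))
        assert out.shape == (20, 50 - 14)

    def test_excluded_samples_absent_downstream(self, small_matrix):
        excl = pd.DataFrame(
            {"sample_id": ["S00", "S01"], "reason": "PCA_ARTIFACT", "statistic": 4.0}
        )
        out = apply_qc(small_matrix, QcReport(excluded_samples=excl))
        assert "S00" not in out.sample_ids and "S01" not in out.sample_ids


def test_qc_chain_does_not_eat_markers():
    """Across the full QC chain the fraction of true markers excluded stays
    at or below 5% (median over seeds)."""
    eaten = []
    for seed in range(5):
        spec = CohortSpec(seed=seed)
        m, ann, truth = generate_cohort(spec)
        m = median_normalize(calibrate_plates(m, ann).calibrated).normalized
        study = ann[ann["class_label"].isin(["CASE", "CONTROL"])]
        m = m.subset(samples=list(study["sample_id"]))
        pca = pca_artifact_screen(m, ann, covariates=("site", "plate_id"))
        m2 = apply_qc(m, QcReport(excluded_samples=pca.excluded_samples))
        ks = filter_ks_control_sets(m2, ann)
        pm, pa = generate_paired_draws(spec)
        paired = filter_paired_draws(pm, pa)
        excluded = set(ks.excluded_analytes["analyte_id"]) | set(
            paired.excluded_analytes["analyte_id"]
        )
        markers = set(truth.true_marker_ids)
        eaten.append(len(excluded & markers) / len(markers))
    assert np.median(eaten) <= 0.05
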