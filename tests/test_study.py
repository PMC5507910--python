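"""Coefficient of variation and the simulated test-retest studies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcmri import (
    DomainError,
    PhantomSpec,
    RepeatedMeasure,
    StudyDesign,
    StudyError,
    cov,
    run_study1,
    run_study2,
    summarize,
)


def brute_force_cov(table: list[list[float]]) -> float:
    """Two-loop reference for the per-subject SD/mean averaged over subjects."""
    total = 0.0
    for repeats in table:
        n = len(repeats)
        mean = sum(repeats) / n
        var = sum((x - mean) ** 2 for x in repeats) / (n - 1)
        total += var**0.5 / mean
    return 100.0 * total / len(table)


class TestCoV:
    def test_single_subject_hand_value(self):
        """Repeats {0.20, 0.22}: SD 0.014142, mean 0.21 -> 6.73%."""
        result = cov([RepeatedMeasure("r1", "venc120", [0.20, 0.22])])
        assert result == pytest.approx(6.7343, abs=1e-3)

    def test_two_subject_average(self):
        """(6.734% + 0%) / 2 = 3.37%."""
        measures = [
            RepeatedMeasure("r1", "venc120", [0.20, 0.22]),
            RepeatedMeasure("r2", "venc120", [0.30, 0.30]),
        ]
        assert cov(measures) == pytest.approx(3.3672, abs=1e-3)

    def test_identical_repeats_give_zero(self):
        measures = [RepeatedMeasure(f"r{i}", "c", [1.5, 1.5, 1.5]) for i in range(5)]
        assert cov(measures) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(DomainError):
            cov([RepeatedMeasure("r1", "c", [-1.0, 1.0])])

    def test_single_repeat_rejected(self):
        with pytest.raises(DomainError):
            cov([RepeatedMeasure("r1", "c", [1.0])])

    def test_mixed_conditions_rejected(self):
        with pytest.raises(DomainError):
            cov(
                [
                    RepeatedMeasure("r1", "a", [1.0, 1.1]),
                    RepeatedMeasure("r2", "b", [1.0, 1.1]),
                ]
            )

    def test_unequal_repeat_counts_flagged(self):
        with pytest.warns(RuntimeWarning):
            cov(
                [
                    RepeatedMeasure("r1", "c", [1.0, 1.1]),
                    RepeatedMeasure("r2", "c", [1.0, 1.1, 1.2]),
                ]
            )

    @settings(max_examples=100, derandomize=True)
    @given(
        table=st.lists(
            st.lists(
                st.floats(min_value=0.1, max_value=10.0), min_size=2, max_size=5
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_brute_force_reference(self, table):
        measures = [
            RepeatedMeasure(f"r{i}", "c", repeats) for i, repeats in enumerate(table)
        ]
        assert cov(measures) == pytest.approx(brute_force_cov(table), rel=1e-9)


class TestStudies:
    def test_noiseless_repeats_are_identical(self):
        """Without noise, repeat scans coincide and every CoV is zero."""
        design = StudyDesign(n_subjects=2, n_repeats=2, master_seed=3, snr=np.inf)
        df = run_study1(design, vencs=(120.0,), modes=(True,))
        for _, grp in df.groupby("subject_id"):
            assert grp["flow_ml_s"].nunique() == 1
            assert grp["wss_n_m2"].nunique() == 1

    def test_deterministic_given_design(self):
        design = StudyDesign(n_subjects=2, n_repeats=1, master_seed=4)
        a = run_study1(design, vencs=(120.0,), modes=(True,))
        b = run_study1(design, vencs=(120.0,), modes=(True,))
        pd.testing.assert_frame_equal(a, b)

    def test_nongated_flow_not_above_gated(self, study1_noisy_df):
        """Cycle averaging loses systolic information: flow biased low."""
        piv = (
            study1_noisy_df.groupby(["subject_id", "gated"])["flow_ml_s"]
            .mean()
            .unstack("gated")
        )
        assert (piv[False] <= piv[True]).all()

    def test_resolution_sweep_directions(self, study2_noiseless_df):
        """Partial volume: coarse grids inflate flow/area and suppress WSS.

        The two finest grids are statistically comparable — no ordering
        is claimed between them, only agreement.
        """
        g = study2_noiseless_df.groupby("resolution_mm")[
            ["flow_ml_s", "area_mm2", "wss_n_m2"]
        ].mean()
        g = g.sort_index(ascending=False)  # 0.63 -> 0.16
        coarse, mid, fine1, fine2 = (g.loc[r] for r in g.index)
        for col in ("flow_ml_s", "area_mm2"):
            assert coarse[col] >= mid[col] >= max(fine1[col], fine2[col])
            assert fine1[col] == pytest.approx(fine2[col], rel=0.10)
        assert coarse["wss_n_m2"] <= min(mid["wss_n_m2"], fine1["wss_n_m2"], fine2["wss_n_m2"])
        assert mid["wss_n_m2"] <= max(fine1["wss_n_m2"], fine2["wss_n_m2"])

    def test_finest_resolution_area_matches_subject_anatomy(self, study2_noiseless_df):
        """Fitted areas track each subject's pi R^2 at the finest grid.

        The detection-level contour includes the partial-volume rim, a
        positive bias of order pixel/R, so the smallest subjects sit a
        few percent above the 10% seen for the reference 0.5 mm radius.
        """
        finest = study2_noiseless_df[
            study2_noiseless_df["resolution_mm"] == study2_noiseless_df["resolution_mm"].min()
        ]
        true_area = np.pi * finest["true_radius_mm"] ** 2
        assert np.allclose(finest["area_mm2"], true_area, rtol=0.15)
        # the rim bias is one-sided: never an underestimate
        assert (finest["area_mm2"] >= true_area * 0.97).all()

    def test_higher_snr_reduces_cov(self):
        """Mean flow CoV over seed ensembles falls as SNR rises."""
        covs = {}
        for snr in (10.0, 40.0):
            per_seed = []
            for seed in range(20):
                design = StudyDesign(
                    n_subjects=1, n_repeats=2, master_seed=seed, snr=snr
                )
                df = run_study1(design, vencs=(120.0,), modes=(True,), matrix_size=64)
                grp = df.groupby("subject_id")["flow_ml_s"].apply(list)
                per_seed.append(
                    cov(
                        [
                            RepeatedMeasure(sid, "c", reps)
                            for sid, reps in grp.items()
                        ]
                    )
                )
            covs[snr] = np.mean(per_seed)
        assert covs[40.0] < covs[10.0]

    def test_unusable_anatomy_raises_study_error(self):
        base = PhantomSpec(center=(0.3, 20.0), snr=np.inf)  # lumen crosses FOV edge
        design = StudyDesign(n_subjects=2, n_repeats=1, master_seed=0, snr=np.inf)
        with pytest.raises(StudyError):
            run_study1(design, base_spec=base, vencs=(120.0,), modes=(True,))


class TestSummarize:
    def test_empty_table_refused(self):
        with pytest.raises(DomainError):
            summarize(pd.DataFrame(), ["gated"])

    def test_means_match_direct_recomputation(self, study2_noiseless_df):
        summary, md = summarize(study2_noiseless_df, ["resolution_mm"])
        direct = (
            study2_noiseless_df.groupby(["resolution_mm", "subject_id"])["flow_ml_s"]
            .mean()
            .groupby("resolution_mm")
            .mean()
        )
        for _, row in summary.iterrows():
            assert row["flow_ml_s_mean"] == pytest.approx(
                direct[row["resolution_mm"]], rel=1e-12
            )
        assert md.startswith("|")
        assert md.count("\n") >= 1 + study2_noiseless_df["resolution_mm"].nunique()

    def test_single_condition_single_row(self):
        df = pd.DataFrame(
            {
                "subject_id": ["s0", "s1"],
                "gated": [True, True],
                "flow_ml_s": [0.1, 0.12],
                "wss_n_m2": [3.0, 3.1],
                "area_mm2": [0.8, 0.82],
            }
        )
        summary, _ = summarize(df, ["gated"])
        assert len(summary) == 1
        assert summary.loc[0, "n_scans"] == 2
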