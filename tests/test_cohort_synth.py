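"""Synthetic cohort generator: calibration, realizations, rescoring."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from pragmascore.agreement import icc_two_way
from pragmascore.annotation_model import CellLabel, validate_grid_annotation
from pragmascore.cohort_synth import (
    CohortConfig,
    SyntheticCohort,
    generate_cohort,
    generate_rescore,
    largest_remainder_counts,
    realize_annotations,
    realize_lobe_assessments,
    sqrt_scale_moments,
)
from pragmascore.scoring import CFCT_COMPONENT_MAXIMA, DEFAULT_CFCT_WEIGHTS, cfct_scores, pragma_subscores


def small_config(**kw):
    defaults = dict(n_enrolled=40, n_with_scan=40, p_sos_scorable=1.0, p_eos_scorable=1.0, seed=0)
    defaults.update(kw)
    return CohortConfig(**defaults)


def test_sqrt_scale_moment_inversion_is_exact():
    for mean, sd in [(9.96, 7.58), (2.14, 2.47), (17.94, 6.71)]:
        m, s = sqrt_scale_moments(mean, sd)
        assert m**2 + s**2 == pytest.approx(mean, abs=1e-12)
        assert 2 * s**4 + 4 * m**2 * s**2 == pytest.approx(sd**2, abs=1e-9)
    with pytest.raises(ValueError):
        sqrt_scale_moments(1.0, 10.0)


def test_largest_remainder_apportionment():
    counts = largest_remainder_counts([0.10, 0.02, 0.005, 0.01], 4000)
    assert counts.tolist() == [400, 80, 20, 40]
    # remainders distributed to the largest fractional parts, never off by one cell
    fr = [0.333, 0.333, 0.2]
    counts = largest_remainder_counts(fr, 100)
    assert counts.sum() == round(sum(fr) * 100)
    assert all(abs(c - f * 100) < 1 for c, f in zip(counts, fr))
    with pytest.raises(ValueError):
        largest_remainder_counts([0.9, 0.9], 10)


def test_same_seed_gives_identical_cohorts():
    a = generate_cohort(CohortConfig(seed=5))
    b = generate_cohort(CohortConfig(seed=5))
    pd.testing.assert_frame_equal(a.patients, b.patients)
    pd.testing.assert_frame_equal(a.scores, b.scores)


def test_enlarging_the_cohort_keeps_existing_patients():
    small = generate_cohort(small_config(n_enrolled=30, n_with_scan=30))
    large = generate_cohort(small_config(n_enrolled=45, n_with_scan=45))
    pd.testing.assert_frame_equal(small.patients, large.patients.iloc[:30].reset_index(drop=True))
    small_ids = set(small.patients.patient_id)
    pd.testing.assert_frame_equal(
        small.scores,
        large.scores[large.scores.patient_id.isin(small_ids)].reset_index(drop=True),
    )


def test_default_cohort_reproduces_published_sos_disease_moments():
    cohort = generate_cohort(CohortConfig(seed=2))
    sc = cohort.scores
    sos = sc[(sc.system == "pragma") & (sc.subscore == "disease") & (sc.visit == "SOS")]["value"]
    se = 7.58 / math.sqrt(len(sos))
    assert abs(sos.mean() - 9.96) < 2 * se
    assert sos.between(0, 100).all()
    # scorable counts near the published 195 SOS / 196 EOS
    eos = sc[(sc.system == "pragma") & (sc.subscore == "disease") & (sc.visit == "EOS")]["value"]
    for n_obs, target, p in ((len(sos), 195, 195 / 210), (len(eos), 196, 196 / 210)):
        assert abs(n_obs - target) < 3 * math.sqrt(210 * p * (1 - p)) + 1
    # subscores decompose the composite: BE dominant, AWT near zero
    wide = sc[sc.system == "pragma"].pivot_table(
        index=["patient_id", "visit"], columns="subscore", values="value"
    )
    assert np.allclose(
        wide["bronchiectasis"] + wide["mucus_plugging"] + wide["awt"], wide["disease"], atol=1e-9
    )
    assert wide["bronchiectasis"].mean() > wide["mucus_plugging"].mean() > wide["awt"].mean()
    assert np.allclose(wide[["bronchiectasis", "mucus_plugging", "awt", "atelectasis", "normal"]].sum(axis=1), 100.0, atol=1e-9)


def test_cross_system_correlation_is_near_target():
    cohort = generate_cohort(CohortConfig(seed=3))
    sc = cohort.scores
    wide = sc.pivot_table(index=["patient_id", "visit"], columns=["system", "subscore"], values="value")
    pair = wide[[("pragma", "disease"), ("cfct", "disease")]].dropna()
    r = np.corrcoef(np.sqrt(pair.iloc[:, 0]), np.sqrt(pair.iloc[:, 1]))[0, 1]
    assert abs(r - 0.74) < 0.08  # ~3 x the sampling SD of r at n ~ 390


def test_annotation_realization_round_trips_within_quantization():
    cohort = realize_annotations(generate_cohort(small_config(n_enrolled=6, n_with_scan=6)), 12, 12, seed=1)
    wide = cohort.scores[cohort.scores.system == "pragma"].pivot_table(
        index=["patient_id", "visit"], columns="subscore", values="value"
    )
    assert cohort.annotations
    for (pid, visit), ann in cohort.annotations.items():
        assert validate_grid_annotation(ann).valid
        bound = 100.0 / ann.n_lung_cells()
        target = wide.loc[(pid, visit)]
        got = pragma_subscores(ann).as_dict()
        for name in ("bronchiectasis", "mucus_plugging", "awt", "atelectasis", "normal"):
            assert abs(got[name] - target[name]) <= bound + 1e-9, (pid, visit, name)


def test_zero_disease_realizes_as_all_normal_lung():
    scores = pd.DataFrame(
        [
            ("Z1", "SOS", "pragma", name, 0.0 if name != "normal" else 100.0)
            for name in ("bronchiectasis", "mucus_plugging", "awt", "atelectasis", "normal", "disease")
        ],
        columns=["patient_id", "visit", "system", "subscore", "value"],
    )
    cohort = SyntheticCohort(config=CohortConfig(), patients=pd.DataFrame(), scores=scores)
    out = realize_annotations(cohort, 10, 10, seed=0)
    ann = out.annotations[("Z1", "SOS")]
    counts = ann.label_counts()
    assert counts[CellLabel.NORMAL] == ann.n_lung_cells()


def test_lobe_realization_matches_component_targets_within_quantization():
    cohort = realize_lobe_assessments(generate_cohort(small_config(n_enrolled=6, n_with_scan=6)), seed=2)
    wide = cohort.scores[cohort.scores.system == "cfct"].pivot_table(
        index=["patient_id", "visit"], columns="subscore", values="value"
    )
    assert cohort.lobe_assessments
    for (pid, visit), assessment in cohort.lobe_assessments.items():
        got = cfct_scores(assessment)
        for c, k in DEFAULT_CFCT_WEIGHTS.items():
            # rounding to whole extent units: at most half a unit of error
            bound = 100.0 * k / (2 * CFCT_COMPONENT_MAXIMA[c])
            assert abs(got.pct[c] - wide.loc[(pid, visit), c]) <= bound + 1e-9


class TestRescore:
    def test_perfect_target_copies_scores(self):
        cohort = generate_cohort(small_config())
        table = generate_rescore(cohort, icc_target=1.0, n_rescored=10, seed=1)
        wide = table.pivot_table(
            index=["patient_id", "visit", "system", "subscore"], columns="occasion", values="value"
        )
        assert np.allclose(wide[1], wide[2])

    def test_exact_subset_size(self):
        cohort = generate_cohort(CohortConfig(seed=4))
        table = generate_rescore(cohort, icc_target=0.85, n_rescored=20, seed=2)
        assert table[["patient_id", "visit"]].drop_duplicates().shape[0] == 20
        assert set(table["occasion"]) == {1, 2}

    def test_large_subset_recovers_target_icc(self):
        cohort = generate_cohort(CohortConfig(seed=6))
        table = generate_rescore(cohort, icc_target=0.9, n_rescored=200, seed=3)
        block = table[(table.system == "pragma") & (table.subscore == "disease")]
        wide = block.pivot_table(
            index=["patient_id", "visit"], columns="occasion", values="value"
        )
        res = icc_two_way(wide.to_numpy())
        assert abs(res.icc - 0.9) < 0.05

    @pytest.mark.parametrize("target", [0.0, -0.2, 1.5])
    def test_out_of_range_targets_rejected(self, target):
        cohort = generate_cohort(small_config())
        with pytest.raises(ValueError):
            generate_rescore(cohort, icc_target=target, n_rescored=5, seed=0)

    def test_subset_larger_than_cohort_rejected(self):
        cohort = generate_cohort(small_config(n_enrolled=3, n_with_scan=3))
        with pytest.raises(ValueError, match="scorable"):
            generate_rescore(cohort, icc_target=0.9, n_rescored=50, seed=0)


@pytest.mark.parametrize(
    "kw",
    [
        dict(n_with_scan=300),
        dict(p_sos_scorable=1.4),
        dict(sos_disease_mean=120.0),
        dict(residual_sd_sqrt=5.0),
    ],
)
def test_infeasible_configs_rejected(kw):
    with pytest.raises(ValueError):
        CohortConfig(**kw)


def test_long_table_merges_covariates_and_names_outcomes():
    cohort = generate_cohort(small_config())
    long = cohort.long_table(["pragma_disease", "fev1_percent_predicted"])
    assert set(long.columns) == {"patient_id", "visit", "arm", "tobramycin", "outcome", "value"}
    assert set(long["outcome"]) == {"pragma_disease", "fev1_percent_predicted"}
    assert set(long["arm"]) <= {"ataluren", "placebo"}
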