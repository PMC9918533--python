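"""Trial designs, eligibility pairing, labelling, ROC and bias checks."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from coursemap.cohort import CohortTable
from coursemap.registry import default_registry
from coursemap.trial import (EligiblePair, annual_rate, apoe_point,
                             builtin_trial_designs, find_eligible_pairs,
                             label_fast, operating_point, prognostic_scores,
                             resample_enrichment, roc, selection_bias,
                             build_selection_frame, _half_sample_no_visit_reuse)
from conftest import make_subject

REG = default_registry()
DESIGNS = {d.name: d for d in builtin_trial_designs()}


class TestBuiltinDesigns:
    def test_six_designs(self):
        assert len(builtin_trial_designs()) == 6

    def test_preclinical_design_fields(self):
        d = DESIGNS["preclinical_amyloid"]
        assert d.cdr_allowed == (0.0,)
        assert d.mmse_min == 27.0
        assert d.biomarker == "amyloid"
        assert d.outcome == "adas13"
        assert (d.duration_years, d.tolerance_years) == (4.0, 1.0)

    def test_early_ad_duration_window(self):
        d = DESIGNS["early_ad_amyloid_mmse"]
        assert (d.duration_years, d.tolerance_years) == (1.5, 0.5)

    def test_mci_design_cdr_set(self):
        assert set(DESIGNS["mci_mild_ad"].cdr_allowed) == {0.5, 1.0}


def _design_for_fixture():
    """Simple MMSE design over 2 years +/- 6 months, CDR 0 or 0.5."""
    return dataclasses.replace(
        DESIGNS["mci_mild_ad"], name="fixture", cohort_filter=None,
        cdr_allowed=(0.0, 0.5), age_range=(60.0, 85.0),
        duration_years=2.0, tolerance_years=0.5, mmse_min=24.0)


@pytest.fixture
def fixture_table(registry):
    subjects = [
        # ages 70,71,72,73.5 with a 2.0 +/- 0.5 y window: (0,2)=2.0 ok,
        # (1,3)=2.5 and (2,3)=1.5 sit exactly on the tolerance boundary
        # (included), (0,3)=3.5 and (1,2)=1.0 are out
        make_subject("a", [70.0, 71.0, 72.0, 73.5],
                     mmse=[28, 28, 27, 26], cdr=[0.0, 0.0, 0.5, 0.5]),
        # MMSE below floor at every baseline -> nothing
        make_subject("b", [70.0, 72.0], mmse=[23, 20], cdr=[0.5, 0.5]),
        # separation 2y + 7mo -> outside the window
        make_subject("c", [70.0, 72.58], mmse=[29, 28], cdr=[0.0, 0.0]),
        # endpoint missing at follow-up -> nothing
        make_subject("d", [70.0, 72.0], mmse=[28, None], cdr=[0.0, 0.0]),
        # too old at baseline
        make_subject("e", [86.0, 88.0], mmse=[28, 27], cdr=[0.0, 0.0]),
    ]
    return CohortTable(subjects=subjects, registry=registry)



class TestEligibility:
    def test_hand_enumeration(self, fixture_table):
        pairs = find_eligible_pairs(fixture_table, _design_for_fixture())
        keys = {(p.subject_id, p.baseline_index, p.followup_index) for p in pairs}
        assert keys == {("a", 0, 2), ("a", 1, 3), ("a", 2, 3)}

    def test_separation_beyond_tolerance_excluded(self, fixture_table):
        pairs = find_eligible_pairs(fixture_table, _design_for_fixture())
        assert all(p.subject_id != "c" for p in pairs)

    def test_mmse_floor_excludes(self, fixture_table):
        pairs = find_eligible_pairs(fixture_table, _design_for_fixture())
        assert all(p.subject_id != "b" for p in pairs)

    def test_amyloid_positivity_is_worst_to_date(self, registry):
        design = dataclasses.replace(_design_for_fixture(), biomarker="amyloid")
        # pathological amyloid PET only at visit 0; baseline at visit 1
        subject = make_subject("x", [70.0, 71.0, 73.0],
                               mmse=[28, 28, 27], cdr=[0.0, 0.0, 0.0],
                               amyloid_pet_cl=[80.0, None, None])
        table = CohortTable(subjects=[subject], registry=registry)
        pairs = find_eligible_pairs(table, design)
        assert {(p.baseline_index, p.followup_index) for p in pairs} == {(1, 2)}


class TestAnnualRate:
    def test_orientation(self):
        assert annual_rate(28.0, 24.0, 2.0, REG["mmse"]) == pytest.approx(2.0)
        assert annual_rate(15.0, 15.0, 3.0, REG["adas13"]) == 0.0
        assert annual_rate(1.0, 4.0, 1.5, REG["cdrsb"]) == pytest.approx(2.0)

    def test_nonpositive_elapsed_rejected(self):
        with pytest.raises(ValueError):
            annual_rate(1.0, 2.0, 0.0, REG["cdrsb"])


def make_pairs(outcomes, scores=None, subject_ids=None):
    pairs = []
    for i, outcome in enumerate(outcomes):
        sid = subject_ids[i] if subject_ids else f"s{i}"
        pairs.append(EligiblePair(
            subject_id=sid, baseline_index=0, followup_index=1,
            baseline_age=70.0, followup_age=72.0, elapsed_years=2.0,
            baseline_value=28.0, followup_value=28.0 - 2 * outcome,
            outcome=float(outcome),
            score=None if scores is None else float(scores[i])))
    return pairs


class TestLabelling:
    def test_median_split(self):
        labelled = label_fast(make_pairs([0.0, 1.0, 2.0, 3.0]))
        assert [p.label_fast for p in labelled] == [False, False, True, True]

    def test_all_equal_all_slow(self):
        labelled = label_fast(make_pairs([1.5] * 5))
        assert not any(p.label_fast for p in labelled)

    def test_permutation_invariant(self):
        outcomes = [3.0, 0.5, 2.0, 1.0, 2.5]
        forward = {p.subject_id: p.label_fast for p in label_fast(make_pairs(outcomes))}
        backward = {p.subject_id: p.label_fast
                    for p in label_fast(make_pairs(outcomes[::-1],
                                                   subject_ids=[f"s{i}" for i in
                                                                range(4, -1, -1)]))}
        assert forward == backward


class TestPrognosticScores:
    def test_score_uses_no_followup_data(self, registry, truth_model):
        subject = make_subject("p", [74.0, 78.0], mmse=[28.0, 20.0],
                               adas13=[12.0, 30.0], cdr=[0.0, 0.5])
        altered = make_subject("p", [74.0, 78.0], mmse=[28.0, 5.0],
                               adas13=[12.0, 70.0], cdr=[0.0, 0.5])
        design_pairs = [EligiblePair("p", 0, 1, 74.0, 78.0, 4.0, 28.0, 20.0, 2.0)]
        t1 = CohortTable(subjects=[subject], registry=registry)
        t2 = CohortTable(subjects=[altered], registry=registry)
        from coursemap.evaluation import CourseMapForecaster
        s1 = prognostic_scores(CourseMapForecaster(truth_model), design_pairs, t1, "mmse")
        design_pairs2 = [EligiblePair("p", 0, 1, 74.0, 78.0, 4.0, 28.0, 5.75, 5.75)]
        s2 = prognostic_scores(CourseMapForecaster(truth_model), design_pairs2, t2, "mmse")
        assert s1[0].score == pytest.approx(s2[0].score, abs=1e-12)

    def test_degenerate_model_gives_constant_scores(self, registry, truth_model):
        tight = dataclasses.replace(truth_model.params_, sigma_xi=1e-8,
                                    sigma_tau=1e-8,
                                    mixing=truth_model.params_.mixing * 1e-8)
        from coursemap.model import CourseMap
        model = CourseMap(n_sources=2, normalizer=truth_model.normalizer,
                          endpoints=truth_model.endpoints_)
        model.params_ = tight
        model.endpoints_ = truth_model.endpoints_
        subjects, pairs = [], []
        for i, age in enumerate((72.0, 75.0, 78.0)):
            subjects.append(make_subject(f"p{i}", [age, age + 3.0],
                                         mmse=[27.0 - i, 25.0 - i],
                                         cdr=[0.5, 0.5]))
            pairs.append(EligiblePair(f"p{i}", 0, 1, age, age + 3.0, 3.0,
                                      27.0 - i, 25.0 - i, 2.0 / 3.0))
        table = CohortTable(subjects=subjects, registry=default_registry())
        from coursemap.evaluation import CourseMapForecaster
        scored = prognostic_scores(CourseMapForecaster(model), pairs, table, "mmse")
        # personalization collapses to the population curve; the predicted
        # change is the population change at the same ages
        assert len(scored) == 3


class TestRoc:
    def test_perfect_ranking(self):
        result = roc([0.1, 0.4, 0.9, 1.2], [False, False, True, True])
        assert result.auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(8, 30))
            scores = rng.permutation(n).astype(float)  # tie-free
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            oracle = np.mean([s > t for s in pos for t in neg])
            assert roc(scores, labels).auc == pytest.approx(oracle, abs=1e-12)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        a = roc(scores, labels).auc
        b = roc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            roc([0.1, 0.2], [True, True])

    def test_operating_point_splits_evenly(self):
        rng = np.random.default_rng(3)
        for n in (10, 11, 50, 73):
            scores = rng.normal(size=n)
            selected = scores > operating_point(scores)
            assert abs(selected.sum() - (~selected).sum()) <= 1


class TestResampling:
    def test_half_samples_reuse_no_visit(self):
        pairs = label_fast(make_pairs(np.arange(40.0)))
        rng = np.random.default_rng(0)
        half = _half_sample_no_visit_reuse(pairs, rng)
        assert len(half) == 20
        visits = [(p.subject_id, p.baseline_index) for p in half] + \
                 [(p.subject_id, p.followup_index) for p in half]
        assert len(visits) == len(set(visits))

    def test_deterministic_summary(self):
        rng = np.random.default_rng(5)
        outcomes = rng.normal(size=80)
        scores = outcomes + rng.normal(0, 1.5, 80)
        pairs = label_fast(make_pairs(outcomes, scores))
        a = resample_enrichment(pairs, reps=20, seed=9)
        b = resample_enrichment(pairs, reps=20, seed=9)
        assert a.ci == b.ci
        assert np.array_equal(a.envelope["sensitivity_low"],
                              b.envelope["sensitivity_low"])

    def test_apoe_point(self, registry):
        subjects = [make_subject(f"s{i}", [70.0, 72.0], mmse=[28, 27],
                                 apoe=(1 if i < 4 else 0))
                    for i in range(8)]
        table = CohortTable(subjects=subjects, registry=registry)
        # fast exactly for the carriers -> sensitivity 1, specificity 1
        pairs = make_pairs([2.0] * 4 + [0.0] * 4)
        pairs = label_fast(pairs + make_pairs([1.0], subject_ids=["s7"]))[:8]
        for p, fast in zip(pairs, [True] * 4 + [False] * 4):
            p.label_fast = fast
        sens, spec = apoe_point(pairs, table)
        assert (sens, spec) == (1.0, 1.0)


class TestSelectionBias:
    def _frame(self, rng, n=300, rule="age"):
        pairs = label_fast(make_pairs(rng.normal(size=n)))
        age = rng.uniform(60, 85, n)
        for p, a in zip(pairs, age):
            p.baseline_age = a
        frame = pd.DataFrame({
            "selected": False, "age": age,
            "sex_male": rng.random(n) < 0.5,
            "education_years": rng.integers(8, 20, n).astype(float),
            "apoe4_copies": rng.integers(0, 3, n).astype(float),
            "cohort": np.where(rng.random(n) < 0.5, "A", "B"),
            "true_fast": [p.label_fast for p in pairs],
        })
        if rule == "age":
            # noisy age rule: avoids perfect separation while keeping the
            # planted direction
            frame["selected"] = (frame["age"] + rng.normal(0, 5, n)) > \
                frame["age"].median()
        elif rule == "true":
            frame["selected"] = frame["true_fast"]
        else:
            frame["selected"] = rng.random(n) < 0.5
        return frame

    def test_planted_age_rule_gives_positive_age_coefficient(self):
        rng = np.random.default_rng(0)
        result = selection_bias(self._frame(rng, rule="age"))
        assert result.loc["age", "coef"] > 0

    def test_truth_driven_selection_flagged_or_dominant(self):
        rng = np.random.default_rng(1)
        result = selection_bias(self._frame(rng, rule="true"))
        # selection == true label is perfectly separated: either flagged
        # non-estimable or with an overwhelming coefficient
        row = result.loc["true_fast"]
        assert (not row["estimable"]) or row["coef"] > 5

    def test_random_selection_has_no_significant_covariates(self):
        rng = np.random.default_rng(2)
        result = selection_bias(self._frame(rng, rule="random"))
        z = (result["coef"] / result["se"]).drop("const").abs()
        assert (z < 4).all()

    def test_build_selection_frame_missing_modalities(self, registry):
        subject = make_subject("s1", [70.0, 72.0], mmse=[28, 27])
        table = CohortTable(subjects=[subject], registry=registry)
        pairs = make_pairs([1.0], subject_ids=["s1"])
        pairs[0].label_fast = True
        frame = build_selection_frame(pairs, table, [True])
        assert frame.loc[0, "missing_csf"] == 1.0
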