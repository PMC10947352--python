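"""Study table I/O, summary imputation and eligibility screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from algrowth import (
    ImputationError,
    ReportedDistribution,
    SchemaError,
    ScreeningReason,
    StudyRecord,
    impute_mean_sd,
    read_studies,
    resolve_age,
    screen_corpus,
    screen_study,
    write_studies,
)


def make_record(**kw):
    base = dict(
        study_id="s1", region="somewhere", group="EA", n_emmetropes=387,
        age=ReportedDistribution(n=387, mean=13.2, sd=2.1),
        al=ReportedDistribution(n=387, mean=23.41, sd=0.68),
        ser_lower=-0.50, ser_upper=0.50, cycloplegia=True, biometry="optical")
    base.update(kw)
    return StudyRecord(**base)


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path):
        records = [
            make_record(),
            make_record(study_id="s2", group="nonEA", n_emmetropes=40,
                        age=ReportedDistribution(n=40, median=10.0, q1=8.0,
                                                 q3=12.0),
                        al=ReportedDistribution(n=40, median=23.1, min=21.5,
                                                max=24.9),
                        cycloplegia=False, age_is_whole_sample=True,
                        whole_sample_age_range=2.5, prop_male=0.53),
            make_record(study_id="s3", biometry="ultrasound"),
        ]
        path = tmp_path / "studies.csv"
        write_studies(records, path)
        back = read_studies(path)
        assert back == records

    def test_row_count_preserved(self, tmp_path):
        path = tmp_path / "three.csv"
        write_studies([make_record(study_id=f"s{i}") for i in range(3)], path)
        assert len(read_studies(path)) == 3

    def test_missing_al_columns_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({
            "study_id": ["x"], "group": ["EA"], "n": [10],
            "age_mean": [9.0], "age_sd": [1.0], "ser_lower": [-0.5],
            "ser_upper": [0.5], "cycloplegia": [1], "biometry": ["optical"],
        }).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="al_mean"):
            read_studies(path)

    def test_unparseable_numeric_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        df = pd.DataFrame({
            "study_id": ["x"], "group": ["EA"], "n": [10],
            "age_mean": [9.0], "age_sd": [1.0], "al_mean": ["twenty"],
            "al_sd": [0.5], "ser_lower": [-0.5], "ser_upper": [0.5],
            "cycloplegia": [1], "biometry": ["optical"],
        })
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="row 0"):
            read_studies(path)

    def test_unicode_minus_accepted(self, tmp_path):
        path = tmp_path / "u.csv"
        path.write_text(
            "study_id,group,n,age_mean,age_sd,al_mean,al_sd,"
            "ser_lower,ser_upper,cycloplegia,biometry\n"
            "s1,EA,50,10.0,1.0,23.0,0.6,−0.50,0.50,1,optical\n")
        rec = read_studies(path)[0]
        assert rec.ser_lower == -0.50

    def test_al_in_cm_rejected(self, tmp_path):
        path = tmp_path / "cm.csv"
        write_studies([make_record()], path)
        df = pd.read_csv(path)
        df["al_mean"] = 2.341  # centimetres: outside [18, 28] mm window
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="plausibility"):
            read_studies(path)


class TestImputation:
    def test_reported_moments_pass_through(self):
        d = ReportedDistribution(n=16, mean=23.41, sd=0.68)
        assert impute_mean_sd(d) == (23.41, 0.68)

    def test_symmetric_iqr_gives_median_as_mean(self):
        d = ReportedDistribution(n=100, median=10.0, q1=8.0, q3=12.0)
        mean, _ = impute_mean_sd(d)
        assert mean == pytest.approx(10.0)

    def test_iqr_sd_close_to_simulation_oracle(self):
        # a normal with sd 2.9652 has quartiles 8/12 around median 10; the
        # estimator at n=100 gives 3.0088, within 5% of that truth
        d = ReportedDistribution(n=100, median=10.0, q1=8.0, q3=12.0)
        _, sd = impute_mean_sd(d)
        assert sd == pytest.approx(3.0088, abs=1e-3)
        assert abs(sd - 2.9652) / 2.9652 < 0.05

    def test_median_range_scenario(self):
        d = ReportedDistribution(n=50, median=10.0, min=4.0, max=18.0)
        mean, sd = impute_mean_sd(d)
        assert mean == pytest.approx((4 + 20 + 18) / 4)
        assert sd == pytest.approx(
            14.0 / (2 * norm.ppf((50 - 0.375) / (50 + 0.25))))

    def test_five_number_scenario_averages_sd_estimators(self):
        d = ReportedDistribution(n=50, median=10.0, q1=8.0, q3=12.0,
                                 min=4.0, max=18.0)
        mean, sd = impute_mean_sd(d)
        assert mean == pytest.approx((4 + 16 + 20 + 24 + 18) / 8)
        sd_rng = 14.0 / (2 * norm.ppf((50 - 0.375) / (50 + 0.25)))
        sd_iqr = 4.0 / (2 * norm.ppf((0.75 * 50 - 0.125) / (50 + 0.25)))
        assert sd == pytest.approx((sd_rng + sd_iqr) / 2)

    def test_insufficient_summaries_rejected(self):
        with pytest.raises(ImputationError, match="median"):
            impute_mean_sd(ReportedDistribution(n=10, sd=1.0))
        with pytest.raises(ImputationError, match="q1/q3"):
            impute_mean_sd(ReportedDistribution(n=10, median=5.0))
        with pytest.raises(ImputationError, match="n < 2"):
            impute_mean_sd(ReportedDistribution(n=1, median=5.0, min=1.0,
                                                max=9.0))

    @settings(deadline=None, max_examples=50)
    @given(mu=st.floats(5, 30), sigma=st.floats(0.1, 5),
           n=st.integers(5, 500))
    def test_imputation_idempotent_once_moments_known(self, mu, sigma, n):
        d = ReportedDistribution(n=n, mean=mu, sd=sigma, median=mu,
                                 q1=mu - sigma, q3=mu + sigma)
        assert impute_mean_sd(d) == (mu, sigma)

    def test_imputation_unbiased_over_simulated_studies(self, rng):
        """Across simulated normal studies, imputed means land within 1% and
        imputed sds within 5% of the truth on average."""
        mu, sigma = 23.0, 0.7
        for n in (15, 50, 200):
            means, sds = [], []
            for _ in range(1000):
                x = rng.normal(mu, sigma, n)
                q1, med, q3 = np.percentile(x, [25, 50, 75])
                m, s = impute_mean_sd(ReportedDistribution(
                    n=n, median=float(med), q1=float(q1), q3=float(q3)))
                means.append(m)
                sds.append(s)
            assert abs(np.mean(means) - mu) / mu < 0.01
            assert abs(np.mean(sds) - sigma) / sigma < 0.05


class TestResolveAge:
    def test_whole_sample_within_three_years_accepted(self):
        r = make_record(age_is_whole_sample=True, whole_sample_age_range=2.0)
        assert resolve_age(r) == (13.2, 2.1)

    def test_whole_sample_range_too_wide_refused(self):
        r = make_record(age_is_whole_sample=True, whole_sample_age_range=3.5)
        decision = resolve_age(r)
        assert decision.reason is ScreeningReason.AGE_IMPUTATION_REFUSED

    def test_whole_sample_range_unknown_refused(self):
        r = make_record(age_is_whole_sample=True, whole_sample_age_range=None)
        assert not resolve_age(r).eligible

    def test_emmetrope_specific_age_unconditional(self):
        assert resolve_age(make_record()) == (13.2, 2.1)


class TestScreening:
    def test_reference_eligible_record(self):
        d = screen_study(make_record(age=ReportedDistribution(n=387, mean=10.0,
                                                              sd=1.0)))
        assert d.eligible and d.reason is ScreeningReason.OK

    @pytest.mark.parametrize("kw, reason", [
        (dict(biometry="ultrasound"), ScreeningReason.ULTRASOUND_AL),
        (dict(ser_lower=-1.25, ser_upper=1.25),
         ScreeningReason.SER_WINDOW_VIOLATION),
        (dict(cycloplegia=False), ScreeningReason.NONCYCLO_YOUNG),
        (dict(age=ReportedDistribution(n=387, mean=33.0, sd=1.0)),
         ScreeningReason.AGE_OUT_OF_RANGE),
        (dict(al_is_emmetrope_specific=False),
         ScreeningReason.NO_EMMETROPE_AL),
    ])
    def test_each_rule_sets_its_reason(self, kw, reason):
        assert screen_study(make_record(**kw)).reason is reason

    def test_noncyclo_adult_sample_eligible(self):
        r = make_record(cycloplegia=False,
                        age=ReportedDistribution(n=50, mean=23.1, sd=1.0))
        assert screen_study(r).eligible

    def test_rule_order_first_failure_wins(self):
        # ultrasound outranks the emmetropia-window violation
        r = make_record(biometry="ultrasound", ser_lower=-1.25, ser_upper=1.25)
        assert screen_study(r).reason is ScreeningReason.ULTRASOUND_AL

    def test_screening_deterministic(self):
        r = make_record(cycloplegia=False)
        assert screen_study(r) == screen_study(r)

    def test_corpus_report_counts(self):
        records = [make_record(study_id="a"),
                   make_record(study_id="b", biometry="ultrasound"),
                   make_record(study_id="c", biometry="ultrasound")]
        report = screen_corpus(records)
        assert report["reason"].value_counts()["ultrasound_al"] == 2


def test_order_statistics_validated():
    with pytest.raises(ValueError, match="order statistics"):
        ReportedDistribution(n=10, median=5.0, q1=7.0, q3=6.0)
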