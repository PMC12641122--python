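import numpy as np
import pandas as pd
import pytest

from lfpei.stats import (
    EstimationError,
    genotype_compare,
    match_fei_pac,
    match_fei_spikes,
    match_pac_spikes,
    rmcorr,
    weekly_to_monthly,
)


def ancova_oracle(df):
    """Brute-force rmcorr: explicit design matrix (subject dummies + common
    slope) solved by least squares."""
    subjects = sorted(df["subject"].unique())
    X = np.zeros((len(df), len(subjects) + 1))
    for i, s in enumerate(subjects):
        X[(df["subject"] == s).to_numpy(), i] = 1.0
    X[:, -1] = df["x"].to_numpy()
    y = df["y"].to_numpy()
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_resid = float(resid @ resid)
    # effect SS: extra SS explained by the slope over the intercept-only fit
    X0 = X[:, :-1]
    coef0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    resid0 = y - X0 @ coef0
    ss_effect = float(resid0 @ resid0) - ss_resid
    r = np.sign(coef[-1]) * np.sqrt(ss_effect / (ss_effect + ss_resid))
    return r


def _pairs(seed=0, n_subj=4, n_rep=8, slope=0.5, noise=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        x = rng.normal(0, 1, n_rep)
        y = slope * x + 2.0 * s + rng.normal(0, noise, n_rep)
        rows += [dict(subject=f"m{s}", x=a, y=b) for a, b in zip(x, y)]
    return pd.DataFrame(rows)


class TestRmcorr:
    def test_parallel_lines_give_perfect_correlation(self):
        rows = [dict(subject=s, x=float(x), y=float(x) + c)
                for s, c in (("a", 0.0), ("b", 5.0)) for x in range(4)]
        res = rmcorr(pd.DataFrame(rows))
        assert res.r_rm == pytest.approx(1.0)
        assert res.p == 0.0

    def test_matches_brute_force_ancova(self):
        df = _pairs(seed=1, n_subj=3, n_rep=8)
        res = rmcorr(df)
        assert res.r_rm == pytest.approx(ancova_oracle(df), abs=1e-10)
        assert res.dof == 24 - 3 - 1

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        df = _pairs(seed=2, n_subj=5, n_rep=6)
        res = rmcorr(df)
        ref = pg.rm_corr(data=df, x="x", y="y", subject="subject")
        assert res.r_rm == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)
        assert res.dof == int(ref["dof"].iloc[0])

    def test_invariant_to_per_subject_centering(self):
        df = _pairs(seed=3)
        centered = df.copy()
        for col in ("x", "y"):
            centered[col] -= centered.groupby("subject")[col].transform("mean")
        assert rmcorr(centered).r_rm == pytest.approx(rmcorr(df).r_rm, abs=1e-12)

    def test_null_calibration_type_one_error(self):
        hits = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(10_000 + rep)
            rows = [dict(subject=s, x=rng.normal(), y=rng.normal() + s)
                    for s in range(6) for _ in range(6)]
            if rmcorr(pd.DataFrame(rows)).p < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_zero_variance_subjects_dropped(self):
        df = _pairs(seed=4, n_subj=3)
        flat = pd.DataFrame([dict(subject="flat", x=1.0, y=v) for v in (1.0, 2.0)])
        res_with = rmcorr(pd.concat([df, flat]))
        assert res_with.n_subjects == 3

    def test_all_degenerate_raises(self):
        df = pd.DataFrame([dict(subject="a", x=1.0, y=1.0),
                           dict(subject="a", x=1.0, y=2.0)])
        with pytest.raises(EstimationError):
            rmcorr(df)

    def test_ci_brackets_estimate(self):
        res = rmcorr(_pairs(seed=5))
        assert res.ci95[0] <= res.r_rm <= res.ci95[1]


def _weekly_table():
    rows = []
    for subj, geno in (("m1", "WT"), ("m2", "APP")):
        for ch in ("e1", "e2"):
            for wk, val in zip(range(20, 24), (1.0, 1.2, np.nan, 1.1)):
                rows.append(dict(subject=subj, genotype=geno, age_week=wk,
                                 age_month=5, channel=ch, region="HC",
                                 hc_layer="pyramidal", metric="fei",
                                 band="35–45 Hz", value=val))
    return pd.DataFrame(rows)


class TestAggregation:
    def test_electrode_month_mean_skips_missing(self):
        elec, mouse = weekly_to_monthly(_weekly_table())
        assert np.allclose(elec["value"], 1.1)
        assert np.allclose(mouse["value"], 1.1)

    def test_two_stage_mean_over_electrodes(self):
        df = _weekly_table()
        df.loc[(df.subject == "m1") & (df.channel == "e2"), "value"] = 0.5
        _, mouse = weekly_to_monthly(df)
        m1 = mouse.loc[mouse.subject == "m1", "value"].iloc[0]
        assert m1 == pytest.approx((1.1 + 0.5) / 2)

    def test_idempotent(self):
        elec, mouse = weekly_to_monthly(_weekly_table())
        elec2, mouse2 = weekly_to_monthly(elec)
        pd.testing.assert_frame_equal(
            mouse.sort_index(axis=1), mouse2.sort_index(axis=1), check_like=True)

    def test_single_week_passthrough(self):
        df = _weekly_table()
        df = df[df.age_week == 20]
        elec, _ = weekly_to_monthly(df)
        assert np.allclose(elec["value"], 1.0)


class TestMatching:
    def test_fei_pac_join_cardinality(self):
        fei = pd.DataFrame([dict(subject="m1", channel=c, age_month=m, value=1.0)
                            for c in ("e1", "e2") for m in (5, 6)])
        pac = fei.copy()
        pac["value"] = 0.01
        pairs = match_fei_pac(fei, pac)
        assert len(pairs) == 4

    def test_missing_month_dropped_from_join(self):
        fei = pd.DataFrame([dict(subject="m1", channel="e1", age_month=5, value=1.0)])
        pac = pd.DataFrame([dict(subject="m1", channel="e1", age_month=m, value=0.01)
                            for m in (5, 6)])
        assert len(match_fei_pac(fei, pac)) == 1

    def test_empty_join_raises(self):
        fei = pd.DataFrame([dict(subject="m1", channel="e1", age_month=5, value=1.0)])
        pac = pd.DataFrame([dict(subject="m2", channel="e1", age_month=5, value=0.01)])
        with pytest.raises(EstimationError):
            match_fei_pac(fei, pac)

    def test_zero_rate_weeks_excluded(self):
        fei = pd.DataFrame([dict(subject="m1", age_week=w, value=v)
                            for w, v in ((20, 1.0), (21, 1.1), (22, 1.2))])
        rates = pd.DataFrame([dict(subject="m1", age_week=w, rate_hz=r)
                              for w, r in ((20, 0.0), (21, 0.05), (22, 0.02))])
        pairs = match_fei_spikes(fei, rates)
        assert sorted(pairs["age_week"]) == [21, 22]

    def test_channel_average_before_spike_join(self):
        fei = pd.DataFrame([dict(subject="m1", age_week=20, value=v)
                            for v in (1.0, 1.1, 1.2)])
        rates = pd.DataFrame([dict(subject="m1", age_week=20, rate_hz=0.05)])
        pairs = match_fei_spikes(fei, rates)
        assert pairs["x"].iloc[0] == pytest.approx(1.1)

    def test_pac_spikes_monthly_rate_mean_and_zero_drop(self):
        pac = pd.DataFrame([dict(subject="m1", age_month=m, value=0.01)
                            for m in (5, 6)])
        rates = pd.DataFrame([dict(subject="m1", age_week=w, rate_hz=r)
                              for w, r in ((20, 0.02), (21, 0.04), (24, 0.0),
                                           (25, 0.0), (26, 0.0), (27, 0.0))])
        pairs = match_pac_spikes(pac, rates)
        assert len(pairs) == 1
        assert pairs["y"].iloc[0] == pytest.approx(0.03)


class TestGenotypeCompare:
    def _mouse_month(self, seed=0, shift=0.0, n=6, months=(5, 6)):
        rng = np.random.default_rng(seed)
        rows = []
        for m in months:
            for g in ("WT", "APP"):
                for i in range(n):
                    v = rng.normal(1.0, 0.1) + (shift if g == "APP" and m == 6 else 0)
                    rows.append(dict(subject=f"{g}{i}", genotype=g,
                                     age_month=m, value=v))
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        df = self._mouse_month(seed=1, shift=0.0)
        out = genotype_compare(df)
        assert all(not c.significant for c in out)

    def test_large_shift_flagged_after_fdr(self):
        df = self._mouse_month(seed=2, shift=0.5)
        out = {c.age_month: c for c in genotype_compare(df)}
        assert out[6].significant and not out[5].significant
        assert out[6].delta == pytest.approx(0.5, abs=0.2)

    def test_welch_chosen_when_variances_differ(self):
        rng = np.random.default_rng(3)
        rows = [dict(subject=f"WT{i}", genotype="WT", age_month=5,
                     value=rng.normal(1.0, 0.01)) for i in range(10)]
        rows += [dict(subject=f"AP{i}", genotype="APP", age_month=5,
                      value=rng.normal(1.0, 1.0)) for i in range(10)]
        out = genotype_compare(pd.DataFrame(rows))
        assert out[0].test == "welch" and out[0].levene_p < 0.05

    def test_small_groups_skipped(self):
        df = pd.DataFrame([dict(subject="w", genotype="WT", age_month=5, value=1.0),
                           dict(subject="a", genotype="APP", age_month=5, value=1.0)])
        assert genotype_compare(df) == []
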