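import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import chi2

from bisewas.ewas import (
    CollinearityError,
    build_design,
    estimate_qvalues,
    fit_binomial_glm,
    genomic_lambda,
    make_model_spec,
    run_ewas,
    summarize_dmcs,
)
from bisewas.filtering import filter_cpgs


def _two_group_design(n0, n1):
    X = np.column_stack([np.ones(n0 + n1),
                         np.r_[np.zeros(n0), np.ones(n1)]])
    return X


def _closed_form(meth0, tot0, meth1, tot1):
    """Grouped-binomial two-group fit: difference of pooled logits and its
    standard error."""
    p0, p1 = meth0 / tot0, meth1 / tot1
    beta = logit(p1) - logit(p0)
    se = np.sqrt(1.0 / (tot0 * p0 * (1 - p0)) + 1.0 / (tot1 * p1 * (1 - p1)))
    return beta, se


class TestBinomialGlm:
    def test_identical_proportions_give_zero_beta(self):
        X = _two_group_design(10, 10)
        fit = fit_binomial_glm([10] * 20, [20] * 20, X)
        assert abs(fit["beta"]) < 1e-8
        assert fit["converged"]

    def test_matches_pooled_logit_closed_form(self):
        # group0 pooled 30/100, group1 pooled 60/100
        X = _two_group_design(10, 10)
        meth = [3] * 10 + [6] * 10
        total = [10] * 20
        fit = fit_binomial_glm(meth, total, X)
        beta, se = _closed_form(30, 100, 60, 100)
        assert abs(beta - 1.2528) < 1e-4 and abs(se - 0.2988) < 1e-4
        assert abs(fit["beta"] - beta) < 1e-8
        assert abs(fit["se"] - se) < 1e-8

    def test_closed_form_agreement_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n0, n1 = rng.integers(5, 40, 2)
            X = _two_group_design(n0, n1)
            total = rng.integers(5, 50, n0 + n1)
            p = rng.uniform(0.15, 0.85, 2)
            meth = rng.binomial(total, np.r_[np.full(n0, p[0]),
                                             np.full(n1, p[1])])
            if meth[:n0].sum() in (0, total[:n0].sum()):
                continue
            if meth[n0:].sum() in (0, total[n0:].sum()):
                continue
            fit = fit_binomial_glm(meth, total, X)
            beta, se = _closed_form(meth[:n0].sum(), total[:n0].sum(),
                                    meth[n0:].sum(), total[n0:].sum())
            assert abs(fit["beta"] - beta) < 1e-8
            assert abs(fit["se"] - se) < 1e-8

    def test_agrees_with_statsmodels_glm_with_covariates(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n),
                             rng.integers(0, 2, n).astype(float),
                             rng.integers(0, 3, n).astype(float)])
        total = rng.integers(10, 40, n)
        eta = 0.2 + 0.3 * X[:, 1] - 0.5 * X[:, 2] + 0.4 * X[:, 3]
        meth = rng.binomial(total, 1 / (1 + np.exp(-eta)))
        fit = fit_binomial_glm(meth, total, X)
        ref = sm.GLM(np.column_stack([meth, total - meth]), X,
                     family=sm.families.Binomial()).fit()
        assert abs(fit["beta"] - ref.params[-1]) < 1e-6
        assert abs(fit["se"] - ref.bse[-1]) < 1e-6

    def test_constant_predictor_errors(self):
        X = np.column_stack([np.ones(10), np.zeros(10)])
        with pytest.raises(ValueError, match="constant"):
            fit_binomial_glm([5] * 10, [10] * 10, X)

    def test_collinear_design_reports_columns(self):
        n = 20
        z = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), z, 2 * z,
                             np.r_[np.zeros(10), np.ones(10)]])
        with pytest.raises(CollinearityError):
            fit_binomial_glm([5] * n, [10] * n, X,
                             column_names=["intercept", "a", "b", "grp"])

    def test_separated_fit_flagged_not_converged(self):
        # group 0 fully unmethylated, group 1 fully methylated
        X = _two_group_design(8, 8)
        fit = fit_binomial_glm([0] * 8 + [10] * 8, [10] * 16, X)
        assert not fit["converged"]


class TestModelSpecs:
    def test_model_definitions(self, small_study):
        s = small_study["samples"]
        for name, pred, has_cells, n_mask in [
                ("I", "acpa_pos", False, (~s["ra"]).sum()),
                ("II", "acpa_pos", True, (~s["ra"]).sum()),
                ("III", "case", True, len(s)),
                ("IV", "acpa_dose", True, (~s["ra"]).sum()),
                ("V", "case", False, len(s))]:
            spec = make_model_spec(name, s)
            assert spec.predictor == pred
            assert ("prop_neutrophil" in spec.covariates) == has_cells
            assert spec.sample_mask.sum() == n_mask
        assert make_model_spec("V", s).covariates == []

    def test_basophil_dropped_for_full_rank(self, small_study):
        s = small_study["samples"]
        X, names, t_idx = build_design(s, make_model_spec("II", s))
        assert "prop_basophil" not in names
        assert names[t_idx] == "acpa_pos"
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_smoking_coded_as_two_indicators(self, small_study):
        s = small_study["samples"]
        X, names, _ = build_design(s, make_model_spec("I", s))
        assert "smoking_current" in names and "smoking_past" in names
        assert "smoking_never" not in names


class TestRunEwas:
    def test_results_invariant_to_sample_and_cpg_order(self, small_study):
        m, s = small_study["m"], small_study["samples"]
        m, _ = filter_cpgs(m)
        m = m.subset_cpgs(np.arange(300))
        spec = make_model_spec("II", s)
        res = run_ewas(m, s, spec)

        perm = np.random.default_rng(0).permutation(m.n_samples)
        m_p = m.subset_samples(perm)
        s_p = s.iloc[perm].reset_index(drop=True)
        res_p = run_ewas(m_p, s_p, make_model_spec("II", s_p))
        np.testing.assert_allclose(res["beta"], res_p["beta"],
                                   rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(res["p_value"], res_p["p_value"],
                                   rtol=1e-5, atol=1e-12)

    def test_planted_dose_effects_recovered_by_ordinal_model(self, small_study):
        m, s = small_study["m"], small_study["samples"]
        truth = small_study["truth"]
        m, _ = filter_cpgs(m)
        res = run_ewas(m, s, make_model_spec("IV", s))
        planted = set()
        for chrom, start, end, _, mech in truth.true_dmr_intervals:
            if mech != "dose":
                continue
            for c, p in zip(m.chrom, m.pos):
                if c == chrom and start <= p <= end:
                    planted.add((c, p))
        hits = res[[(c, p) in planted
                    for c, p in zip(res["chrom"], res["pos"])]]
        sig = hits["q_value"] < 0.01
        assert sig.mean() > 0.5
        # estimated effect near the planted per-step logit effect
        good = hits[sig & hits["converged"]]
        med = np.median(np.abs(good["beta"]))
        assert abs(med - small_study["config"].effect_logit) \
            < 0.3 * small_study["config"].effect_logit

    def test_cell_confounded_cpgs_lost_after_adjustment(self):
        from bisewas.synthetic_data import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(n_cpgs=4000, n_true_dmrs=0,
                               n_confounded_dmrs=0, n_cell_cpgs=80,
                               cell_effect_logit=3.0, cell_acpa_shift=0.06,
                               n_meqtl_snps=0, n_null_snps=5,
                               mean_coverage=30.0, seed=21)
        m, s, g, ann, truth = simulate_dataset(cfg)
        m, _ = filter_cpgs(m)
        keys = list(zip(m.chrom, m.pos))
        cell_keys = set()
        raw_m, *_ = simulate_dataset(cfg)
        for i in truth.cell_cpg_index:
            cell_keys.add((raw_m.chrom[i], raw_m.pos[i]))
        sel = [k in cell_keys for k in keys]

        res1 = run_ewas(m, s, make_model_spec("I", s))
        res2 = run_ewas(m, s, make_model_spec("II", s))
        p1 = res1.loc[sel, "p_value"]
        p2 = res2.loc[sel, "p_value"]
        sig1 = (res1.loc[sel, "q_value"] < 0.05).sum()
        sig2 = (res2.loc[sel, "q_value"] < 0.05).sum()
        # neutrophil-driven CpGs light up without cell adjustment and are
        # attenuated once measured proportions enter the model
        assert sig1 >= 5
        assert sig2 < 0.5 * sig1
        assert np.nanmedian(p2) > np.nanmedian(p1)


class TestQValues:
    def test_all_ones_give_q_one(self):
        q, model = estimate_qvalues([1.0, 1.0, 1.0])
        np.testing.assert_allclose(q, 1.0)
        assert model.pi0 == 1.0

    def test_hand_enumerated_step_up_example(self):
        q, _ = estimate_qvalues([0.001, 0.5, 0.9], pi0=1.0)
        np.testing.assert_allclose(q, [0.003, 0.75, 0.9], rtol=1e-12)

    def test_evenly_spaced_p_give_q_one(self):
        m = 50
        p = np.arange(1, m + 1) / m
        q, _ = estimate_qvalues(p, pi0=1.0)
        np.testing.assert_allclose(q, 1.0, rtol=1e-12)

    def test_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=2000) ** 2
        q, model = estimate_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= 0).all() and (q <= 1).all()
        assert 0 < model.pi0 <= 1

    def test_matches_r_qvalue_package(self):
        """Cross-check pi0 smoothing and q-values against the reference R
        implementation on a fixed p-value set."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(size=900),
                            rng.beta(0.2, 5.0, size=100)])
        script = (
            "p <- scan('stdin', quiet=TRUE);"
            "m <- length(p); lam <- seq(0.05, 0.9, 0.05);"
            "pi0l <- sapply(lam, function(l) mean(p > l)/(1 - l));"
            "fit <- smooth.spline(lam, pi0l, df=3);"
            "pi0 <- min(max(predict(fit, x=0.9)$y, 0), 1);"
            "o <- order(p); ro <- rank(p, ties.method='first');"
            "q <- pi0 * m * p[o]/seq_len(m);"
            "q <- rev(cummin(rev(q))); q <- pmin(q, 1)[ro];"
            "cat(pi0, q[1:10], sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", script],
                             input="\n".join(f"{x:.17g}" for x in p),
                             capture_output=True, text=True, check=True)
        vals = [float(x) for x in out.stdout.split()]
        pi0_r, q_r = vals[0], vals[1:]
        q, model = estimate_qvalues(p)
        assert abs(model.pi0 - pi0_r) < 0.03
        np.testing.assert_allclose(q[:10] * (pi0_r / model.pi0), q_r,
                                   rtol=1e-6)

    def test_empty_and_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            estimate_qvalues([])
        with pytest.raises(ValueError):
            estimate_qvalues([0.5, 1.5])


class TestGenomicLambda:
    def test_null_median_gives_lambda_one(self):
        assert abs(genomic_lambda([0.5] * 11) - 1.0) < 1e-9

    def test_uniform_p_values_give_lambda_one(self):
        rng = np.random.default_rng(5)
        lam = genomic_lambda(rng.uniform(size=100_000))
        assert abs(lam - 1.0) < 0.02

    def test_median_chi_square_ratio(self):
        # a median transformed statistic of 0.4777 corresponds to ~1.05
        p_med = float(chi2.sf(0.4777, df=1))
        lam = genomic_lambda([p_med] * 3)
        assert abs(lam - 1.05) < 0.005
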