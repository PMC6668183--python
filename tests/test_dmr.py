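import numpy as np
import pandas as pd
import pytest

from bisewas.dmr import (
    DmrRecord,
    call_dmrs,
    compare_dmr_sets,
    compare_sets,
    directional_filter,
    dmrs_to_frame,
)
from bisewas.io_formats import MethylationMatrix


def _results(pos, p, q, beta, chrom="chr1"):
    n = len(pos)
    return pd.DataFrame({
        "chrom": [chrom] * n,
        "pos": pos,
        "beta": beta,
        "se": [0.1] * n,
        "wald_z": np.asarray(beta) / 0.1,
        "p_value": p,
        "q_value": q,
        "n_used": [100] * n,
        "direction": np.sign(beta).astype(int),
        "converged": [True] * n,
        "methdiff": np.asarray(beta) * 0.1,
    })


def brute_force_dmrs(results, q_threshold=0.01, p_threshold=0.01, window=200):
    """Independent enumerator: every maximal run of consecutive tested CpGs
    that lies inside some seed window, has >= 3 members all with p below
    threshold and equal sign, and contains >= 1 seed."""
    out = []
    tested = results[results["converged"]
                     & np.isfinite(results["p_value"])].reset_index(drop=True)
    for chrom in tested["chrom"].unique():
        sub = tested[tested["chrom"] == chrom].reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        seeds = np.flatnonzero(np.nan_to_num(sub["q_value"], nan=1.0)
                               < q_threshold)
        covered = np.zeros(len(sub), dtype=bool)
        for s in seeds:
            covered |= (pos >= pos[s] - window) & (pos <= pos[s] + window)
        ok = ((sub["p_value"].to_numpy() < p_threshold)
              & (np.sign(sub["beta"].to_numpy()) != 0) & covered)
        sign = np.sign(sub["beta"].to_numpy())
        runs = []
        i = 0
        while i < len(sub):
            if not ok[i]:
                i += 1
                continue
            j = i + 1
            while j < len(sub) and ok[j] and sign[j] == sign[i]:
                j += 1
            runs.append((i, j))
            i = j
        seed_set = set(seeds)
        for i, j in runs:
            if j - i >= 3 and any(k in seed_set for k in range(i, j)):
                out.append((chrom, int(pos[i]), int(pos[j - 1]), j - i,
                            "hyper" if sign[i] > 0 else "hypo"))
    return out


class TestCallDmrs:
    def test_two_qualifying_cpgs_insufficient(self):
        res = _results([100, 150, 500], [0.001, 0.005, 0.2],
                       [0.004, 0.02, 0.5], [1, 1, 1])
        assert call_dmrs(res) == []

    def test_worked_example_three_member_region(self):
        res = _results([100, 150, 220, 500],
                       [0.001, 0.005, 0.009, 0.2],
                       [0.02, 0.004, 0.03, 0.5],
                       [1.0, 1.0, 1.0, 1.0])
        dmrs = call_dmrs(res)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end, d.n_cpgs, d.direction) == (100, 220, 3, "hyper")
        assert d.member_pos == [100, 150, 220]

    def test_sign_break_prevents_run(self):
        res = _results([100, 150, 200], [0.001] * 3, [0.001] * 3,
                       [1.0, -1.0, 1.0])
        assert call_dmrs(res) == []

    def test_run_must_contain_seed(self):
        # qualifying run far from the only seed window
        res = _results([100, 120, 140, 5000, 5020, 5040],
                       [0.001] * 6, [0.001, 1, 1, 1, 1, 1],
                       [1.0] * 6)
        dmrs = call_dmrs(res)
        assert len(dmrs) == 1
        assert dmrs[0].start == 100

    def test_boundary_cpg_inside_window(self):
        res = _results([100, 300, 301], [0.001, 0.001, 0.001],
                       [0.001, 1.0, 1.0], [1.0, 1.0, 1.0])
        # 300 == 100 + 200 inside; 301 outside -> only 2 members, no DMR
        assert call_dmrs(res) == []

    def test_mean_statistics_over_members(self):
        res = _results([100, 150, 200], [0.001] * 3, [0.001, 0.002, 0.003],
                       [0.5, 0.7, 0.9])
        d = call_dmrs(res)[0]
        assert abs(d.mean_q - 0.002) < 1e-12
        assert abs(d.mean_methdiff - 0.07) < 1e-12

    def test_unsorted_input_rejected(self):
        res = _results([200, 100], [0.001, 0.001], [0.001, 0.001], [1, 1])
        with pytest.raises(ValueError, match="sorted"):
            call_dmrs(res)

    def test_matches_brute_force_enumerator_on_random_instances(self):
        rng = np.random.default_rng(12)
        for trial in range(1000):
            n = int(rng.integers(3, 51))
            pos = np.sort(rng.choice(np.arange(1, 3000), n, replace=False))
            p = rng.uniform(size=n) ** 2
            q = p * rng.uniform(1.0, 3.0, n)
            beta = rng.normal(size=n)
            res = _results(pos, p, q, beta)
            got = [(d.chrom, d.start, d.end, d.n_cpgs, d.direction)
                   for d in call_dmrs(res)]
            assert got == brute_force_dmrs(res), f"trial {trial}"

    def test_invariant_to_chromosome_processing_order(self):
        rng = np.random.default_rng(4)
        frames = []
        for chrom in ["chr2", "chr1", "chr10"]:
            n = 30
            pos = np.sort(rng.choice(np.arange(1, 2000), n, replace=False))
            frames.append(_results(pos, rng.uniform(size=n) ** 3,
                                   rng.uniform(size=n) ** 3,
                                   rng.normal(size=n), chrom=chrom))
        res = pd.concat(frames, ignore_index=True)
        a = dmrs_to_frame(call_dmrs(res))
        res2 = pd.concat(frames[::-1], ignore_index=True)
        b = dmrs_to_frame(call_dmrs(res2))
        a = a.sort_values(["chrom", "start"]).reset_index(drop=True)
        b = b.sort_values(["chrom", "start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_every_dmr_has_seed_and_homogeneous_direction(self, default_run):
        results = default_run["results"]
        by_key = {(c, p): s for c, p, s in zip(
            results["chrom"], results["pos"], np.sign(results["beta"]))}
        for d in default_run["dmrs"]:
            assert d.n_cpgs >= 3
            assert d.n_seeds >= 1
            want = 1 if d.direction == "hyper" else -1
            assert all(by_key[(d.chrom, p)] == want for p in d.member_pos)


class TestDirectionalFilter:
    def _study(self, means, cov=400):
        """Four-group toy study with fixed pooled group means at one CpG."""
        groups = (["negative"] * 5 + ["medium"] * 5 + ["high"] * 5
                  + ["ra"] * 4)
        n = len(groups)
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "acpa_od": [10] * 5 + [40] * 5 + [80] * 5 + [40] * 4,
            "acpa_group": ["negative"] * 5 + ["medium"] * 5 + ["high"] * 5
            + ["medium"] * 4,
            "ra": [False] * 15 + [True] * 4,
            "age": 50.0, "sex": "F", "smoking": "never",
        })
        for c, v in zip(["monocyte", "lymphocyte", "neutrophil",
                         "eosinophil", "basophil"],
                        [0.07, 0.30, 0.575, 0.045, 0.01]):
            samples[f"prop_{c}"] = v
        meth = np.zeros((1, n), dtype=int)
        total = np.full((1, n), cov, dtype=int)
        for gi, gname in enumerate(["negative", "medium", "high", "ra"]):
            mask = [g == gname for g in groups]
            meth[0, np.asarray(mask)] = int(round(means[gi] * cov))
        m = MethylationMatrix(["chr1"], [100], meth, total,
                              list(samples["sample_id"]))
        dmcs = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        return m, samples, dmcs

    def test_decreasing_means_with_ra_extension_is_hypo_consistent(self):
        m, s, dmcs = self._study([0.50, 0.45, 0.40, 0.35])
        out = directional_filter(m, s, dmcs)
        assert out.loc[0, "direction"] == "hypo"
        assert bool(out.loc[0, "ra_consistent"])

    def test_equal_means_give_direction_none(self):
        m, s, dmcs = self._study([0.5, 0.5, 0.5, 0.5])
        out = directional_filter(m, s, dmcs)
        assert out.loc[0, "direction"] == "none"
        assert not bool(out.loc[0, "ra_consistent"])

    def test_non_monotone_means_give_none(self):
        m, s, dmcs = self._study([0.50, 0.55, 0.52, 0.60])
        out = directional_filter(m, s, dmcs)
        assert out.loc[0, "direction"] == "none"

    def test_ra_breaking_trend_not_consistent(self):
        m, s, dmcs = self._study([0.40, 0.45, 0.50, 0.30])
        out = directional_filter(m, s, dmcs)
        assert out.loc[0, "direction"] == "hyper"
        assert not bool(out.loc[0, "ra_consistent"])

    def test_missing_group_errors(self):
        m, s, dmcs = self._study([0.5, 0.45, 0.4, 0.35])
        s2 = s[s["acpa_group"] != "high"].reset_index(drop=True)
        m2 = m.subset_samples([g != "high" for g in s["acpa_group"]])
        with pytest.raises(ValueError, match="high"):
            directional_filter(m2, s2, dmcs)

    def test_planted_dose_regions_are_directional_and_ra_consistent(
            self, default_run):
        m_filt = default_run["m_filt"]
        samples = default_run["samples"]
        truth = default_run["truth"]
        planted = []
        for chrom, start, end, direction, mech in truth.true_dmr_intervals:
            if mech != "dose":
                continue
            sel = (m_filt.chrom == chrom) & (m_filt.pos >= start) \
                & (m_filt.pos <= end)
            for p in m_filt.pos[sel]:
                planted.append((chrom, p, direction))
        dmcs = pd.DataFrame({"chrom": [t[0] for t in planted],
                             "pos": [t[1] for t in planted]})
        calls = directional_filter(m_filt, samples, dmcs)
        agree = np.mean([c == d for c, d in zip(calls["direction"],
                                                [t[2] for t in planted])])
        assert agree > 0.6
        dir_calls = calls[calls["direction"] != "none"]
        assert dir_calls["ra_consistent"].mean() > 0.7


class TestSetComparisons:
    def test_identical_sets(self):
        shared, a_only, b_only, j = compare_sets({1, 2}, {1, 2})
        assert shared == {1, 2} and not a_only and not b_only and j == 1.0

    def test_disjoint_sets(self):
        shared, a_only, b_only, j = compare_sets({1}, {2})
        assert not shared and j == 0.0

    def test_interval_overlap_pairing(self):
        a = [DmrRecord("chr1", 100, 200, [100, 150, 200], "hyper", 0, 0, 1)]
        b = [DmrRecord("chr1", 150, 300, [150, 300, 250], "hyper", 0, 0, 1),
             DmrRecord("chr2", 150, 300, [150, 300, 250], "hyper", 0, 0, 1)]
        shared, a_only, b_only, frac = compare_dmr_sets(a, b)
        assert shared == [(0, 0)]
        assert a_only == [] and b_only == [1]
        assert abs(frac - 2 / 3) < 1e-12
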