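import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chemgenfit import diffit, synthpool as sp


# ---------------------------------------------------------------------------
# independent oracles


def tmm_factor_oracle(obs, ref, trim_m=0.30, trim_a=0.05):
    """Direct weighted-trimmed-mean-of-M evaluation, written independently
    of the pipeline code path (explicit python loops)."""
    n_obs, n_ref = float(sum(obs)), float(sum(ref))
    rows = []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m = np.log2((o / n_obs) / (r / n_ref))
            a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
            w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
            rows.append((m, a, w))
    n = len(rows)
    lo_m, hi_m = int(np.floor(n * trim_m)), n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)), n - int(np.floor(n * trim_a))
    order_m = sorted(range(n), key=lambda i: rows[i][0])
    order_a = sorted(range(n), key=lambda i: rows[i][1])
    rank_m = {i: k for k, i in enumerate(order_m)}
    rank_a = {i: k for k, i in enumerate(order_a)}
    num = den = 0.0
    for i, (m, a, w) in enumerate(rows):
        if lo_m <= rank_m[i] < hi_m and lo_a <= rank_a[i] < hi_a:
            num += w * m
            den += w
    return 2 ** (num / den) if den > 0 else 1.0


def bh_oracle(p):
    """Literal step-up definition: q_i = min over p_(j) >= p_i of m p_(j)/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, m * p[i] / (rank + 1))
        q[i] = running
    return q


# ---------------------------------------------------------------------------
# TMM


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 40], "b": [10, 20, 30, 40]},
                              index=list("wxyz"))
        norm = diffit.tmm_factors(counts)
        assert norm.factors.to_numpy() == pytest.approx([1.0, 1.0])

    def test_pure_depth_change_is_absorbed(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 40], "b": [20, 40, 60, 80]},
                              index=list("wxyz"))
        norm = diffit.tmm_factors(counts)
        assert norm.factors.to_numpy() == pytest.approx([1.0, 1.0])

    def test_geometric_mean_is_one(self, planted_dataset):
        norm = diffit.tmm_factors(planted_dataset["counts"])
        assert np.exp(np.mean(np.log(norm.factors))) == pytest.approx(1.0)
        assert (norm.factors > 0).all()

    def test_toy_inflated_gene_matches_oracle(self):
        a = [100, 200, 300, 150, 120, 80, 60, 500]
        b = [100, 200, 300, 150, 120, 80, 60, 5000]
        counts = pd.DataFrame({"a": a, "b": b})
        norm = diffit.tmm_factors(counts, reference="a")
        expected = tmm_factor_oracle(b, a)
        got = norm.factors["b"] / norm.factors["a"]
        assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g = rng.integers(10, 60)
            a = rng.poisson(rng.uniform(5, 200), g) + 1
            b = (a * np.exp(rng.normal(0, 0.3, g))).astype(int) + 1
            counts = pd.DataFrame({"a": a, "b": b})
            norm = diffit.tmm_factors(counts, reference="a")
            expected = tmm_factor_oracle(b, a)
            assert (norm.factors["b"] / norm.factors["a"]
                    == pytest.approx(expected, abs=1e-9))

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero library"):
            diffit.tmm_factors(counts)

    def test_sample_permutation_equivariance(self, planted_dataset):
        counts = planted_dataset["counts"]
        norm = diffit.tmm_factors(counts)
        perm = list(counts.columns[::-1])
        norm_p = diffit.tmm_factors(counts[perm])
        pd.testing.assert_series_equal(norm.factors.sort_index(),
                                       norm_p.factors.sort_index())


# ---------------------------------------------------------------------------
# dispersion


class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        cat = sp.generate_catalog(2000, 10, seed=1)
        cfg = sp.TruthConfig(fractions={"neutral": 1.0, "beneficial-only": 0,
                                        "deleterious-only": 0,
                                        "antagonistic": 0}, dispersion=0.0)
        truth = sp.generate_truth(cat, ["a"], cfg, seed=2)
        design = sp.generate_design(["a"], 3, seed=3)
        cm = sp.simulate_counts(cat, design, truth, depth=1_000_000, seed=4,
                                batch_sigma=0.0)
        norm = diffit.tmm_factors(cm.counts)
        disp = diffit.estimate_dispersion(cm.counts, design, norm, "a")
        assert np.nanmedian(disp.trend) <= 0.01

    def test_nb_dispersion_recovered(self):
        cat = sp.generate_catalog(2000, 10, seed=5)
        cfg = sp.TruthConfig(fractions={"neutral": 1.0, "beneficial-only": 0,
                                        "deleterious-only": 0,
                                        "antagonistic": 0}, dispersion=0.2)
        truth = sp.generate_truth(cat, ["a"], cfg, seed=6)
        design = sp.generate_design(["a"], 3, seed=7)
        cm = sp.simulate_counts(cat, design, truth, depth=1_000_000, seed=8,
                                batch_sigma=0.0)
        norm = diffit.tmm_factors(cm.counts)
        disp = diffit.estimate_dispersion(cm.counts, design, norm, "a")
        assert 0.1 <= np.nanmedian(disp.trend) <= 0.3
        assert 0.1 <= np.nanmedian(disp.shrunk) <= 0.3

    def test_all_zero_gene_flagged_untestable(self, planted_dataset):
        counts = planted_dataset["counts"].copy()
        counts.iloc[0, :] = 0
        design = planted_dataset["design"]
        norm = diffit.tmm_factors(counts)
        disp = diffit.estimate_dispersion(counts, design, norm, "c0")
        assert np.isnan(disp.gene.iloc[0])
        assert np.isnan(disp.shrunk.iloc[0])
        assert disp.gene.notna().sum() >= len(counts) - 5


# ---------------------------------------------------------------------------
# testing


class TestFitTest:
    def test_identical_treatment_and_control_is_null(self):
        genes = [f"g{i}" for i in range(80)]
        rng = np.random.default_rng(1)
        base = rng.poisson(200, (80, 3))
        cols = {}
        design_rows = []
        for r in range(1, 4):
            cols[f"a_ctrl_{r}"] = base[:, r - 1]
            cols[f"a_trt_{r}"] = base[:, r - 1]
            for role, sid in (("control", f"a_ctrl_{r}"),
                              ("treatment", f"a_trt_{r}")):
                design_rows.append({"sample_id": sid, "compound": "a",
                                    "role": role, "pair_id": f"p{r}",
                                    "batch": f"b{r}", "replicate": r,
                                    "generations": 8.0})
        counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
        design = pd.DataFrame(design_rows)
        norm = diffit.tmm_factors(counts)
        disp = diffit.estimate_dispersion(counts, design, norm, "a")
        res = diffit.fit_test(counts, design, norm, disp, "a")
        assert np.allclose(res["log2_effect"], 0.0, atol=1e-6)
        assert (res["p_value"] >= 0.99).all()

    def test_planted_effect_recovered_with_sign(self, planted_dataset,
                                                planted_fitness):
        truth = planted_dataset["truth"]
        design = planted_dataset["design"]
        t = planted_fitness.table.set_index(["gene", "inhibitor"])
        gmean = design.groupby("compound")["generations"].mean()
        strong = []
        for c in truth.s.columns:
            s = truth.s[c]
            for g in s.index[(s.abs() * gmean[c]) >= 3]:
                strong.append((g, c))
        sub = t.loc[strong]
        assert (sub["q_value"] < 0.05).mean() >= 0.9
        hit = sub[sub["significant"]]
        planted_sign = np.sign([truth.s.loc[g, c] for g, c in hit.index])
        assert (np.sign(hit["log2_effect"]) == planted_sign).all()

    def test_type_one_error_calibrated(self):
        cat = sp.generate_catalog(2000, 10, seed=9)
        cfg = sp.TruthConfig(fractions={"neutral": 1.0, "beneficial-only": 0,
                                        "deleterious-only": 0,
                                        "antagonistic": 0})
        truth = sp.generate_truth(cat, ["a"], cfg, seed=10)
        design = sp.generate_design(["a"], 3, seed=11)
        cm = sp.simulate_counts(cat, design, truth, depth=500_000, seed=12)
        norm = diffit.tmm_factors(cm.counts)
        disp = diffit.estimate_dispersion(cm.counts, design, norm, "a")
        res = diffit.fit_test(cm.counts, design, norm, disp, "a")
        p = res["p_value"].dropna()
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_paired_beats_unpaired_with_batch_effects(self):
        wins = []
        for seed in range(5):
            cat = sp.generate_catalog(500, 10, seed=seed)
            cfg = sp.TruthConfig(effect_low=0.15, effect_high=0.3)
            truth = sp.generate_truth(cat, ["a", "b"], cfg, seed=seed + 50)
            design = sp.generate_design(["a", "b"], 3, seed=seed + 100)
            cm = sp.simulate_counts(cat, design, truth, depth=400_000,
                                    seed=seed + 150, batch_sigma=0.4)
            norm = diffit.tmm_factors(cm.counts)
            affected = truth.s.index[truth.s["a"].abs() > truth.effect_floor]
            power = {}
            for paired in (True, False):
                disp = diffit.estimate_dispersion(cm.counts, design, norm,
                                                  "a", paired=paired)
                res = diffit.fit_test(cm.counts, design, norm, disp, "a",
                                      paired=paired)
                q = diffit.bh_adjust(res["p_value"])
                sig = set(res.index[q < 0.05])
                power[paired] = len(sig & set(affected)) / len(affected)
            wins.append(power[True] - power[False])
        assert np.mean(wins) > 0
        assert sum(w > 0 for w in wins) >= 4

    def test_design_validation_errors(self, planted_dataset):
        counts = planted_dataset["counts"]
        norm = diffit.tmm_factors(counts)
        design = planted_dataset["design"]
        # paired controls missing for referenced pair ids
        broken = design[~((design["compound"] == "c0")
                          & (design["role"] == "control"))]
        with pytest.raises(ValueError, match="missing paired controls"):
            diffit.build_contrast(counts, broken, norm, "c0")
        # unknown inhibitor
        with pytest.raises(ValueError, match="not in design"):
            diffit.build_contrast(counts, design, norm, "nope")
        # fewer than 2 treatment replicates
        single = design[design["sample_id"].isin(["c0_ctrl_1", "c0_trt_1"])]
        with pytest.raises(ValueError, match=">= 2 treatment"):
            diffit.build_contrast(counts, single, norm, "c0")


# ---------------------------------------------------------------------------
# BH and table assembly


class TestBH:
    def test_textbook_example(self):
        q = diffit.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert diffit.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_significance_boundary_is_strict(self):
        sig_q = 0.049
        not_q = 0.051
        assert sig_q < 0.05 and not not_q < 0.05

    def test_nan_propagates_and_is_excluded(self):
        q = diffit.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.02)  # m=2, not 3

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_step_up_oracle(self, p):
        q = diffit.bh_adjust(p)
        expect = bh_oracle(p)
        assert np.allclose(q, expect, atol=1e-12)
        # order preserving and >= p
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, p))


class TestFitnessTable:
    def test_toy_union_and_counts(self):
        genes = ["g1", "g2", "g3", "g4", "g5"]
        mk = lambda sig: pd.DataFrame(
            {"log2_effect": [sig.get(g, (0, 1))[0] for g in genes],
             "p_value": [sig.get(g, (0, 1))[1] for g in genes]},
            index=pd.Index(genes, name="gene"))
        results = {"A": mk({"g1": (1.5, 1e-6), "g2": (-2.0, 1e-5)}),
                   "B": mk({"g2": (1.0, 1e-6)})}
        ft = diffit.build_fitness_table(results, fdr=0.05)
        assert ft.significant_union == ["g1", "g2"]
        per = ft.per_inhibitor.set_index("inhibitor")
        assert per.loc["A", "n_significant"] == 2
        assert per.loc["A", "n_beneficial"] == 1
        assert per.loc["B", "n_deleterious"] == 0
        t = ft.table.set_index(["gene", "inhibitor"])
        assert t.loc[("g2", "A"), "direction"] == "deleterious"
        assert t.loc[("g2", "B"), "direction"] == "beneficial"

    def test_invariants_hold(self, planted_fitness):
        t = planted_fitness.table
        ok = t["q_value"].notna()
        assert (t.loc[ok, "q_value"] >= t.loc[ok, "p_value"] - 1e-12).all()
        assert (t.loc[t["significant"], "q_value"] < 0.05).all()
        ben = t["direction"] == "beneficial"
        assert (t.loc[ben, "log2_effect"] > 0).all()
        dele = t["direction"] == "deleterious"
        assert (t.loc[dele, "log2_effect"] < 0).all()
        # q monotone in p within each inhibitor
        for _, part in t.dropna(subset=["p_value"]).groupby("inhibitor"):
            part = part.sort_values("p_value")
            assert part["q_value"].is_monotonic_increasing

    def test_empty_union_handled(self):
        genes = ["g1", "g2"]
        df = pd.DataFrame({"log2_effect": [0.0, 0.0], "p_value": [0.9, 0.8]},
                          index=pd.Index(genes, name="gene"))
        ft = diffit.build_fitness_table({"A": df, "B": df.copy()})
        assert ft.significant_union == []

    def test_inconsistent_universe_rejected(self):
        a = pd.DataFrame({"log2_effect": [0.0], "p_value": [0.5]},
                         index=pd.Index(["g1"], name="gene"))
        b = pd.DataFrame({"log2_effect": [0.0], "p_value": [0.5]},
                         index=pd.Index(["g2"], name="gene"))
        with pytest.raises(ValueError, match="universe"):
            diffit.build_fitness_table({"A": a, "B": b})

    def test_union_tracks_planted_nonneutral(self, planted_dataset,
                                             planted_fitness):
        planted = (planted_dataset["truth"].gene_class != "neutral").sum()
        union = len(planted_fitness.significant_union)
        assert abs(union - planted) / planted <= 0.15
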