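import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from panrx.cohort import HistotypeAnnotation
from panrx.features import (
    FeatureSet,
    bonferroni_threshold,
    encode_histotype,
    make_control_features,
    moderated_t_statistics,
    select_bootstrap,
    select_moderated_t,
    select_mrmr,
    shuffle_matrix,
    spearman_screen,
)


def _xy(rng, n=50, m=20, signal_col=None):
    X = pd.DataFrame(
        rng.normal(size=(n, m)), columns=[f"P{j}" for j in range(m)],
        index=[f"c{i}" for i in range(n)],
    )
    y = pd.Series(rng.normal(size=n), index=X.index)
    if signal_col is not None:
        X[signal_col] = y.values
    return X, y


class TestSpearmanScreen:
    def test_probe_identical_to_y_selected(self, rng):
        X, y = _xy(rng, signal_col="P3")
        screen, fs = spearman_screen(X, y)
        assert "P3" in fs.probe_ids
        assert screen.p["P3"] == pytest.approx(0.0, abs=1e-12)

    def test_null_selection_rate(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 2000)))
        X.columns = [f"P{j}" for j in range(2000)]
        y = pd.Series(rng.normal(size=100), index=X.index)
        _, fs = spearman_screen(X, y)
        band = 2.576 * np.sqrt(2000 * 0.05 * 0.95)
        assert abs(fs.n_features - 100) < band

    def test_sign_flip_same_selection(self, rng):
        X, y = _xy(rng)
        _, a = spearman_screen(X, y)
        _, b = spearman_screen(X, -y)
        assert a.probe_ids == b.probe_ids

    def test_constant_probe_gets_p_one(self, rng):
        X, y = _xy(rng)
        X["P0"] = 5.0
        screen, fs = spearman_screen(X, y)
        assert screen.p["P0"] == 1.0
        assert "P0" not in fs.probe_ids

    def test_constant_y_hard_error(self, rng):
        X, _ = _xy(rng)
        with pytest.raises(ValueError, match="constant"):
            spearman_screen(X, pd.Series(1.0, index=X.index))

    def test_too_few_cells_rejected(self, rng):
        X, y = _xy(rng, n=4)
        with pytest.raises(ValueError, match="at least 5"):
            spearman_screen(X, y)


class TestBonferroni:
    def test_array_scale_feature_count(self):
        # 0.05 / 49386 to two significant figures
        cutoff = bonferroni_threshold(0.05, 49386)
        assert float(f"{cutoff:.1e}") == 1.0e-6

    def test_identity_case(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_direct_division(self):
        assert bonferroni_threshold(0.05, 500) == pytest.approx(1.0e-4)

    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_bc_subset_of_deg(self, rng):
        X, y = _xy(rng, n=60, m=300, signal_col="P7")
        _, deg = spearman_screen(X, y, alpha=0.05)
        _, bc = spearman_screen(X, y, alpha=bonferroni_threshold(0.05, 300), method="BC")
        assert set(bc.probe_ids) <= set(deg.probe_ids)
        assert bc.n_features <= deg.n_features <= 300


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self, rng):
        Xh = rng.normal(size=(8, 30))
        Xl = rng.normal(loc=0.3, size=(7, 30))
        t_mod, _, _ = moderated_t_statistics(Xh, Xl, d0_override=0.0)
        t_ref = stats.ttest_ind(Xh, Xl, axis=0, equal_var=True).statistic
        np.testing.assert_allclose(t_mod, t_ref, rtol=1e-12)

    def test_hand_oracle_six_cells(self):
        # 6 cells, 4 probes with hand-set per-probe scales (variances spread
        # over orders of magnitude so the prior df is finite): recompute
        # every shrinkage quantity step by step, scalar arithmetic only
        scales = np.array([0.05, 0.3, 1.0, 5.0])
        mh = np.array([1.0, 2.0, 0.0, 5.0])
        ml = np.array([0.0, 1.0, 4.0, 1.0])
        pattern = np.array([-1.0, 0.0, 1.0])
        Xh = mh + np.outer(pattern, scales)
        Xl = ml + np.outer(pattern, scales)
        t_mod, p_mod, d0 = moderated_t_statistics(Xh, Xl)

        d = 4  # 3 + 3 - 2
        for g in range(4):
            s2 = (np.var(Xh[:, g], ddof=1) * 2 + np.var(Xl[:, g], ddof=1) * 2) / d
            # prior fitted on all four log variances
            s2_all = np.array(
                [
                    (np.var(Xh[:, j], ddof=1) * 2 + np.var(Xl[:, j], ddof=1) * 2) / d
                    for j in range(4)
                ]
            )
            e = np.log(s2_all) - special.digamma(d / 2) + np.log(d / 2)
            evar = e.var(ddof=1) - special.polygamma(1, d / 2)
            assert evar > 0  # hand-set variances are spread out
            # invert trigamma by bisection, independently of the package
            lo, hi = 1e-6, 1e6
            for _ in range(200):
                mid = np.sqrt(lo * hi)
                if special.polygamma(1, mid) > evar:
                    lo = mid
                else:
                    hi = mid
            d0_ref = 2 * lo
            s0sq = np.exp(e.mean() + special.digamma(d0_ref / 2) - np.log(d0_ref / 2))
            assert d0 == pytest.approx(d0_ref, rel=1e-3)
            s2_tilde = (d0_ref * s0sq + d * s2) / (d0_ref + d)
            t_ref = (Xh[:, g].mean() - Xl[:, g].mean()) / np.sqrt(s2_tilde * (2 / 3))
            assert t_mod[g] == pytest.approx(t_ref, rel=1e-3)
            p_ref = 2 * stats.t.sf(abs(t_ref), df=d + d0_ref)
            assert p_mod[g] == pytest.approx(p_ref, rel=1e-3)

    def test_null_fdr_controlled(self, rng):
        fracs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(40, 300)))
            X.columns = [f"P{j}" for j in range(300)]
            y = pd.Series(r.normal(size=40), index=X.index)
            fs = select_moderated_t(X, y)
            fracs.append(fs.n_features / 300)
        assert np.mean(fracs) <= 0.05

    def test_tail_too_small_rejected(self, rng):
        X, y = _xy(rng, n=8)
        with pytest.raises(ValueError, match="tail"):
            select_moderated_t(X, y, tail_frac=0.25)


class TestBootstrap:
    def test_perfect_probe_selected_both_modes(self, rng):
        X, y = _xy(rng, n=60, m=10, signal_col="P0")
        ann = HistotypeAnnotation(
            pd.Series([f"h{i % 12}" for i in range(60)], index=X.index)
        )
        bs = select_bootstrap(X, y, n_boot=20, seed=0)
        assert "P0" in bs.probe_ids and bs.method == "BS"
        bsh = select_bootstrap(
            X, y, n_boot=20, consensus=0.5, stratify_histotype=True,
            annotation=ann, seed=0,
        )
        assert "P0" in bsh.probe_ids and bsh.method == "BS_HIST"

    def test_pure_noise_probe_never_survives_full_consensus(self):
        hits = 0
        for trial in range(100):
            r = np.random.default_rng(trial)
            X = pd.DataFrame({"P0": r.normal(size=30)}, index=[f"c{i}" for i in range(30)])
            y = pd.Series(r.normal(size=30), index=X.index)
            fs = select_bootstrap(X, y, n_boot=20, seed=trial)
            hits += fs.n_features
        assert hits == 0

    def test_bs_subset_of_deg(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(60, 100)))
            X.columns = [f"P{j}" for j in range(100)]
            X["P1"] += 0.0
            y = pd.Series(X["P2"].values + r.normal(scale=1.0, size=60), index=X.index)
            _, deg = spearman_screen(X, y)
            bs = select_bootstrap(X, y, n_boot=20, seed=seed)
            assert set(bs.probe_ids) <= set(deg.probe_ids)

    def test_bad_consensus_rejected(self, rng):
        X, y = _xy(rng)
        with pytest.raises(ValueError, match="consensus"):
            select_bootstrap(X, y, consensus=0.0)

    def test_hist_subsets_one_cell_per_histotype(self, rng):
        # the histotype mode builds subsets of size = number of histotypes;
        # with 12 histotypes, subsets are below the screen minimum of 5 never
        X, y = _xy(rng, n=36, m=5)
        ann = HistotypeAnnotation(
            pd.Series([f"h{i % 12}" for i in range(36)], index=X.index)
        )
        fs = select_bootstrap(
            X, y, n_boot=10, consensus=0.5, stratify_histotype=True,
            annotation=ann, seed=1,
        )
        assert fs.params["consensus"] == 0.5


def _greedy_oracle(X: pd.DataFrame, y: pd.Series, k: int) -> list[str]:
    """Brute-force greedy path on the published criterion, scipy per pair."""
    cols = list(X.columns)
    chosen: list[str] = []
    while len(chosen) < k:
        best, best_score = None, -np.inf
        for c in cols:
            if c in chosen:
                continue
            rel = abs(stats.spearmanr(X[c], y).statistic)
            if chosen:
                red = np.mean(
                    [abs(stats.spearmanr(X[c], X[s]).statistic) for s in chosen]
                )
                score = rel - red
            else:
                score = rel
            if score > best_score + 1e-12:
                best, best_score = c, score
        chosen.append(best)
    return chosen


class TestMRMR:
    def test_k1_is_max_relevance(self, rng):
        X, y = _xy(rng, n=40, m=8)
        fs = select_mrmr(X, y, k=1)
        rel = {c: abs(stats.spearmanr(X[c], y).statistic) for c in X.columns}
        assert fs.probe_ids == [max(rel, key=rel.get)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_greedy(self, seed):
        r = np.random.default_rng(seed)
        X = pd.DataFrame(r.normal(size=(30, 8)), columns=[f"P{j}" for j in range(8)])
        y = pd.Series(X["P0"].values + r.normal(scale=0.5, size=30), index=X.index)
        fs = select_mrmr(X, y, k=3)
        assert fs.probe_ids == _greedy_oracle(X, y, 3)

    def test_duplicate_probe_not_picked_second(self, rng):
        # P0 is the most relevant probe and P1 its exact duplicate; P2 has
        # genuine relevance beyond P0, i.e. a positive margin, so the
        # redundancy penalty (rel - 1 for the duplicate) excludes P1
        X, y = _xy(rng, n=40, m=6)
        y = pd.Series(X["P0"].values + 0.4 * rng.normal(size=40), index=X.index)
        X["P1"] = X["P0"]
        X["P2"] = y.values + 0.8 * rng.normal(size=40)
        fs = select_mrmr(X, y, k=2)
        assert fs.probe_ids[0] in ("P0", "P1")
        assert fs.probe_ids[1] not in ("P0", "P1")

    def test_k_too_large_rejected(self, rng):
        X, y = _xy(rng, m=5)
        with pytest.raises(ValueError, match="exceeds"):
            select_mrmr(X, y, k=6)


class TestControls:
    def test_empty_reference(self):
        probes = [f"P{j}" for j in range(10)]
        empty = FeatureSet("DEG", [])
        assert make_control_features(probes, empty, "CTR1").probe_ids == []
        assert make_control_features(probes, empty, "CTR2").probe_ids == probes

    def test_cardinalities(self, rng):
        probes = [f"P{j}" for j in range(100)]
        ref = FeatureSet("DEG", probes[:30])
        assert make_control_features(probes, ref, "CTR1", seed=1).n_features == 30
        assert make_control_features(probes, ref, "CTR2").n_features == 70

    def test_ctr1_reproducible_and_unrestricted(self):
        probes = [f"P{j}" for j in range(50)]
        ref = FeatureSet("DEG", probes[:25])
        a = make_control_features(probes, ref, "CTR1", seed=3)
        b = make_control_features(probes, ref, "CTR1", seed=3)
        assert a.probe_ids == b.probe_ids
        # CTR1 draws from ALL probes, so overlap with the reference occurs
        overlaps = [
            len(set(make_control_features(probes, ref, "CTR1", seed=s).probe_ids)
                & set(ref.probe_ids))
            for s in range(20)
        ]
        assert max(overlaps) > 0

    def test_ctr2_disjoint_from_reference(self):
        probes = [f"P{j}" for j in range(40)]
        ref = FeatureSet("DEG", probes[5:15])
        ctr2 = make_control_features(probes, ref, "CTR2")
        assert not set(ctr2.probe_ids) & set(ref.probe_ids)


class TestShuffleMatrix:
    def test_columns_are_permutations(self, rng):
        X, _ = _xy(rng, n=30, m=10)
        shuffled, fs = shuffle_matrix(X, 5, seed=2)
        assert fs.method == "RCTR" and shuffled.shape == (30, 5)
        for c in shuffled.columns:
            assert sorted(shuffled[c]) == pytest.approx(sorted(X[c]))

    def test_seed_reproducible(self, rng):
        X, _ = _xy(rng)
        a, _ = shuffle_matrix(X, 4, seed=9)
        b, _ = shuffle_matrix(X, 4, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_breaks_association(self, rng):
        # a probe equal to y becomes uninformative after shuffling
        X, y = _xy(rng, n=200, m=3, signal_col="P0")
        rhos = []
        for seed in range(30):
            shuffled, _ = shuffle_matrix(X[["P0"]], 1, seed=seed)
            rhos.append(stats.spearmanr(shuffled["P0"], y).statistic)
        assert abs(np.mean(rhos)) < 0.05


class TestEncodeHistotype:
    def test_rows_sum_to_one(self):
        ann = HistotypeAnnotation(pd.Series({"a": "x", "b": "y", "c": "x", "d": "z"}))
        onehot = encode_histotype(ann, ["a", "b", "c", "d"])
        assert (onehot.sum(axis=1) == 1).all()

    def test_three_cell_example(self):
        ann = HistotypeAnnotation(pd.Series({"c1": "a", "c2": "b", "c3": "a"}))
        onehot = encode_histotype(ann, ["c1", "c2", "c3"])
        np.testing.assert_array_equal(
            onehot.to_numpy(), [[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]]
        )
        assert list(onehot.columns) == ["a", "b"]

    def test_column_sums_equal_counts(self, rng):
        labels = pd.Series(
            rng.choice(["x", "y", "z"], size=30), index=[f"c{i}" for i in range(30)]
        )
        ann = HistotypeAnnotation(labels)
        onehot = encode_histotype(ann, labels.index)
        for h in ("x", "y", "z"):
            assert onehot[h].sum() == (labels == h).sum()

    def test_unlabeled_cell_hard_error(self):
        ann = HistotypeAnnotation(pd.Series({"a": "x"}))
        with pytest.raises(KeyError, match="without histotype"):
            encode_histotype(ann, ["a", "missing"])
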