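"""Rank tests vs references, compact letters, normalization, differential binding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cobind.io_formats import CountMatrix, GenomicInterval, Peak
from cobind.occupancy_stats import (
    _letters_insert_absorb,
    differential_binding,
    kruskal_wallis,
    normalize_counts,
    pairwise_letters,
    stratify_by_motif_count,
    wilcoxon_rank_sum,
)


def _peaks_with_scores(scores):
    return [
        Peak(f"p{i}", GenomicInterval("c", i * 10, i * 10 + 5), score=s)
        for i, s in enumerate(scores)
    ]


class TestStratify:
    def test_pooling_above_max_group(self):
        peaks = _peaks_with_scores([1.0, 2.0, 3.0, 4.0])
        counts = {"p0": 0, "p1": 1, "p2": 1, "p3": 5}
        groups = stratify_by_motif_count(peaks, counts, max_group=2)
        assert set(groups) == {"0", "1", ">=2"}
        assert groups["1"] == [2.0, 3.0] and groups[">=2"] == [4.0]

    def test_group_sizes_conserve_peaks(self):
        rng = np.random.default_rng(0)
        peaks = _peaks_with_scores(rng.random(200))
        counts = {p.id: int(rng.integers(0, 6)) for p in peaks}
        groups = stratify_by_motif_count(peaks, counts, max_group=3)
        assert sum(len(v) for v in groups.values()) == len(peaks)

    def test_single_group_refused_downstream(self):
        peaks = _peaks_with_scores([1.0, 2.0])
        groups = stratify_by_motif_count(peaks, {"p0": 1, "p1": 1}, max_group=3)
        with pytest.raises(ValueError):
            pairwise_letters(groups)


class TestRankTests:
    def test_kruskal_wallis_worked_example(self):
        h, p = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert h == pytest.approx(3.857, abs=5e-4)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_identical_groups_give_zero_h(self):
        h, p = kruskal_wallis({"a": [2, 2, 2], "b": [2, 2, 2]})
        assert h == 0.0 and p == 1.0

    def test_kruskal_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = {
                str(i): rng.integers(0, 12, size=int(rng.integers(3, 12))).tolist()
                for i in range(k)
            }
            try:
                ref = sps.kruskal(*groups.values())
            except ValueError:  # all values identical
                continue
            h, p = kruskal_wallis(groups)
            assert abs(h - ref.statistic) < 1e-10
            assert abs(p - ref.pvalue) < 1e-10

    def test_wilcoxon_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            x = rng.integers(0, 10, size=int(rng.integers(3, 15))).tolist()
            y = rng.integers(0, 10, size=int(rng.integers(3, 15))).tolist()
            ref = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            _, p = wilcoxon_rank_sum(x, y)
            assert abs(p - ref.pvalue) < 1e-10

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(23)
        ps = []
        for _ in range(400):
            pooled = rng.normal(size=20)
            _, p = kruskal_wallis({"a": pooled[:10], "b": pooled[10:]})
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 1e-3


class TestLetters:
    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(3)
        groups = {"lo": rng.normal(0, 1, 50).tolist(), "hi": rng.normal(10, 1, 50).tolist()}
        res = pairwise_letters(groups)
        assert set(res.letters["lo"]).isdisjoint(res.letters["hi"])

    def test_identical_distributions_share_a_letter(self):
        rng = np.random.default_rng(4)
        pooled = rng.normal(size=90)
        groups = {"a": pooled[:30], "b": pooled[30:60], "c": pooled[60:]}
        res = pairwise_letters(groups)
        assert set(res.letters["a"]) & set(res.letters["b"]) & set(res.letters["c"])

    def test_letter_invariant_holds_on_result(self):
        rng = np.random.default_rng(5)
        groups = {
            "0": rng.normal(0, 1, 40).tolist(),
            "1": rng.normal(0.7, 1, 40).tolist(),
            "2": rng.normal(1.4, 1, 40).tolist(),
            "3": rng.normal(5, 1, 40).tolist(),
        }
        res = pairwise_letters(groups)
        for (a, b), padj in res.pairwise.items():
            share = bool(set(res.letters[a]) & set(res.letters[b]))
            assert share == (padj >= res.alpha)

    def test_insert_absorb_on_fuzzed_significance(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            labels = [str(i) for i in range(int(rng.integers(2, 7)))]
            sig = {}
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    sig[(a, b)] = bool(rng.random() < 0.4)
            letters = _letters_insert_absorb(labels, sig)
            for (a, b), s in sig.items():
                share = bool(set(letters[a]) & set(letters[b]))
                assert share != s


class TestNormalization:
    def _cm(self, arr, conds=("a", "a", "b", "b")):
        df = pd.DataFrame(
            np.asarray(arr), columns=[f"s{i}" for i in range(len(conds))]
        )
        df.index = [f"p{i}" for i in range(df.shape[0])]
        return CountMatrix(counts=df, condition_of={f"s{i}": c for i, c in enumerate(conds)})

    def test_identical_columns_unit_factors(self):
        cm = self._cm([[10, 10], [5, 5]], conds=("a", "b"))
        sf, norm = normalize_counts(cm)
        assert np.allclose(sf, 1.0)
        assert norm.equals(cm.counts / 1.0)

    def test_scaled_column_scaled_factor(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 200, size=50)
        cm = self._cm(np.column_stack([base, base * 2]), conds=("a", "b"))
        sf, _ = normalize_counts(cm)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        arr = rng.integers(0, 100, size=(40, 4))
        sf1, _ = normalize_counts(self._cm(arr))
        sf2, _ = normalize_counts(self._cm(arr[rng.permutation(40)]))
        assert np.allclose(sf1.to_numpy(), sf2.to_numpy())

    def test_fallback_to_library_size_with_warning(self, caplog):
        arr = [[5, 0], [0, 7]]  # no row positive everywhere
        with caplog.at_level("WARNING"):
            sf, _ = normalize_counts(self._cm(arr, conds=("a", "b")))
        assert "library-size" in caplog.text
        assert np.allclose(np.log(sf).sum(), 0.0)


class TestDifferentialBinding:
    def _simulated_cm(self, seed=0, n=400, effect=2.0, frac=0.1):
        rng = np.random.default_rng(seed)
        mu = 100.0
        delta = np.zeros(n)
        affected = rng.choice(n, size=int(n * frac), replace=False)
        delta[affected] = effect
        lam1 = rng.gamma(10, mu / 10, size=(n, 3))
        lam2 = rng.gamma(10, (mu * 2.0**delta)[:, None] / 10, size=(n, 3))
        counts = np.column_stack([rng.poisson(lam1), rng.poisson(lam2)])
        df = pd.DataFrame(counts, columns=[f"s{i}" for i in range(6)])
        df.index = [f"p{i}" for i in range(n)]
        cond = {f"s{i}": ("ctrl" if i < 3 else "mut") for i in range(6)}
        return CountMatrix(counts=df, condition_of=cond), set(f"p{i}" for i in affected)

    def test_antisymmetric_under_label_swap(self):
        cm, _ = self._simulated_cm()
        fwd = differential_binding(cm, condition_order=["ctrl", "mut"])
        rev = differential_binding(cm, condition_order=["mut", "ctrl"])
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_flat_peak_is_null(self):
        df = pd.DataFrame(
            {f"s{i}": [10, 20] for i in range(4)},
            index=["p0", "p1"],
        )
        df.loc["p1"] = [5, 8, 5, 8]  # some variation elsewhere
        cm = CountMatrix(
            counts=df, condition_of={f"s{i}": ("a" if i < 2 else "b") for i in range(4)}
        )
        res = differential_binding(cm).set_index("peak_id")
        assert res.loc["p0", "log2fc"] == 0.0
        assert res.loc["p0", "p"] >= 0.99

    def test_recovers_planted_effects(self):
        cm, affected = self._simulated_cm(seed=3)
        res = differential_binding(cm)
        sig = set(res.loc[res.significant, "peak_id"])
        assert len(sig & affected) / len(affected) >= 0.8
        assert len(sig - affected) / max(len(sig), 1) <= 0.15

    def test_welch_mode_available_and_calibrated(self):
        cm, _ = self._simulated_cm(seed=4, frac=0.0)
        res = differential_binding(cm, moderate_variance=False)
        assert res.significant.mean() <= 0.05

    def test_requires_two_replicates(self):
        df = pd.DataFrame({"s0": [1, 2], "s1": [3, 4], "s2": [5, 6]})
        df.index = ["p0", "p1"]
        cm = CountMatrix(counts=df, condition_of={"s0": "a", "s1": "a", "s2": "b"})
        with pytest.raises(ValueError, match="replicates"):
            differential_binding(cm)

    def test_bh_adjustment_is_monotone(self):
        cm, _ = self._simulated_cm(seed=5)
        res = differential_binding(cm).sort_values("p")
        assert (np.diff(res["fdr"].to_numpy()) >= -1e-12).all()
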