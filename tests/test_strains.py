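import itertools

import numpy as np
import pytest

from rdhfp.fingerprint import RatioProfile
from rdhfp.strains import (
    InferenceConfig,
    colocalization_candidates,
    min_strain_decomposition,
    min_strain_lower_bound,
    ratio_levels,
)
from rdhfp.synth import make_identifiable_strains

from oracles import exhaustive_min_strains


def profile(ratios, sample="s", below=None):
    return RatioProfile(sample_id=sample, values=dict(ratios),
                        below_detection=dict(below or {}))


class TestRatioLevels:
    def test_three_levels(self):
        ls = ratio_levels(profile({"a": 1.0, "b": 0.95, "c": 0.5, "d": 0.05}))
        assert len(ls) == 3
        assert [sorted(genes) for _, genes in ls.levels] == [["a", "b"], ["c"], ["d"]]
        assert ls.representatives[0] == pytest.approx(np.sqrt(1.0 * 0.95))

    def test_single_level(self):
        ls = ratio_levels(profile({"a": 1.0, "b": 0.99, "c": 1.01}))
        assert len(ls) == 1

    def test_empty_profile(self):
        ls = ratio_levels(profile({}))
        assert len(ls) == 0


class TestLowerBound:
    @pytest.mark.parametrize("L,expected", [(0, 0), (1, 1), (2, 2), (3, 2), (4, 3), (7, 3), (8, 4)])
    def test_formula(self, L, expected):
        ls = ratio_levels(profile({f"g{i}": 10.0 ** (-i) for i in range(L)}))
        assert len(ls) == L
        assert min_strain_lower_bound(ls) == expected

    def test_two_strains_cannot_make_four_levels(self):
        # exhaustive subset-sum check: k=2 yields at most 3 distinct sums
        for a in np.linspace(0.05, 0.95, 19):
            sums = {round(a, 9), round(1 - a, 9), 1.0}
            assert len(sums) <= 3


class TestDecomposition:
    def test_single_strain(self):
        m = min_strain_decomposition(profile({"g1": 1.0, "g2": 1.0, "g3": 1.0}))
        assert m.k == 1
        assert m.abundances == pytest.approx([1.0])
        assert m.residual <= 1e-9

    def test_worked_two_strain_example(self):
        m = min_strain_decomposition(profile({"g1": 1.0, "g2": 0.6, "g3": 0.4}))
        assert m.k == 2
        assert sorted(m.abundances, reverse=True) == pytest.approx([0.6, 0.4], abs=1e-6)
        content = {g: tuple(int(x) for x in row) for g, row in zip(m.genes, m.content)}
        assert content["g1"] == (1, 1)
        assert content["g2"] == (1, 0)
        assert content["g3"] == (0, 1)
        # k = 1 is infeasible: 0.6 deviates more than epsilon from {0, 1}
        assert abs(0.6 - 1.0) > 0.05 and abs(0.6 - 0.0) > 0.05

    def test_five_gene_instance_matches_oracle(self):
        ratios = {"g1": 1.0, "g2": 0.7, "g3": 0.5, "g4": 0.3, "g5": 0.2}
        m = min_strain_decomposition(profile(ratios), InferenceConfig(k_max=3))
        observed = np.array([ratios[g] for g in sorted(ratios)])
        k_oracle, resid_oracle = exhaustive_min_strains(observed, 0.05, 3)
        assert m.k == k_oracle
        assert m.residual <= 0.05 + 1e-9

    def test_oracle_equivalence_random(self, rng):
        # exhaustive-oracle equivalence on small random instances
        for _ in range(6):
            n_genes = int(rng.integers(2, 5))
            observed = np.sort(rng.uniform(0.05, 1.0, size=n_genes))[::-1]
            ratios = {f"g{i}": float(v) for i, v in enumerate(observed)}
            cfg = InferenceConfig(k_max=3)
            m = min_strain_decomposition(profile(ratios), cfg)
            k_oracle, best = exhaustive_min_strains(
                np.array([ratios[g] for g in sorted(ratios)]), cfg.epsilon, 3
            )
            assert (m.k if m.feasible else None) == k_oracle

    def test_lower_bound_never_exceeds_k(self, rng):
        for _ in range(10):
            n_genes = int(rng.integers(2, 7))
            ratios = {f"g{i}": float(v)
                      for i, v in enumerate(rng.uniform(0.05, 1.0, size=n_genes))}
            m = min_strain_decomposition(profile(ratios))
            if m.feasible:
                assert m.lower_bound <= m.k

    def test_model_invariants(self, rng):
        for _ in range(10):
            n_genes = int(rng.integers(2, 7))
            ratios = {f"g{i}": float(v)
                      for i, v in enumerate(rng.uniform(0.05, 1.0, size=n_genes))}
            m = min_strain_decomposition(profile(ratios))
            if not m.feasible:
                continue
            assert m.abundances.sum() == pytest.approx(1.0)
            assert (m.abundances > 0).all()
            observed = np.array([ratios[g] for g in m.genes if g in ratios])
            predicted = m.predicted()[: len(observed)]
            assert np.max(np.abs(observed - predicted)) <= 0.05 + 1e-9
            cols = {tuple(m.content[:, s]) for s in range(m.k)}
            assert len(cols) == m.k  # no duplicate strain columns

    def test_epsilon_monotonicity(self):
        ratios = {"g1": 1.0, "g2": 0.62, "g3": 0.45, "g4": 0.18}
        ks = []
        for eps in (0.2, 0.1, 0.05, 0.02):
            m = min_strain_decomposition(
                profile(ratios), InferenceConfig(epsilon=eps, k_max=5)
            )
            ks.append(m.k if m.feasible else 6)
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_censored_genes_zero_rows(self):
        m = min_strain_decomposition(
            profile({"g1": 1.0, "g2": 0.5}, below={"g3": 0.001})
        )
        assert m.genes[-1] == "g3"
        assert (m.content[-1] == 0).all()

    def test_ratio_above_one_clipped(self):
        m = min_strain_decomposition(profile({"g1": 1.4, "g2": 1.0}))
        assert m.k == 1
        assert m.clipped_genes == ["g1"]

    def test_infeasible_reports_kmax_plus_one(self):
        ratios = {f"g{i}": 0.1 + 0.11 * i for i in range(8)}
        cfg = InferenceConfig(k_max=2, epsilon=0.01)
        m = min_strain_decomposition(profile(ratios), cfg)
        assert not m.feasible
        assert m.k is None
        assert ">= 3" in m.note

    def test_no_defined_ratios_error(self):
        with pytest.raises(ValueError, match="no defined ratios"):
            min_strain_decomposition(profile({}))


def gapped_abundances(k, rng, min_gap=0.15, min_abundance=0.05):
    while True:
        a = rng.dirichlet(np.ones(k))
        a = np.sort(a)[::-1]
        if a[-1] < min_abundance:
            continue
        if all(a[i] - a[i + 1] >= min_gap for i in range(k - 1)):
            return a


class TestRecovery:
    def test_noiseless_k_and_abundance_recovery(self):
        # 50 seeded synthetic communities with k in {1,2,3}
        failures = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            k = int(rng.integers(1, 4))
            from rdhfp.synth import DEFAULT_PANEL

            strains = make_identifiable_strains(k, panel=DEFAULT_PANEL[:10], seed=seed)
            a = gapped_abundances(k, rng) if k > 1 else np.array([1.0])
            panel = sorted(strains[0].gene_content)
            content = np.array(
                [[s.gene_content[g] for s in strains] for g in panel], dtype=float
            )
            ratios = content @ a
            values = {g: float(v) for g, v in zip(panel, ratios) if v > 0}
            m = min_strain_decomposition(profile(values), InferenceConfig(k_max=4))
            if m.k != k:
                failures.append((seed, k, m.k))
                continue
            got = np.sort(m.abundances)[::-1]
            if np.max(np.abs(got - a)) > 0.02:
                failures.append((seed, k, "abundance", got, a))
        assert failures == []


class TestColocalization:
    def make_profiles(self, trajectories):
        out = []
        n = len(next(iter(trajectories.values())))
        for i in range(n):
            out.append(profile({g: tr[i] for g, tr in trajectories.items()},
                               sample=f"s{i}"))
        return out

    def test_identical_trajectories_grouped(self):
        tr = [0.9, 0.4, 0.05, 0.3, 0.7, 0.1]
        profiles = self.make_profiles({"a": tr, "b": tr,
                                       "c": [0.01, 0.5, 0.9, 0.02, 0.1, 0.6]})
        groups = colocalization_candidates(profiles)
        assert groups == [["a", "b"]]

    def test_offset_trajectories_excluded(self):
        tr = [0.9, 0.4, 0.05, 0.3, 0.7, 0.1]
        profiles = self.make_profiles({"a": tr, "b": [x / 10 for x in tr]})
        groups = colocalization_candidates(profiles)
        assert groups == []  # correlated but 10-fold offset

    def test_synthetic_co_located_pair_recovered(self, rng):
        base = rng.uniform(0.05, 0.9, size=6)
        noise = lambda: rng.normal(0, 0.02, size=6)
        trajectories = {
            "a": np.exp(np.log(base) + noise()),
            "b": np.exp(np.log(base) + noise()),
            "c": rng.uniform(0.05, 0.9, size=6),
            "d": rng.uniform(0.05, 0.9, size=6),
        }
        profiles = self.make_profiles(
            {g: list(map(float, tr)) for g, tr in trajectories.items()}
        )
        groups = colocalization_candidates(profiles)
        assert ["a", "b"] in groups

    def test_insufficient_shared_samples_skipped(self):
        profiles = self.make_profiles({"a": [0.5, 0.4], "b": [0.5, 0.4]})
        assert colocalization_candidates(profiles) == []
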