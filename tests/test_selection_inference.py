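"""Neutrality regression, ENC deviation, clustering, group RSCU tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from plastcub.codon_metrics import usage_profile
from plastcub.selection_inference import (
    cluster_profiles,
    enc_deviation,
    linkage_to_newick,
    mutation_contribution,
    neutrality_regression,
    rscu_group_test,
)
from plastcub.synthetic_data import SimSpec, simulate_usage_regime


class TestNeutralityRegression:
    def test_identity_line(self):
        pts = [(x, x) for x in (0.1, 0.3, 0.5, 0.7)]
        fit = neutrality_regression(pts)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_gc12_slope_zero(self):
        fit = neutrality_regression([(0.1, 0.4), (0.3, 0.4), (0.8, 0.4)])
        assert fit.slope == pytest.approx(0.0)

    def test_matches_closed_form_normal_equations(self):
        pts = [(0.10, 0.42), (0.25, 0.44), (0.33, 0.40), (0.52, 0.47), (0.61, 0.50)]
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        fit = neutrality_regression(pts)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.n_points == 5

    def test_fewer_than_three_points_missing(self):
        assert neutrality_regression([(0.1, 0.2), (0.3, 0.4)]) is None


class TestMutationContribution:
    @pytest.mark.parametrize("slope, pct", [(0.0763, 7.6), (0.0, 0.0), (0.3237, 32.4)])
    def test_slope_to_percent(self, slope, pct):
        assert round(mutation_contribution(slope), 1) == pct


class TestEncDeviation:
    def _profile(self, name, enc_value, gc3s_value):
        from plastcub.codon_metrics import UsageProfile, expected_enc

        return UsageProfile(name=name, n_codons=100, rscu={}, enc=enc_value,
                            gc1=None, gc2=None, gc3=None, gc12=None,
                            gc3s=gc3s_value, pr2_at=None, pr2_gc=None)

    def test_gene_exactly_on_curve(self):
        from plastcub.codon_metrics import expected_enc

        p = self._profile("g", expected_enc(0.3), 0.3)
        df, frac = enc_deviation([p])
        assert df["deviation"].iloc[0] == pytest.approx(0.0)

    def test_empty_set_missing_summary(self):
        df, frac = enc_deviation([])
        assert frac is None and df.empty

    def test_selection_regime_genes_fall_below_curve(self):
        genes, _ = simulate_usage_regime(
            SimSpec(seed=21, n_genes=40, codons_per_gene=200, regime="selection",
                    gc_pressure_range=(0.05, 0.3))
        )
        profiles = [usage_profile(g) for g in genes]
        _, frac = enc_deviation(profiles)
        assert frac > 0.9


def ward_increase(c1, c2):
    """Ward objective: increase in within-cluster sum of squares on merging."""
    c1, c2 = np.asarray(c1, float), np.asarray(c2, float)
    n1, n2 = len(c1), len(c2)
    d = c1.mean(axis=0) - c2.mean(axis=0)
    return (n1 * n2 / (n1 + n2)) * float(d @ d)


class TestClustering:
    def test_identical_rows_co_cluster(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0]], index=["a", "b", "c"])
        res = cluster_profiles(m, n_clusters=2)
        assert res.labels["a"] == res.labels["b"] != res.labels["c"]

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(3)
        blob1 = rng.normal(0, 0.1, size=(3, 4))
        blob2 = rng.normal(5, 0.1, size=(3, 4))
        m = pd.DataFrame(np.vstack([blob1, blob2]),
                         index=[f"r{i}" for i in range(6)])
        res = cluster_profiles(m, n_clusters=2)
        labels = [res.labels[f"r{i}"] for i in range(6)]
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_merge_sequence_matches_brute_force_ward(self):
        pts = {"a": [0.0], "b": [0.2], "c": [1.0], "d": [1.1]}
        m = pd.DataFrame.from_dict(pts, orient="index")
        res = cluster_profiles(m)
        # brute-force greedy Ward: first merge (c,d), then (a,b), then all.
        clusters = {k: [v] for k, v in pts.items()}
        merges = []
        while len(clusters) > 1:
            pair = min(
                itertools.combinations(sorted(clusters), 2),
                key=lambda p: ward_increase(clusters[p[0]], clusters[p[1]]),
            )
            merges.append(set(pair))
            clusters[pair[0] + pair[1]] = clusters.pop(pair[0]) + clusters.pop(pair[1])
        assert merges[0] == {"c", "d"}
        assert merges[1] == {"a", "b"}
        # scipy linkage merge order: rows sorted by height; same partitions
        names = list(pts)
        z = res.linkage
        first = {names[int(z[0, 0])], names[int(z[0, 1])]}
        second = {names[int(z[1, 0])], names[int(z[1, 1])]}
        assert {frozenset(first), frozenset(second)} == {
            frozenset({"c", "d"}), frozenset({"a", "b"})
        }

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"r{i}" for i in range(8)])
        res1 = cluster_profiles(m, n_clusters=3)
        perm = m.sample(frac=1.0, random_state=4)
        res2 = cluster_profiles(perm, n_clusters=3)
        # same partition: co-membership must agree for every pair
        for a, b in itertools.combinations(m.index, 2):
            assert (res1.labels[a] == res1.labels[b]) == (res2.labels[a] == res2.labels[b])

    def test_singleton(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["only"])
        res = cluster_profiles(m, n_clusters=1)
        assert res.labels == {"only": 1}
        assert linkage_to_newick(res) == "(only);"

    def test_newick_export_contains_all_leaves(self):
        m = pd.DataFrame(np.eye(4), index=list("wxyz"))
        nwk = linkage_to_newick(cluster_profiles(m))
        assert nwk.endswith(";")
        for leaf in "wxyz":
            assert leaf in nwk

    def test_missing_cells_imputed(self):
        m = pd.DataFrame([[1.0, np.nan], [1.0, 2.0], [5.0, 6.0]], index=list("abc"))
        res = cluster_profiles(m, n_clusters=2)
        assert res.labels["a"] == res.labels["b"]


class TestRscuGroupTest:
    def _tables(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        codons = ["UUA", "GCU", "CGU"]
        mk = lambda n, delta: pd.DataFrame(
            rng.normal(1.0, 0.1, size=(n, 3)) + delta, columns=codons
        )
        return {"g1": mk(6, 0.0), "g2": mk(6, 0.0), "g3": mk(6, shift)}

    def test_identical_groups_h_zero(self):
        t = pd.DataFrame([[1.0, 2.0]] * 4, columns=["UUA", "GCU"])
        df = rscu_group_test({"a": t, "b": t.copy()})
        assert (df["H"] == 0.0).all()

    def test_shifted_group_detected(self):
        df = rscu_group_test(self._tables(shift=3.0))
        assert (df["p_bonferroni"] < 0.05).all()

    def test_null_groups_mostly_nonsignificant(self):
        df = rscu_group_test(self._tables(shift=0.0, seed=5))
        assert (df["p_bonferroni"] > 0.05).all()

    def test_requires_two_members_per_group(self):
        t = pd.DataFrame([[1.0]], columns=["UUA"])
        with pytest.raises(ValueError):
            rscu_group_test({"a": t, "b": t})


class TestRegimeDiscrimination:
    """Headline parameter-recovery property at reduced scale (the full
    80 x 300 x 20-seed sweep runs in the acceptance suite)."""

    def test_slopes_separate(self):
        mutation, selection = [], []
        for seed in range(3):
            for regime, sink in (("mutation", mutation), ("selection", selection)):
                genes, _ = simulate_usage_regime(
                    SimSpec(seed=seed, n_genes=40, codons_per_gene=200, regime=regime)
                )
                pts = []
                for g in genes:
                    from plastcub.codon_metrics import positional_gc

                    gc1, gc2, gc3, gc12 = positional_gc(g)
                    pts.append((gc3, gc12))
                sink.append(neutrality_regression(pts).slope)
        assert all(0.85 <= s <= 1.15 for s in mutation)
        assert all(-0.1 <= s <= 0.1 for s in selection)
        assert min(mutation) > max(selection)
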