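import math

import numpy as np
import pandas as pd
import pytest

from phosig.errors import ConfigurationError, ValidationError
from phosig.io import validate_ks_map
from phosig.kinase import (
    KseaScorer,
    build_substrate_graph,
    consensus_topk,
    ksea_z,
    overrep_exact,
    smooth_fc,
    smoothed_ksea,
    substrate_links,
)
from phosig.signature import SignatureSet


def ks_map(assignments: dict[str, list[str]]) -> pd.DataFrame:
    rows = []
    for kid, sites in assignments.items():
        for s in sites:
            prot, rest = s.split("_p")
            rows.append((kid, prot, int(rest[1:]), rest[0]))
    return validate_ks_map(pd.DataFrame(
        rows, columns=["kinase_id", "substrate_protein_id", "position", "residue"]))


def sites(prefix, n, start=1):
    return [f"{prefix}_pS{start + i}" for i in range(n)]


class TestKseaZ:
    def test_substrate_mean_equal_global_gives_null(self):
        fc = pd.Series(np.tile([1.0, -1.0], 10), index=sites("P", 20))
        ks = ks_map({"K1": sites("P", 4)})  # mean of first 4 = 0 = global mean
        out = ksea_z(fc, ks)
        assert out.loc["K1", "z"] == pytest.approx(0.0)
        assert out.loc["K1", "p"] == pytest.approx(1.0)

    def test_direct_formula_case(self):
        # global mean 0, population sd 1, m=4 substrates with mean 0.5 -> z=1
        a = (-1 + np.sqrt(6)) / 2
        b = (-1 - np.sqrt(6)) / 2
        fc_vals = np.array([0.5, 0.5, 0.5, 0.5, a, a, b, b])
        assert fc_vals.mean() == pytest.approx(0.0)
        assert fc_vals.std() == pytest.approx(1.0)
        fc = pd.Series(fc_vals, index=sites("P", 8))
        ks = ks_map({"K1": sites("P", 4)})
        out = ksea_z(fc, ks)
        assert out.loc["K1", "z"] == pytest.approx(1.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        fc = pd.Series(rng.normal(0, 1, 30), index=sites("P", 30))
        ks = ks_map({"K1": sites("P", 5), "K2": sites("P", 6, start=10)})
        z1 = ksea_z(fc, ks)["z"]
        z2 = ksea_z(fc + 3.7, ks)["z"]
        assert np.allclose(z1, z2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        fc = pd.Series(rng.normal(0, 1, 30), index=sites("P", 30))
        ks = ks_map({"K1": sites("P", 5)})
        assert np.allclose(ksea_z(fc, ks)["z"], ksea_z(fc * 4.2, ks)["z"])

    def test_degenerate_distribution_rejected(self):
        fc = pd.Series(np.ones(10), index=sites("P", 10))
        ks = ks_map({"K1": sites("P", 4)})
        with pytest.raises(ValidationError, match="degenerate"):
            ksea_z(fc, ks)

    def test_min_substrates_filter(self):
        rng = np.random.default_rng(2)
        fc = pd.Series(rng.normal(0, 1, 10), index=sites("P", 10))
        ks = ks_map({"K1": sites("P", 2), "K2": sites("P", 5, start=3)})
        out = KseaScorer(min_substrates=3).fit(fc, ks).scores_
        assert list(out.index) == ["K2"]


class TestOverrep:
    def test_enumeration_example(self):
        universe = set(sites("P", 10))
        regulated = set(sites("P", 5))
        ks = ks_map({"K1": sites("P", 2)})
        out = overrep_exact(regulated, ks, universe, min_substrates=1)
        assert out.loc["K1", "p"] == pytest.approx(10 / 45)

    def test_regulated_equal_universe_forces_p1(self):
        universe = set(sites("P", 10))
        ks = ks_map({"K1": sites("P", 3)})
        out = overrep_exact(universe, ks, universe, min_substrates=1)
        assert out.loc["K1", "p"] == pytest.approx(1.0)

    def test_no_substrates_in_universe_gives_p1(self):
        universe = set(sites("P", 5))
        ks = ks_map({"K1": sites("Q", 3)})
        out = overrep_exact(set(), ks, universe, min_substrates=0)
        assert out.loc["K1", "p"] == pytest.approx(1.0)

    def test_regulated_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            overrep_exact({"P_pS99"}, ks_map({"K1": sites("P", 3)}),
                          set(sites("P", 3)))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_full_enumeration_oracle(self, seed):
        """Hypergeometric tail equals exhaustive enumeration for universes <= 25."""
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 26))
        uni = sites("P", N)
        n_reg = int(rng.integers(0, N + 1))
        regulated = set(rng.choice(uni, n_reg, replace=False))
        K = int(rng.integers(1, N + 1))
        subs = list(rng.choice(uni, K, replace=False))
        out = overrep_exact(regulated, ks_map({"K1": subs}), set(uni),
                            min_substrates=0)
        k_obs = len(set(subs) & regulated)
        # enumerate P(X >= k) directly from the hypergeometric pmf
        oracle = sum(
            math.comb(n_reg, x) * math.comb(N - n_reg, K - x) / math.comb(N, K)
            for x in range(k_obs, min(K, n_reg) + 1)
        )
        assert out.loc["K1", "p"] == pytest.approx(oracle, abs=1e-12)


class TestSmoothed:
    def test_lambda_zero_reduces_to_ksea(self):
        rng = np.random.default_rng(3)
        fc = pd.Series(rng.normal(0, 1, 30), index=sites("P", 30))
        ks = ks_map({"K1": sites("P", 5), "K2": sites("P", 5, start=10)})
        base = ksea_z(fc, ks)
        sm = smoothed_ksea(fc, ks, lam=0.0)
        assert np.allclose(base["z"], sm["z"])

    def test_path_graph_hand_case(self):
        fc = pd.Series([0.0, 1.0, 2.0, 3.0, 4.0], index=list("abcde"))
        graph = {"a": ["b"], "b": ["a", "c"], "c": ["b", "d"],
                 "d": ["c", "e"], "e": ["d"]}
        out = smooth_fc(fc, graph, lam=0.5)
        assert out.tolist() == pytest.approx([0.5, 1.0, 2.0, 3.0, 3.5])

    def test_complete_graph_contracts_toward_mean(self):
        rng = np.random.default_rng(4)
        fc = pd.Series(rng.normal(0, 1, 20), index=sites("P", 20))
        ks = ks_map({"K1": sites("P", 5)})
        graph = {s: [t for t in fc.index if t != s] for s in fc.index}
        z0 = abs(ksea_z(fc, ks).loc["K1", "z"])
        for lam in (0.3, 0.6, 0.9):
            sm = smooth_fc(fc, graph, lam)
            z = abs(ksea_z(sm, ks).loc["K1", "z"])
            assert z <= z0 + 1e-9

    def test_lambda_out_of_range_rejected(self):
        fc = pd.Series([1.0, 2.0], index=sites("P", 2))
        with pytest.raises(ConfigurationError):
            smooth_fc(fc, {}, lam=1.0)

    def test_default_graph_links_co_substrates_and_co_protein_sites(self):
        ks = ks_map({"K1": ["P1_pS1", "P2_pS2"], "K2": ["P2_pS3"]})
        g = build_substrate_graph(ks)
        assert "P2_pS2" in g["P1_pS1"]          # shared kinase
        assert "P2_pS3" in g["P2_pS2"]          # shared protein


class TestConsensus:
    def _scores(self, zs, ps=None):
        idx = [f"K{i + 1:02d}" for i in range(len(zs))]
        df = pd.DataFrame({"z": zs}, index=pd.Index(idx, name="kinase_id"))
        df["p"] = ps if ps is not None else 2 * (1 - 0.5 * (1 + np.tanh(np.abs(df["z"]))))
        return df

    def test_identical_rankings_intersect_fully(self):
        zs = np.linspace(5, 1, 6)
        s = self._scores(zs, ps=np.full(6, 1e-4))
        cons = consensus_topk({"a": s, "b": s.copy(), "c": s.copy()}, k=3)
        assert cons.intersection == set(cons.topk["a"]) == {"K01", "K02", "K03"}

    def test_disjoint_topk_gives_empty_intersection(self):
        a = self._scores([5, 4, 0.1, 0.1], ps=[1e-4, 1e-4, 0.9, 0.9])
        b = self._scores([0.1, 0.1, 5, 4], ps=[0.9, 0.9, 1e-4, 1e-4])
        c = a.copy()
        cons = consensus_topk({"a": a, "b": b, "c": c}, k=2)
        assert cons.intersection == set()

    def test_insignificant_kinases_never_ranked(self):
        s = self._scores([5, 0.2], ps=[1e-4, 0.8])
        cons = consensus_topk({"a": s}, k=10)
        assert cons.topk["a"] == ["K01"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        frames = {}
        for scheme in ("x", "y", "w"):
            z = rng.normal(0, 2, 15)
            frames[scheme] = self._scores(z, ps=rng.uniform(0, 0.2, 15))
        k = 5
        cons = consensus_topk(frames, k=k, alpha=0.05)
        # brute force: rank each scheme independently, then triple loop
        tops = {}
        for scheme, df in frames.items():
            elig = df[df["p"] < 0.05]
            order = sorted(elig.index, key=lambda i: (-abs(elig.loc[i, "z"]),
                                                      elig.loc[i, "p"], i))
            tops[scheme] = order[:k]
        brute = {kid for kid in frames["x"].index
                 if all(kid in tops[s] for s in tops)}
        assert cons.intersection == brute


class TestSubstrateLinks:
    def test_single_substrate_gets_rank_one(self):
        ks = ks_map({"K1": ["P1_pS1"]})
        fc = pd.Series([2.0], index=["P1_pS1"])
        out = substrate_links(SignatureSet({"P1"}), fc, ks)
        assert out.loc[0, "rank"] == 1

    def test_order_equals_sort_oracle(self):
        ks = ks_map({"K1": sites("P", 6)})
        vals = [0.5, -3.0, 2.0, -1.0, 2.5, 0.1]
        fc = pd.Series(vals, index=sites("P", 6))
        out = substrate_links(SignatureSet(set(sites("P", 6))), fc, ks, top_n=6)
        expect = [s for _, s in sorted(zip(vals, sites("P", 6)),
                                       key=lambda t: (-abs(t[0]), t[1]))]
        got = list(out.sort_values("rank")["site_id"])
        assert got == expect

    def test_planted_kinase_substrates_dominate(self, standard_cohort):
        from phosig.differential import differential_table, preset_spec
        from phosig.preprocess import standard_preprocess

        table, sheet, ks, truth = standard_cohort
        m = standard_preprocess(table, sheet)
        d = differential_table(m, sheet, preset_spec("strict", "DA-NR", "DA-CR"))
        sig_sites = set(d.index[d["status"] != "ns"])
        out = substrate_links(SignatureSet(sig_sites), d["log2fc"].dropna(), ks,
                              top_n=10, site_p=d["p"])
        top_kinases = out["kinase_id"].value_counts()
        assert top_kinases.idxmax() == "K01"
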