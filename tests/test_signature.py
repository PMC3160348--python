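"""Overlap statistics: RF, hypergeometric tail, sign test, resampling."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bcellsig as b
from bcellsig.containers import ConfigurationError
from bcellsig.signature import DirectionalGeneList, HomologMap, LigandCompendium


def hyper_tail_exact(x, n1, n2, N):
    """Exact rational-arithmetic tail, independent of scipy."""
    total = Fraction(0)
    denom = math.comb(N, n2)
    for j in range(x, min(n1, n2) + 1):
        total += Fraction(math.comb(n1, j) * math.comb(N - n1, n2 - j), denom)
    return total


def binom_tail_exact(k, x):
    return Fraction(sum(math.comb(x, j) for j in range(k, x + 1)), 2**x)


class TestRepresentationFactor:
    def test_expected_overlap_of_one(self):
        assert b.representation_factor(5, 10, 10, 100) == 5.0

    def test_null_expectation_gives_one(self):
        assert b.representation_factor(2, 10, 20, 100) == 1.0

    def test_zero_overlap(self):
        assert b.representation_factor(0, 10, 10, 100) == 0.0

    def test_scale_consistency(self):
        assert b.representation_factor(5, 10, 10, 100) == b.representation_factor(
            10, 20, 20, 200
        )

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            b.representation_factor(5, 10, 10, 0)
        with pytest.raises(ConfigurationError):
            b.representation_factor(11, 10, 10, 100)


class TestHypergeomTail:
    def test_trivial_bounds(self):
        assert b.hypergeom_tail(0, 5, 5, 20) == 1.0
        assert b.hypergeom_tail(5, 5, 5, 5) == 1.0  # certain event

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(2, 25), st.data())
    def test_matches_exact_enumeration(self, N, data):
        n1 = data.draw(st.integers(0, N))
        n2 = data.draw(st.integers(0, N))
        lo = max(0, n1 + n2 - N)
        x = data.draw(st.integers(lo, min(n1, n2)))
        got = b.hypergeom_tail(x, n1, n2, N)
        assert abs(got - float(hyper_tail_exact(x, n1, n2, N))) < 1e-12

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ConfigurationError):
            b.hypergeom_tail(6, 5, 5, 20)


class TestSignConcordance:
    def test_all_concordant_triple(self):
        assert b.sign_concordance_test(3, 3) == 0.125

    def test_half_concordant_not_significant(self):
        assert b.sign_concordance_test(5, 10) > 0.5

    def test_zero_overlap_p_one(self):
        assert b.sign_concordance_test(0, 0) == 1.0

    def test_101_of_112_matches_exact_arithmetic(self):
        """The headline 101-of-112 concordance, checked against Fractions."""
        got = b.sign_concordance_test(101, 112)
        exact = float(binom_tail_exact(101, 112))
        assert math.isclose(got, exact, rel_tol=1e-9)
        assert got < 1e-15  # overwhelming directional agreement


class TestSignatureBuilding:
    def _compendium(self):
        rows = pd.DataFrame(
            {
                "ligand": ["il4"] * 4,
                "symbol": ["Xbp1", "Egr1", "Weak", "Neg"],
                "log2fc": [0.6, -0.7, 0.3, -0.5],
                "timepoint_h": [4.0] * 4,
            }
        )
        return LigandCompendium(rows)

    def test_cutoff_arithmetic(self):
        sig = b.build_ligand_signature(self._compendium(), "il4", fc_cutoff=1.5)
        # log2(1.5) ~ 0.585: 0.6 passes (up), -0.7 passes (down), 0.3/-0.5 fail
        assert dict(sig.directions) == {"XBP1": 1, "EGR1": -1}

    def test_degenerate_cutoff_includes_all(self):
        sig = b.build_ligand_signature(self._compendium(), "il4", fc_cutoff=1.0)
        assert len(sig) == 4

    def test_unknown_ligand_rejected(self):
        with pytest.raises(KeyError):
            b.build_ligand_signature(self._compendium(), "baff")


class TestSharedUniverse:
    def test_case_insensitive_symbol_matching(self):
        dis = DirectionalGeneList.from_dict({"XBP1": 1, "EGR1": -1, "CAV1": 1})
        sig = DirectionalGeneList.from_dict({"Xbp1": 1, "Notonchip": 1})
        hmap = HomologMap.same_symbol(["Xbp1", "Egr1", "Cav1"])
        dis_r, sig_r, N, universe = b.restrict_to_shared_universe(
            dis, sig, {"XBP1", "EGR1", "CAV1", "RRM2"}, hmap
        )
        assert N == 3  # RRM2 has no mouse counterpart; Notonchip absent
        assert sig_r.symbols == {"XBP1"}
        assert dis_r.symbols == {"XBP1", "EGR1", "CAV1"}

    def test_empty_universe_rejected(self):
        dis = DirectionalGeneList.from_dict({"A": 1})
        sig = DirectionalGeneList.from_dict({"B": 1})
        with pytest.raises(ConfigurationError):
            b.restrict_to_shared_universe(dis, sig, {"A"}, HomologMap({"B": "B"}))


class TestResampling:
    def test_maximal_statistic_hits_floor(self):
        universe = {f"G{i}" for i in range(30)}
        dis = DirectionalGeneList.from_dict({f"G{i}": 1 for i in range(15)})
        sig = DirectionalGeneList.from_dict(
            {g: 1 if g in dis.symbols else -1 for g in universe}
        )
        p = b.resample_null(dis, sig, universe, n_resamples=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_converges_to_joint_null(self):
        """Empirical joint p matches the analytic hypergeometric-binomial null."""
        rng = np.random.default_rng(31)
        universe = {f"G{i}" for i in range(40)}
        dis = DirectionalGeneList.from_dict(
            {f"G{i}": int(d) for i, d in zip(range(15), rng.choice([1, -1], 15))}
        )
        sig_genes = rng.choice(sorted(universe), 12, replace=False)
        sig = DirectionalGeneList.from_dict(
            {g: int(d) for g, d in zip(sig_genes, rng.choice([1, -1], 12))}
        )
        from bcellsig.signature import _overlap_counts

        x_obs, k_obs = _overlap_counts(dis, sig)
        # analytic: P(X >= x_obs and K >= k_obs), K | X=x ~ Binomial(x, 1/2)
        N, n1, n2 = 40, 15, 12
        p_exact = 0.0
        for x in range(x_obs, min(n1, n2) + 1):
            px = math.comb(n1, x) * math.comb(N - n1, n2 - x) / math.comb(N, n2)
            p_exact += px * float(binom_tail_exact(k_obs, x))
        p_emp = b.resample_null(dis, sig, universe, n_resamples=20_000, seed=7)
        se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(p_emp - p_exact) < 4 * se + 1e-4

    def test_planted_configuration_is_significant(self, small_study):
        cfg, matrix, annotation, truth, compendium, homolog = small_study
        expressed = b.filter_expressed(matrix, annotation).matrix
        symbols = set(expressed.gene_symbols[expressed.gene_symbols != ""].str.upper())
        sig = b.build_ligand_signature(compendium, truth.target_ligand)
        dis, sig_r, N, universe = b.restrict_to_shared_universe(
            truth.module_list(), sig, symbols, homolog
        )
        st_ = b.overlap_stats(dis, sig_r, universe, truth.target_ligand,
                              n_resamples=2000, seed=3)
        assert st_.rf > 1
        assert st_.p_hyper < 1e-6
        assert st_.p_resample is not None and st_.p_resample <= 0.001


class TestRankLigands:
    def test_single_ligand_ranks_first(self):
        rows = pd.DataFrame(
            {
                "ligand": ["only"],
                "symbol": ["Xbp1"],
                "log2fc": [1.0],
                "timepoint_h": [4.0],
            }
        )
        dis = DirectionalGeneList.from_dict({"XBP1": 1, "EGR1": -1})
        table = b.rank_ligands(
            dis,
            LigandCompendium(rows),
            {"XBP1", "EGR1"},
            HomologMap.same_symbol(["Xbp1", "Egr1"]),
        )
        assert list(table["ligand"]) == ["only"]

    def test_planted_target_ranked_first(self, small_study):
        cfg, matrix, annotation, truth, compendium, homolog = small_study
        expressed = b.filter_expressed(matrix, annotation).matrix
        symbols = set(expressed.gene_symbols[expressed.gene_symbols != ""].str.upper())
        table = b.rank_ligands(truth.module_list(), compendium, symbols, homolog)
        assert table.iloc[0]["ligand"] == truth.target_ligand
        assert bool(table.iloc[0]["significant"])

    def test_decoy_sign_test_calibrated(self):
        """Across decoys the sign test rejects at ~nominal 5% rate."""
        p_values = []
        for seed in range(5):
            cfg = b.SimulationConfig(n_genes=3000, seed=500 + seed, module_size=400)
            matrix, annotation, truth = b.simulate_study(cfg)
            compendium, homolog, truth = b.simulate_ligand_compendium(cfg, truth)
            expressed = b.filter_expressed(matrix, annotation).matrix
            symbols = set(
                expressed.gene_symbols[expressed.gene_symbols != ""].str.upper()
            )
            table = b.rank_ligands(truth.module_list(), compendium, symbols, homolog)
            decoys = table[table["ligand"] != truth.target_ligand]
            p_values.extend(decoys["p_sign"].tolist())
        frac = np.mean(np.array(p_values) < 0.05)
        assert 0.01 <= frac <= 0.10  # nominal 5%, binomial slack on 160 draws


class TestEnrichment:
    def test_disjoint_set_p_one_and_sorting(self):
        table = b.gene_set_enrichment(
            ["A", "B", "C"],
            {"hit": ["A", "B"], "miss": ["X", "Y"]},
            ["A", "B", "C", "X", "Y", "Z"],
        )
        assert table.iloc[0]["set"] == "hit"
        assert table.set_index("set").loc["miss", "p"] == 1.0

    def test_single_set_correction_is_identity(self):
        table = b.gene_set_enrichment(
            ["A", "B"], {"only": ["A", "X"]}, ["A", "B", "X", "Y"]
        )
        assert table.iloc[0]["p"] == table.iloc[0]["p_corrected"]

    def test_empty_set_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            table = b.gene_set_enrichment(
                ["A"], {"empty": ["Q"], "ok": ["A"]}, ["A", "B"]
            )
        assert list(table["set"]) == ["ok"]

    def test_planted_module_strongly_enriched(self, small_study):
        cfg, matrix, annotation, truth, _, _ = small_study
        universe = set(matrix.gene_symbols[matrix.gene_symbols != ""].str.upper())
        sets = {"module": truth.module_gene_ids, "other": sorted(universe)[:200]}
        table = b.gene_set_enrichment(truth.module_gene_ids, sets, universe)
        assert table.iloc[0]["set"] == "module"
        assert table.iloc[0]["p_corrected"] < 1e-10
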