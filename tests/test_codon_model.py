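"""Codon substitution model: rate-matrix structure, pruning likelihood
against explicit state enumeration, fitting, and rate bookkeeping."""

import numpy as np
import pytest
from scipy.linalg import expm

from molechron.codon_model import (
    CodonAlignment,
    CodonModelSpec,
    build_rate_matrix,
    category_synonymous_rate,
    estimate_frequencies,
    fit_branch_model,
    flux_fractions,
    likelihood_ratio_test,
    neutral_scaled_rate_matrix,
    prepare_paml_alignment,
    prune_loglik,
)
from molechron.genetic_code import STANDARD_CODE
from molechron.io import read_labeled_tree
from molechron.models import BACKGROUND, CodingAlignment, GeneModel, StructuralError
from molechron.simulate import SimulationConfig, simulate_codon_alignment

from conftest import aged_tree

CODE = STANDARD_CODE


def random_spec(rng, omegas):
    pi = rng.dirichlet(np.full(61, 5.0))
    return CodonModelSpec(
        pi=pi / pi.sum(),
        kappa=float(rng.uniform(0.5, 5.0)),
        omega_by_category=omegas,
    )


def brute_force_loglik(ltt, aln, spec):
    """Joint enumeration over all internal-node state assignments.

    Transition matrices come from scipy's expm, independent of the
    package's eigendecomposition path.
    """
    nodes = list(ltt.tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    axis = {id(nd): k for k, nd in enumerate(internal)}
    rank = len(internal)
    P = {}
    for nd in nodes:
        if nd.parent_node is None:
            continue
        Q = build_rate_matrix(spec, spec.omega_by_category[nd.category])
        P[id(nd)] = expm(Q * nd.edge.length)
    n_sites = aln.n_codons
    total = 0.0
    for site in range(n_sites):
        arr = np.ones((61,) * rank)
        root_ax = axis[id(ltt.tree.seed_node)]
        shape = [1] * rank
        shape[root_ax] = 61
        arr = arr * spec.pi.reshape(shape)
        for nd in nodes:
            if nd.parent_node is None:
                continue
            p_ax = axis[id(nd.parent_node)]
            M = P[id(nd)]
            if nd.is_leaf():
                codon = aln.codons[ltt.tip_label(nd)][site]
                mask = CODE.codon_state_mask(codon).astype(float)
                vec = M @ mask
                shape = [1] * rank
                shape[p_ax] = 61
                arr = arr * vec.reshape(shape)
            else:
                c_ax = axis[id(nd)]
                Mt = M if p_ax < c_ax else M.T
                a1, a2 = min(p_ax, c_ax), max(p_ax, c_ax)
                shape = [1] * rank
                shape[a1] = 61
                shape[a2] = 61
                arr = arr * Mt.reshape(shape)
        total += np.log(arr.sum())
    return total


def random_codon_alignment(rng, taxa, n_sites):
    return CodonAlignment(
        {t: [CODE.sense_codons[i]
             for i in rng.integers(0, 61, size=n_sites)] for t in taxa},
        CODE,
    )


class TestRateMatrix:
    def test_rows_sum_to_zero_and_unit_scale(self, uniform_pi):
        rng = np.random.default_rng(1)
        for _ in range(5):
            spec = random_spec(rng, {BACKGROUND: 0.5})
            Q = build_rate_matrix(spec, float(rng.uniform(0.05, 3.0)))
            assert np.abs(Q.sum(axis=1)).max() < 1e-10
            assert abs(-(spec.pi * np.diag(Q)).sum() - 1.0) < 1e-10

    def test_detailed_balance(self):
        rng = np.random.default_rng(2)
        spec = random_spec(rng, {BACKGROUND: 0.7})
        Q = build_rate_matrix(spec, 0.7)
        F = spec.pi[:, None] * Q
        assert np.abs(F - F.T).max() < 1e-12

    def test_neutral_flux_ratio_is_one(self, uniform_pi):
        spec = CodonModelSpec(pi=uniform_pi, kappa=1.0,
                              omega_by_category={BACKGROUND: 1.0})
        fS, fN = flux_fractions(spec, 1.0)
        # at omega=1 the per-site dN/dS, normalized by the same neutral
        # opportunity, equals 1 exactly
        fS_w, fN_w = flux_fractions(spec, 1.0)
        dnds = (fN_w / fN) / (fS_w / fS)
        assert dnds == pytest.approx(1.0, abs=1e-12)

    def test_zero_pi_entry_rejected(self, uniform_pi):
        pi = uniform_pi.copy()
        pi[0] = 0.0
        pi /= pi.sum()
        spec = CodonModelSpec(pi=pi, kappa=2.0,
                              omega_by_category={BACKGROUND: 1.0})
        with pytest.raises(StructuralError):
            build_rate_matrix(spec, 1.0)

    def test_neutral_scaling_equalizes_synonymous_rate(self, uniform_pi):
        spec = CodonModelSpec(pi=uniform_pi, kappa=3.0,
                              omega_by_category={BACKGROUND: 1.0})
        ii, jj, _, ns = _pairs()
        syn_rate = {}
        for omega in (0.15, 1.0):
            Q = neutral_scaled_rate_matrix(spec, omega)
            flux = spec.pi[ii] * Q[ii, jj]
            syn_rate[omega] = flux[~ns].sum()
        assert syn_rate[0.15] == pytest.approx(syn_rate[1.0], rel=1e-12)


def _pairs():
    from molechron.codon_model import _pair_structure

    return _pair_structure(CODE)


class TestFrequencies:
    def test_uniform_composition_gives_uniform_pi(self):
        aln = CodonAlignment(
            {"A": ["ACGT"[i] * 3 for i in range(4)]}, CODE
        )
        for model in ("CF1", "CF2"):
            pi = estimate_frequencies(aln, model)
            assert np.allclose(pi, 1.0 / 61.0)

    def test_equal_composition_across_positions_cf1_equals_cf2(self):
        rng = np.random.default_rng(3)
        # same multiset of bases at every codon position
        bases = list("AACGTT")
        rows = {}
        for t in "AB":
            cods = []
            for _ in range(30):
                rng.shuffle(bases)
                cods.append("".join(bases[:3]))
                cods.append("".join(bases[3:]))
            rows[t] = [c for c in cods if c not in CODE.stop_codons]
        n = min(len(r) for r in rows.values())
        aln = CodonAlignment({t: r[:n] for t, r in rows.items()}, CODE)
        # not guaranteed equal for arbitrary data; force symmetry instead
        sym = CodonAlignment(
            {"A": ["ACA", "CAC", "AAC", "CAA", "ACC", "CCA"]}, CODE
        )
        pi1 = estimate_frequencies(sym, "CF1")
        pi2 = estimate_frequencies(sym, "CF2")
        assert np.allclose(pi1, pi2)

    def test_estimated_pi_converges_to_generating_pi(self):
        tree = aged_tree("(A:0.0,B:0.0);", {1: 0.0, 2: 5.0})
        cfg = SimulationConfig(tree=tree, seed=4, n_codons=4000,
                               omega_background=1.0)
        aln, _ = simulate_codon_alignment(cfg)
        pi_hat = estimate_frequencies(aln, "CF1")
        assert np.abs(pi_hat - cfg.pi).max() < 0.01


class TestPrepare:
    def test_lesion_free_alignment_unchanged(self):
        gm = GeneModel("G", [9])
        aln = CodingAlignment.from_rows(
            "G", {"ref": "ATGAAACCC", "tx": "ATGAAACCC"}, "ref", gm
        )
        out = prepare_paml_alignment(aln)
        assert out.to_sequences() == {"ref": "ATGAAACCC", "tx": "ATGAAACCC"}

    def test_internal_stop_becomes_nnn_only_in_that_row(self):
        gm = GeneModel("G", [9])
        aln = CodingAlignment.from_rows(
            "G", {"ref": "ATGAAACCC", "tx": "ATGTGACCC"}, "ref", gm
        )
        out = prepare_paml_alignment(aln)
        assert out.codons["tx"] == ["ATG", "NNN", "CCC"]
        assert out.codons["ref"] == ["ATG", "AAA", "CCC"]

    def test_output_never_contains_stop_codons(self):
        rng = np.random.default_rng(6)
        gm = GeneModel("G", [30])
        letters = np.array(list("ACGT"))
        for _ in range(20):
            ref = "".join(rng.choice(letters, size=30))
            tx = "".join(rng.choice(letters, size=30))
            aln = CodingAlignment.from_rows(
                "G", {"ref": ref, "tx": tx}, "ref", gm
            )
            out = prepare_paml_alignment(aln)
            for row in out.codons.values():
                assert not any(CODE.is_stop(c) for c in row)


class TestPruning:
    def test_single_sequence_zero_tree(self, uniform_pi):
        ltt = read_labeled_tree("(A:0.0,B:0.0);")
        spec = CodonModelSpec(pi=uniform_pi, kappa=2.0,
                              omega_by_category={BACKGROUND: 0.5})
        aln = CodonAlignment({"A": ["ATG", "AAA"], "B": ["ATG", "AAA"]}, CODE)
        lnL = prune_loglik(ltt, aln, spec)
        assert lnL == pytest.approx(2 * np.log(1 / 61), abs=1e-10)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for trial in range(8):
            nwk = ("((A:{:.3f},B:{:.3f}):{:.3f},(C:{:.3f},D:{:.3f}):{:.3f});"
                   .format(*rng.uniform(0.02, 0.6, size=6)))
            ltt = read_labeled_tree(nwk)
            spec = random_spec(rng, {BACKGROUND: float(rng.uniform(0.1, 2.0))})
            aln = random_codon_alignment(rng, "ABCD", 2)
            got = prune_loglik(ltt, aln, spec)
            want = brute_force_loglik(ltt, aln, spec)
            assert got == pytest.approx(want, abs=1e-8)

    def test_ambiguous_codons_match_brute_force(self):
        rng = np.random.default_rng(8)
        ltt = read_labeled_tree("((A:0.1,B:0.2):0.15,C:0.3);")
        spec = random_spec(rng, {BACKGROUND: 0.4})
        aln = CodonAlignment(
            {"A": ["ATN", "NNN"], "B": ["A-G", "ACG"], "C": ["ATG", "AAA"]},
            CODE,
        )
        got = prune_loglik(ltt, aln, spec)
        want = brute_force_loglik(ltt, aln, spec)
        assert got == pytest.approx(want, abs=1e-8)

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(9)
        nwk = "((A:0.1,B:0.25):0.2,(C:0.15,D:0.3):0.1);"
        spec = random_spec(rng, {BACKGROUND: 0.6})
        aln = random_codon_alignment(rng, "ABCD", 5)
        ltt = read_labeled_tree(nwk)
        base = prune_loglik(ltt, aln, spec)
        ltt2 = read_labeled_tree(nwk)
        edge = [nd for nd in ltt2.tree.leaf_node_iter()
                if ltt2.tip_label(nd) == "C"][0].edge
        ltt2.tree.reroot_at_edge(edge, length1=0.05, length2=0.10)
        rerooted = prune_loglik(ltt2, aln, spec)
        assert rerooted == pytest.approx(base, abs=1e-8)


class TestFitting:
    def test_two_ratio_recovery_and_nesting(self):
        tree = aged_tree(
            "(((A:0.0,B:0.0):0.0,(C:0.0,D#T1:0.0):0.0):0.0,"
            "(E:0.0,F:0.0):0.0);",
            {1: 0.0, 2: 25.0, 4: 50.0, 6: 70.0},
        )
        cfg = SimulationConfig(tree=tree, seed=10, n_codons=400,
                               omega_background=0.15)
        # the transitional tip with no switch evolves functionally; relabel
        # its true omega by simulating with a neutral switch over the
        # whole branch instead
        cfg.switch_time = 24.9  # nearly the whole D branch is neutral
        aln, _ = simulate_codon_alignment(cfg)
        fit2 = fit_branch_model(tree, aln, "CF1", omega_starts=(0.5,))
        bg_tree = aged_tree(
            "(((A:0.0,B:0.0):0.0,(C:0.0,D:0.0):0.0):0.0,(E:0.0,F:0.0):0.0);",
            {1: 0.0, 2: 25.0, 4: 50.0, 6: 70.0},
        )
        fit1 = fit_branch_model(bg_tree, aln, "CF1", omega_starts=(0.5,))
        assert fit2.lnL >= fit1.lnL - 1e-6
        assert fit2.omega_hat[BACKGROUND] == pytest.approx(0.15, abs=0.06)
        assert fit2.omega_hat["transitional:1"] > fit2.omega_hat[BACKGROUND]

    def test_omega_equals_dn_ds_ratio(self):
        tree = aged_tree("(A:0.0,(B:0.0,C:0.0):0.0);",
                         {1: 0.0, 2: 20.0, 3: 40.0})
        cfg = SimulationConfig(tree=tree, seed=12, n_codons=200,
                               omega_background=0.3)
        aln, _ = simulate_codon_alignment(cfg)
        fit = fit_branch_model(tree, aln, "CF1", omega_starts=(0.5,))
        info = fit.per_category[BACKGROUND]
        assert info["dN_dS"] == pytest.approx(fit.omega_hat[BACKGROUND],
                                              rel=1e-6)

    def test_fixed_category_omega_stays_fixed(self):
        tree = aged_tree("((M1#P1:0.0,M2#P1:0.0)#T1:0.0,(A:0.0,B:0.0):0.0);",
                         {1: 0.0, 2: 15.0, 4: 50.0})
        cfg = SimulationConfig(tree=tree, seed=13, n_codons=150,
                               switch_time=30.0)
        aln, _ = simulate_codon_alignment(cfg)
        fit = fit_branch_model(tree, aln, "CF1", fix_pseudogenic_omega=1.0,
                               omega_starts=(0.5,))
        assert fit.omega_hat["pseudogenic:1"] == 1.0
        assert "pseudogenic:1" in fit.fixed_categories


class TestLikelihoodRatioTest:
    def test_equal_likelihoods_give_p_one(self):
        class F:
            lnL = -100.0

        assert likelihood_ratio_test(F, F, 1) == 1.0

    def test_chi_square_quantile_identity(self):
        class Null:
            lnL = -100.0

        class Alt:
            lnL = -100.0 + 3.841 / 2.0

        assert likelihood_ratio_test(Null, Alt, 1) == pytest.approx(0.05,
                                                                    abs=5e-4)

    def test_negative_statistic_clamped(self):
        class Null:
            lnL = -99.0

        class Alt:
            lnL = -100.0

        assert likelihood_ratio_test(Null, Alt, 1) == 1.0


class TestSynonymousRate:
    def _fit(self, scale=1.0, seed=14):
        tree = aged_tree(
            "((M1#P1:0.0,M2#P1:0.0)#T1:0.0,(A:0.0,(B:0.0,C:0.0):0.0):0.0);",
            {1: 0.0, 2: 15.0 * scale, 3: 40.0 * scale, 5: 60.0 * scale},
        )
        cfg = SimulationConfig(tree=tree, seed=seed, n_codons=200,
                               switch_time=30.0 * scale)
        aln, _ = simulate_codon_alignment(cfg)
        fit = fit_branch_model(tree, aln, "CF1", omega_starts=(0.5,))
        return tree, fit

    def test_doubling_ages_halves_rate(self):
        tree, fit = self._fit(1.0)
        s1 = category_synonymous_rate(fit, tree, BACKGROUND)
        tree2, _ = self._fit(2.0)
        # same fitted substitutions, doubled durations
        fit.per_category[BACKGROUND]["total_duration_my"] *= 2
        s2 = category_synonymous_rate(fit, tree2, BACKGROUND)
        assert s2 == pytest.approx(s1 / 2)

    def test_zero_duration_category_errors(self):
        tree, fit = self._fit(1.0)
        fit.per_category[BACKGROUND]["total_duration_my"] = 0.0
        with pytest.raises(StructuralError):
            category_synonymous_rate(fit, tree, BACKGROUND)
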