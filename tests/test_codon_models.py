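"""GY94 rate matrix, pruning likelihood, site-model fits, LRT, NEB/BEB."""

import itertools
import math

import numpy as np
import pytest

from pmmevol.codon_models import (
    CodonLikelihood,
    SiteModelSpec,
    beb_posteriors,
    build_q,
    code_structure,
    equilibrium_frequencies,
    fit_model,
    lrt,
    lrt_pvalue,
    m0_pairwise_ds,
    neb_posteriors,
    q_eigen,
    transition_matrix,
)
from pmmevol.distances import ng86_pair
from pmmevol.seqio import STANDARD_CODE, CodonAlignment, NamedSequence, parse_newick
from pmmevol.simulate import SimulationConfig, simulate_alignment

CODONS = STANDARD_CODE.sense_codons
UNIFORM = np.full(61, 1.0 / 61)


def random_alignment(rng, names, n_codons):
    return CodonAlignment([
        NamedSequence(n, "".join(rng.choice(CODONS) for _ in range(n_codons)))
        for n in names
    ])


class TestRateMatrix:
    def test_rows_sum_to_zero(self):
        Q = build_q(UNIFORM, 2.0, 0.3)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_mean_rate_is_one(self):
        Q = build_q(UNIFORM, 3.0, 0.7)
        assert -UNIFORM @ np.diag(Q) == pytest.approx(1.0)

    def test_detailed_balance(self):
        rng = np.random.default_rng(2)
        pi = rng.dirichlet(np.ones(61))
        Q = build_q(pi, 2.5, 0.4)
        F = pi[:, None] * Q
        assert np.allclose(F, F.T, atol=1e-14)

    def test_omega_zero_only_synonymous_rates(self):
        # nonzero off-diagonal entries must coincide with the synonymy
        # relation derived independently from the genetic code
        Q = build_q(UNIFORM, 2.0, 0.0)
        syn = set()
        for c1, c2 in itertools.combinations(CODONS, 2):
            diff = [i for i in range(3) if c1[i] != c2[i]]
            if len(diff) == 1 and (STANDARD_CODE.codon_to_aa[c1]
                                   == STANDARD_CODE.codon_to_aa[c2]):
                syn.add((c1, c2))
        idx = {c: i for i, c in enumerate(CODONS)}
        nz = {
            (CODONS[i], CODONS[j])
            for i in range(61) for j in range(i + 1, 61)
            if Q[i, j] > 0
        }
        assert nz == {(a, b) if idx[a] < idx[b] else (b, a) for a, b in syn}


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        Q = build_q(UNIFORM, 2.0, 0.3)
        assert np.allclose(transition_matrix(Q, 0.0, UNIFORM), np.eye(61),
                           atol=1e-12)

    def test_semigroup_property(self):
        Q = build_q(UNIFORM, 2.0, 0.3)
        P1 = transition_matrix(Q, 0.17, UNIFORM)
        P2 = transition_matrix(Q, 0.05, UNIFORM)
        P12 = transition_matrix(Q, 0.22, UNIFORM)
        assert np.allclose(P1 @ P2, P12, atol=1e-8)

    def test_long_time_converges_to_stationary(self):
        rng = np.random.default_rng(7)
        pi = rng.dirichlet(np.ones(61) * 5)
        Q = build_q(pi, 2.0, 0.3)
        P = transition_matrix(Q, 100.0, pi)
        assert np.allclose(P, np.tile(pi, (61, 1)), atol=1e-6)

    def test_rows_sum_to_one(self):
        Q = build_q(UNIFORM, 2.0, 0.3)
        P = transition_matrix(Q, 0.4, UNIFORM)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)


class TestLikelihood:
    def test_two_taxon_single_codon_closed_form(self):
        aln = CodonAlignment([NamedSequence("a", "ATG"),
                              NamedSequence("b", "ACG")])
        tree = parse_newick("(a:0.1,b:0.2);")
        eng = CodonLikelihood(aln, tree, pi=UNIFORM)
        lengths = eng.ti.lengths
        lnl = eng.mixture_lnl(2.0, [1.0], [0.5], lengths)
        # closed form: sum_r pi_r P(t_a)[r, ATG] P(t_b)[r, ACG]
        Q = build_q(UNIFORM, 2.0, 0.5)
        idx = {c: i for i, c in enumerate(CODONS)}
        Pa = transition_matrix(Q, 0.1, UNIFORM)
        Pb = transition_matrix(Q, 0.2, UNIFORM)
        expected = math.log(sum(
            UNIFORM[r] * Pa[r, idx["ATG"]] * Pb[r, idx["ACG"]]
            for r in range(61)
        ))
        assert lnl == pytest.approx(expected, abs=1e-10)

    def test_pruning_matches_brute_force_enumeration(self, rng):
        # 4 taxa x 3 codons: sum over all 61^2 internal-state combinations
        tree = parse_newick("((a:0.2,b:0.3):0.15,(c:0.25,d:0.1):0.05);")
        aln = random_alignment(rng, "abcd", 3)
        eng = CodonLikelihood(aln, tree, pi=UNIFORM)
        lnl = eng.mixture_lnl(2.5, [1.0], [0.3], eng.ti.lengths)

        Q = build_q(UNIFORM, 2.5, 0.3)
        P = {lbl: transition_matrix(Q, t, UNIFORM)
             for lbl, t in [("a", 0.2), ("b", 0.3), ("c", 0.25), ("d", 0.1),
                            ("x", 0.15), ("y", 0.05)]}
        idx = {c: i for i, c in enumerate(CODONS)}
        states = {m.name: [idx[m.codon(i)] for i in range(3)]
                  for m in aln.members}
        brute = 0.0
        for h in range(3):
            sa, sb = states["a"][h], states["b"][h]
            sc, sd = states["c"][h], states["d"][h]
            tot = 0.0
            for r in range(61):
                fx = sum(P["x"][r, x] * P["a"][x, sa] * P["b"][x, sb]
                         for x in range(61))
                fy = sum(P["y"][r, y] * P["c"][y, sc] * P["d"][y, sd]
                         for y in range(61))
                tot += UNIFORM[r] * fx * fy
            brute += math.log(tot)
        assert lnl == pytest.approx(brute, abs=1e-8)

    def test_duplicated_columns_double_lnl(self, rng):
        tree = parse_newick("((a:0.2,b:0.3):0.1,(c:0.25,d:0.1):0.1);")
        aln = random_alignment(rng, "abcd", 5)
        doubled = CodonAlignment([
            NamedSequence(m.name, m.residues * 2) for m in aln.members
        ])
        e1 = CodonLikelihood(aln, tree, pi=UNIFORM)
        e2 = CodonLikelihood(doubled, tree, pi=UNIFORM)
        l1 = e1.mixture_lnl(2.0, [1.0], [0.4], e1.ti.lengths)
        l2 = e2.mixture_lnl(2.0, [1.0], [0.4], e2.ti.lengths)
        assert l2 == pytest.approx(2 * l1, abs=1e-9)

    def test_invariant_under_rerooting(self, rng):
        cfg = SimulationConfig(
            tree=parse_newick(
                "((a:0.2,b:0.3):0.1,(c:0.25,d:0.1):0.1,e:0.4);"),
            spec=SiteModelSpec("M0"), n_codons=40, seed=4, omega=0.3)
        sim = simulate_alignment(cfg)
        lnls = []
        for i in range(5):
            tree = parse_newick(
                "((a:0.2,b:0.3):0.1,(c:0.25,d:0.1):0.1,e:0.4);")
            nodes = [nd for nd in tree.preorder_node_iter()
                     if not nd.is_leaf()]
            tree.reroot_at_node(nodes[i % len(nodes)],
                                update_bipartitions=False)
            eng = CodonLikelihood(sim.alignment, tree, pi=UNIFORM)
            lnls.append(eng.mixture_lnl(2.0, [1.0], [0.3], eng.ti.lengths))
        assert np.ptp(lnls) < 1e-8

    def test_label_mismatch_rejected(self, rng):
        aln = random_alignment(rng, "abcd", 4)
        tree = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,x:0.1):0.1);")
        with pytest.raises(ValueError, match="mismatch"):
            CodonLikelihood(aln, tree)


class TestFrequencies:
    def test_modes_are_distributions(self, rng):
        aln = random_alignment(rng, "ab", 60)
        for mode in ("equal", "F1x4", "F3x4"):
            pi = equilibrium_frequencies(aln, mode)
            assert pi.sum() == pytest.approx(1.0)
            assert (pi > 0).all()


@pytest.fixture(scope="module")
def m0_sim():
    """One M0 simulation shared by the fitting tests."""
    tree = parse_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1,e:0.3);")
    cfg = SimulationConfig(tree=tree, spec=SiteModelSpec("M0"),
                           n_codons=150, kappa=2.0, seed=3, omega=0.2)
    return simulate_alignment(cfg)


class TestFitting:
    def test_m3_single_class_equals_m0(self, m0_sim):
        eng = CodonLikelihood(m0_sim.alignment, m0_sim.tree, pi_mode="equal")
        m0 = fit_model(m0_sim.alignment, m0_sim.tree, SiteModelSpec("M0"),
                       seed=0, n_starts=1, engine=eng)
        m3 = fit_model(m0_sim.alignment, m0_sim.tree,
                       SiteModelSpec("M3", k=1), seed=0, n_starts=1,
                       fix_branch_lengths=m0.branch_lengths, engine=eng)
        m0f = fit_model(m0_sim.alignment, m0_sim.tree, SiteModelSpec("M0"),
                        seed=0, n_starts=1,
                        fix_branch_lengths=m0.branch_lengths, engine=eng)
        assert m3.lnL == pytest.approx(m0f.lnL, abs=1e-4)

    def test_nested_models_respect_lnl_ordering(self, m0_sim):
        from pmmevol.pipeline import stage_scan

        scan = stage_scan(m0_sim.alignment, m0_sim.tree,
                          {"models": ["M0", "M1a", "M2a", "M7", "M8"],
                           "n_starts": 1, "pi_mode": "equal"}, seed=0)
        fits = scan["fits"]
        assert fits["M2a"].lnL >= fits["M1a"].lnL - 1e-3
        assert fits["M8"].lnL >= fits["M7"].lnL - 1e-3

    def test_ml_pairwise_ds_tracks_ng86(self):
        # dS from 2-taxon M0 fits vs NG86 counting across a divergence grid
        ml, ng = [], []
        for i, t in enumerate(np.linspace(0.05, 0.8, 6)):
            tree = parse_newick(f"(a:{t / 2},b:{t / 2});")
            cfg = SimulationConfig(tree=tree, spec=SiteModelSpec("M0"),
                                   n_codons=300, seed=20 + i, omega=0.2)
            sim = simulate_alignment(cfg)
            fit = fit_model(sim.alignment, tree, SiteModelSpec("M0"),
                            pi_mode="equal", seed=0, n_starts=1)
            ml.append(m0_pairwise_ds(fit))
            sa, sb = sim.alignment.members
            ng.append(ng86_pair(sa, sb)["dS"].value)
        r = np.corrcoef(ml, ng)[0, 1]
        assert r > 0.9


class TestLRT:
    @pytest.mark.parametrize("stat,df,expected", [
        (2.2947, 2, 0.3175),
        (7.6562, 4, 0.1050),
        (0.4223, 1, 0.5158),
        (3.5539, 2, 0.1692),
    ])
    def test_chi_square_upper_tail(self, stat, df, expected):
        assert lrt_pvalue(stat, df) == pytest.approx(expected, abs=5e-5)

    def test_zero_statistic_p_one(self):
        assert lrt_pvalue(0.0, 3) == 1.0

    def test_worse_alternative_is_an_error(self, m0_sim):
        eng = CodonLikelihood(m0_sim.alignment, m0_sim.tree, pi_mode="equal")
        m0 = fit_model(m0_sim.alignment, m0_sim.tree, SiteModelSpec("M0"),
                       seed=0, n_starts=1, engine=eng)
        worse = fit_model(m0_sim.alignment, m0_sim.tree, SiteModelSpec("M0"),
                          seed=0, n_starts=1, engine=eng)
        worse.lnL = m0.lnL - 5.0
        with pytest.raises(RuntimeError, match="optimization failure"):
            lrt(m0, worse, df=1)


@pytest.fixture(scope="module")
def m2a_sim_fit():
    """Strong positive selection: 10% of sites at omega = 4.9."""
    tree = parse_newick("((a:0.3,b:0.3):0.1,(c:0.3,d:0.3):0.1,(e:0.3,f:0.3):0.1);")
    cfg = SimulationConfig(tree=tree, spec=SiteModelSpec("M2a"),
                           n_codons=250, kappa=2.0, seed=9,
                           props=[0.85, 0.05, 0.10], omegas=[0.05, 1.0, 4.9])
    sim = simulate_alignment(cfg)
    eng = CodonLikelihood(sim.alignment, tree, pi_mode="equal")
    m1a = fit_model(sim.alignment, tree, SiteModelSpec("M1a"), seed=0,
                    n_starts=1, engine=eng)
    from pmmevol.pipeline import _warm_start

    m2a = fit_model(sim.alignment, tree, SiteModelSpec("M2a"), seed=0,
                    n_starts=2, engine=eng,
                    extra_starts=[_warm_start("M2a", m1a)])
    return sim, m2a


class TestEmpiricalBayes:
    def test_posteriors_row_normalized(self, m2a_sim_fit):
        _, fit = m2a_sim_fit
        post = fit.site_posteriors()
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_posterior_is_one(self, m0_sim):
        fit = fit_model(m0_sim.alignment, m0_sim.tree, SiteModelSpec("M0"),
                        pi_mode="equal", seed=0, n_starts=1)
        assert np.allclose(fit.site_posteriors(), 1.0)

    def test_neb_enriches_true_positive_sites(self, m2a_sim_fit):
        sim, fit = m2a_sim_fit
        post = fit.site_posteriors()
        positive = fit.class_omegas > 1.0
        p_pos = post[:, positive].sum(axis=1)
        true_pos = sim.site_classes == 2
        assert p_pos[true_pos].mean() > p_pos[~true_pos].mean()

    def test_neb_reports_sites_with_reference_aa(self, m2a_sim_fit):
        sim, fit = m2a_sim_fit
        reports = neb_posteriors(fit)
        from pmmevol.seqio import translate

        ref = translate(sim.alignment.members[0]).residues
        for r in reports:
            assert 1 <= r.site <= sim.alignment.n_codons
            assert r.reference_aa == ref[r.site - 1]
            assert 0.5 < r.posterior <= 1.0

    def test_beb_bounded_and_conservative(self, m2a_sim_fit):
        sim, fit = m2a_sim_fit
        neb = {r.site: r.posterior for r in neb_posteriors(fit, threshold=0.0)}
        beb = {r.site: r.posterior for r in beb_posteriors(fit, threshold=0.0)}
        assert all(0.0 <= p <= 1.0 for p in beb.values())
        n_neb95 = sum(p >= 0.95 for p in neb.values())
        n_beb95 = sum(p >= 0.95 for p in beb.values())
        assert n_beb95 <= n_neb95

    def test_beb_rejects_unsupported_model(self, m0_sim):
        fit = fit_model(m0_sim.alignment, m0_sim.tree, SiteModelSpec("M0"),
                        pi_mode="equal", seed=0, n_starts=1)
        with pytest.raises(ValueError, match="M2a and M8"):
            beb_posteriors(fit)

    def test_beb_approaches_neb_with_long_alignments(self):
        # sharply peaked likelihood (2000 codons): BEB ~ NEB per site
        tree = parse_newick("((a:0.3,b:0.3):0.1,(c:0.3,d:0.3):0.1);")
        cfg = SimulationConfig(tree=tree, spec=SiteModelSpec("M2a"),
                               n_codons=2000, kappa=2.0, seed=12,
                               props=[0.8, 0.1, 0.1],
                               omegas=[0.05, 1.0, 4.9])
        sim = simulate_alignment(cfg)
        eng = CodonLikelihood(sim.alignment, tree, pi_mode="equal")
        m1a = fit_model(sim.alignment, tree, SiteModelSpec("M1a"), seed=0,
                        n_starts=1, engine=eng)
        from pmmevol.pipeline import _warm_start

        fit = fit_model(sim.alignment, tree, SiteModelSpec("M2a"), seed=0,
                        n_starts=1, engine=eng,
                        extra_starts=[_warm_start("M2a", m1a)])
        neb = {r.site: r.posterior
               for r in neb_posteriors(fit, threshold=-1.0)}
        beb = {r.site: r.posterior
               for r in beb_posteriors(fit, threshold=-1.0)}
        diffs = [abs(neb[s] - beb[s]) for s in neb]
        assert np.mean(diffs) < 0.05
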