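"""f-statistics, block jackknife, qpWave and qpAdm."""

import itertools

import numpy as np
import pytest

from paleokin import fstats, io, simulate


def freq_groups(pf, count=100):
    n = len(next(iter(pf.values())))
    return {k: fstats.GroupFreqs(k, v, np.full(n, count))
            for k, v in pf.items()}


@pytest.fixture(scope="module")
def blocks50k():
    return fstats.assign_blocks(simulate.synthetic_snp_panel(50_000))


def two_source_graph(alpha=0.3):
    return {
        "anc": ("root",),
        "O": ("drift", "anc", 0.10),
        "mid": ("drift", "anc", 0.02),
        "mA": ("drift", "mid", 0.01),
        "A": ("drift", "mA", 0.01),
        "R1": ("drift", "mA", 0.01),
        "mB": ("drift", "mid", 0.01),
        "B": ("drift", "mB", 0.01),
        "R2": ("drift", "mB", 0.01),
        "adm": ("admix", "A", "B", alpha, 0.005),
    }


class TestGroupFrequencies:
    def test_single_het_individual(self):
        m = io.GenotypeMatrix(["a"], "diploid", np.array([[1]], np.int8))
        g = fstats.group_frequencies(m, {"a": "P"})["P"]
        assert g.freq[0] == 0.5 and g.count[0] == 2

    def test_all_missing_site(self):
        m = io.GenotypeMatrix(["a"], "diploid",
                              np.array([[io.MISSING]], np.int8))
        g = fstats.group_frequencies(m, {"a": "P"})["P"]
        assert np.isnan(g.freq[0]) and g.count[0] == 0

    def test_mixed_ploidy_hand_count(self, rng):
        """Haploid + diploid individuals against a manual counting oracle."""
        n = 100
        dip = io.GenotypeMatrix(
            ["d0", "d1"], "diploid",
            rng.integers(-1, 3, size=(2, n)).astype(np.int8))
        hap = io.GenotypeMatrix(
            ["h0"], "haploid", rng.integers(-1, 2, size=(1, n)).astype(np.int8))
        labels = {"d0": "P", "d1": "P", "h0": "P"}
        g = fstats.group_frequencies([dip, hap], labels)["P"]
        for s in range(n):
            alt = tot = 0
            for row in range(2):
                c = dip.calls[row, s]
                if c != io.MISSING:
                    alt, tot = alt + c, tot + 2
            c = hap.calls[0, s]
            if c != io.MISSING:
                alt, tot = alt + c, tot + 1
            if tot == 0:
                assert np.isnan(g.freq[s])
            else:
                assert g.freq[s] == pytest.approx(alt / tot)
            assert g.count[s] == tot

    def test_unknown_individual_rejected(self):
        m = io.GenotypeMatrix(["a"], "diploid", np.array([[0]], np.int8))
        with pytest.raises(ValueError, match="no population label"):
            fstats.group_frequencies(m, {})


class TestBlockJackknife:
    def test_constant_blocks_zero_se(self):
        terms = np.ones(100)
        blocks = np.repeat(np.arange(10), 10)
        est, se = fstats.block_jackknife(terms, blocks)
        assert est == 1.0 and se == pytest.approx(0.0, abs=1e-12)

    def test_equal_blocks_match_classic_formula(self, rng):
        """Reduces to the classic delete-one jackknife to 1e-12."""
        terms = rng.normal(size=200)
        blocks = np.repeat(np.arange(20), 10)
        est, se = fstats.block_jackknife(terms, blocks)
        g = 20
        deletes = np.array([terms[blocks != j].mean() for j in range(g)])
        classic = np.sqrt((g - 1) / g * ((deletes - deletes.mean()) ** 2).sum())
        assert est == pytest.approx(terms.mean(), abs=1e-12)
        assert se == pytest.approx(classic, abs=1e-12)

    def test_unequal_blocks_match_textbook_weighted_jackknife(self, rng):
        """Independent re-implementation (plain loops) agrees to 1e-10."""
        sizes = rng.integers(3, 30, size=12)
        blocks = np.repeat(np.arange(12), sizes)
        terms = rng.normal(size=blocks.size)
        est, se = fstats.block_jackknife(terms, blocks)

        n, g = float(terms.size), 12
        theta = terms.mean()
        theta_del = [terms[blocks != j].mean() for j in range(g)]
        h = [n / s for s in sizes]
        theta_J = g * theta - sum((1 - sizes[j] / n) * theta_del[j]
                                  for j in range(g))
        pseudo = [h[j] * theta - (h[j] - 1) * theta_del[j] for j in range(g)]
        var = sum((pseudo[j] - theta_J) ** 2 / (h[j] - 1)
                  for j in range(g)) / g
        assert est == pytest.approx(theta, abs=1e-12)
        assert se == pytest.approx(np.sqrt(var), abs=1e-10)

    def test_single_block_errors(self):
        with pytest.raises(fstats.InsufficientDataError, match="blocks"):
            fstats.block_jackknife(np.ones(5), np.zeros(5, dtype=int))


class TestF3F4Identities:
    def test_f3_zero_for_outgroup_copies(self, blocks50k):
        p = np.random.default_rng(0).uniform(0.05, 0.95, 50_000)
        groups = freq_groups({"O": p, "A": p.copy(), "B": p.copy()})
        r = fstats.f3_outgroup(groups, "O", "A", "B", blocks50k)
        assert r.estimate == 0.0

    def test_f3_symmetry(self, blocks50k):
        pf = simulate.simulate_admixture_freqs(
            two_source_graph(), simulate.SimConfig(n_snps=50_000, seed=1))
        groups = freq_groups(pf)
        ab = fstats.f3_outgroup(groups, "O", "A", "B", blocks50k)
        ba = fstats.f3_outgroup(groups, "O", "B", "A", blocks50k)
        assert ab.estimate == ba.estimate and ab.se == ba.se

    def test_f3_shared_drift_value(self, blocks50k):
        """f3(O; A, B) estimates the shared drift of the (A,B) stem."""
        n = 50_000
        cfg = simulate.SimConfig(n_snps=n, seed=2)
        d_shared = 0.04
        graph = {"anc": ("root",), "O": ("drift", "anc", 0.0),
                 "mid": ("drift", "anc", d_shared),
                 "A": ("drift", "mid", 0.02), "B": ("drift", "mid", 0.02)}
        pf = simulate.simulate_admixture_freqs(graph, cfg)
        groups = freq_groups(pf)
        r = fstats.f3_outgroup(groups, "O", "A", "B", blocks50k)
        # Brownian drift variance d * p (1-p), truncation keeps it close
        expected = d_shared * np.mean(pf["anc"] * (1 - pf["anc"]))
        assert abs(r.estimate - expected) < 3 * r.se + 0.1 * expected

    def test_f3_ranking_by_affinity(self, blocks50k):
        """Outgroup-f3 ranks the sister population above outer branches."""
        cfg = simulate.SimConfig(n_snps=50_000, seed=3)
        pf = simulate.simulate_admixture_freqs(two_source_graph(), cfg)
        groups = freq_groups(pf)
        f3 = {p: fstats.f3_outgroup(groups, "O", "A", p, blocks50k).estimate
              for p in ("R1", "B", "mid")}
        assert f3["R1"] > f3["B"] > 0

    def test_f4_zero_when_c_equals_d(self, blocks50k):
        p = np.random.default_rng(4).uniform(0.05, 0.95, 50_000)
        q = np.random.default_rng(5).uniform(0.05, 0.95, 50_000)
        groups = freq_groups({"A": p, "B": q, "C": q[::-1].copy(),
                              "D": q[::-1].copy()})
        r = fstats.f4(groups, "A", "B", "C", "D", blocks50k)
        assert r.estimate == 0.0

    def test_f4_antisymmetry_and_additivity(self, blocks50k):
        cfg = simulate.SimConfig(n_snps=50_000, seed=6)
        pf = simulate.simulate_admixture_freqs(two_source_graph(), cfg)
        groups = freq_groups(pf)
        args = ("O", "mid")
        ab = fstats.f4(groups, *args, "A", "B", blocks50k)
        ba = fstats.f4(groups, "mid", "O", "A", "B", blocks50k)
        assert ab.estimate == -ba.estimate
        # additivity on identical SNP sets
        ac = fstats.f4(groups, *args, "A", "R1", blocks50k)
        cb = fstats.f4(groups, *args, "R1", "B", blocks50k)
        total = fstats.f4(groups, *args, "A", "B", blocks50k)
        assert ac.estimate + cb.estimate == pytest.approx(total.estimate,
                                                          abs=1e-14)

    def test_strict_intersection_snp_rule(self, blocks50k):
        p = np.random.default_rng(7).uniform(0.1, 0.9, 50_000)
        missing = np.zeros(50_000, bool)
        missing[:1000] = True
        fa = p.copy()
        fa[missing] = np.nan
        counts = np.full(50_000, 10)
        ca = counts.copy()
        ca[missing] = 0
        groups = {"O": fstats.GroupFreqs("O", p, counts),
                  "A": fstats.GroupFreqs("A", fa, ca),
                  "B": fstats.GroupFreqs("B", p.copy(), counts)}
        r = fstats.f3_outgroup(groups, "O", "A", "B", blocks50k)
        assert r.n_snps == 49_000


class TestQpWave:
    def test_full_rank_gives_p_one(self, blocks50k):
        cfg = simulate.SimConfig(n_snps=50_000, seed=8)
        pf = simulate.simulate_admixture_freqs(two_source_graph(), cfg)
        mat, labels = simulate.sample_individuals_from_freqs(
            {k: pf[k] for k in ["O", "A", "B", "R1", "R2"]}, 8, seed=9)
        groups = fstats.group_frequencies(mat, labels)
        r = fstats.qpwave_rank_test(groups, ["A", "B"], ["O", "R1", "R2"],
                                    blocks50k, rank=1)
        assert r.p_value == 1.0 and r.dof == 0

    def test_distinct_branches_rejected(self, blocks50k):
        """Rank 0 is rejected when the two left pops split across branches."""
        rejected = 0
        for rep in range(10):
            cfg = simulate.SimConfig(n_snps=50_000, seed=100 + rep)
            pf = simulate.simulate_admixture_freqs(two_source_graph(), cfg,
                                                   seed=100 + rep)
            mat, labels = simulate.sample_individuals_from_freqs(
                {k: pf[k] for k in ["O", "A", "B", "R1", "R2"]}, 10,
                seed=200 + rep)
            groups = fstats.group_frequencies(mat, labels)
            r = fstats.qpwave_rank_test(groups, ["A", "B"], ["O", "R1", "R2"],
                                        blocks50k, rank=0)
            rejected += r.p_value < 0.01
        assert rejected >= 9

    def test_invariant_to_permuting_trailing_rights(self, blocks50k):
        cfg = simulate.SimConfig(n_snps=50_000, seed=10)
        pf = simulate.simulate_admixture_freqs(two_source_graph(), cfg)
        mat, labels = simulate.sample_individuals_from_freqs(
            {k: pf[k] for k in ["O", "A", "adm", "R1", "R2"]}, 10, seed=11)
        groups = fstats.group_frequencies(mat, labels)
        a = fstats.qpwave_rank_test(groups, ["A", "adm"], ["O", "R1", "R2"],
                                    blocks50k, rank=0)
        b = fstats.qpwave_rank_test(groups, ["A", "adm"], ["O", "R2", "R1"],
                                    blocks50k, rank=0)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)


class TestQpAdm:
    def test_target_equal_to_source(self, blocks50k):
        """Weights collapse to (1, 0) with a large p when target = source1."""
        cfg = simulate.SimConfig(n_snps=50_000, seed=12)
        pf = simulate.simulate_admixture_freqs(two_source_graph(), cfg)
        pf["T"] = pf["A"].copy()
        groups = freq_groups(pf)
        r = fstats.qpadm_weights(groups, "T", ["A", "B"],
                                 ["O", "R1", "R2"], blocks50k)
        assert r.weights[0] == pytest.approx(1.0, abs=1e-6)
        assert r.weights[1] == pytest.approx(0.0, abs=1e-6)
        assert r.p_value > 0.9

    def test_alpha_recovery_single(self, blocks50k):
        cfg = simulate.SimConfig(n_snps=50_000, seed=13)
        pf = simulate.simulate_admixture_freqs(two_source_graph(0.3), cfg)
        mat, labels = simulate.sample_individuals_from_freqs(
            {k: pf[k] for k in ["O", "A", "B", "R1", "R2", "adm"]}, 15,
            seed=14)
        groups = fstats.group_frequencies(mat, labels)
        r = fstats.qpadm_weights(groups, "adm", ["A", "B"],
                                 ["O", "R1", "R2"], blocks50k)
        assert abs(r.weights[0] - 0.3) < 3 * r.se[0]
        assert r.feasible
        assert r.weights.sum() == pytest.approx(1.0)

    def test_invariant_to_permuting_trailing_rights(self, blocks50k):
        cfg = simulate.SimConfig(n_snps=50_000, seed=15)
        pf = simulate.simulate_admixture_freqs(two_source_graph(0.4), cfg)
        mat, labels = simulate.sample_individuals_from_freqs(
            {k: pf[k] for k in ["O", "A", "B", "R1", "R2", "adm"]}, 12,
            seed=16)
        groups = fstats.group_frequencies(mat, labels)
        a = fstats.qpadm_weights(groups, "adm", ["A", "B"],
                                 ["O", "R1", "R2"], blocks50k)
        b = fstats.qpadm_weights(groups, "adm", ["A", "B"],
                                 ["O", "R2", "R1"], blocks50k)
        assert a.weights[0] == pytest.approx(b.weights[0], rel=1e-8)

    def test_contamination_artifact_sign(self, blocks50k):
        """A target carrying 1% outside ancestry is modelled with a small
        positive weight on the outside source; the reciprocal model yields
        the mirrored small negative weight."""
        n = 50_000
        cfg = simulate.SimConfig(n_snps=n, seed=17)
        graph = two_source_graph()
        graph["out"] = ("drift", "anc", 0.08)
        graph["R3"] = ("drift", "out", 0.01)
        graph["contam"] = ("admix", "A", "out", 0.99, 0.0)
        pf = simulate.simulate_admixture_freqs(graph, cfg)
        groups = freq_groups(pf, count=2000)
        r = fstats.qpadm_weights(groups, "contam", ["A", "out"],
                                 ["O", "R1", "R2", "R3"], blocks50k)
        assert 0.0 < r.weights[1] < 0.05
        rec = fstats.qpadm_weights(groups, "A", ["contam", "out"],
                                   ["O", "R1", "R2", "R3"], blocks50k)
        assert -0.05 < rec.weights[1] < 0.0
        assert not rec.feasible

    def test_rights_must_be_disjoint(self, blocks50k):
        p = np.random.default_rng(18).uniform(0.1, 0.9, 50_000)
        groups = freq_groups({"T": p, "S": p.copy(), "O": p.copy()})
        with pytest.raises(ValueError, match="disjoint"):
            fstats.qpadm_weights(groups, "T", ["S"], ["S", "O"], blocks50k)


def test_assign_blocks_physical_fallback():
    panel = simulate.synthetic_snp_panel(2200)
    nogen = io.SnpPanel(panel.snp_id, panel.chromosome, panel.position * 200,
                        panel.ref, panel.alt, None)
    with pytest.warns(UserWarning, match="physical windows"):
        blocks = fstats.assign_blocks(nogen, 5.0, fallback_mb=5.0)
    assert len(np.unique(blocks)) >= 22
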