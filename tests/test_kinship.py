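"""PMR estimation, degree classification, IBD EM, relative pruning."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from paleokin import io, kinship, simulate
from paleokin.pedigree import Pedigree


def hap(ids, rows):
    return io.GenotypeMatrix(ids, "haploid", np.array(rows, dtype=np.int8))


class TestPairwiseMismatchRate:
    def test_hand_counted_example(self):
        m = hap(["A", "B"], [[0, 0, 1, 1], [0, 1, 1, 0]])
        est = kinship.pairwise_mismatch_rate(m, ("A", "B"),
                                             autosomes_only=False)
        assert (est.pmr, est.n_overlap) == (0.5, 4)

    def test_missing_sites_excluded(self):
        m = hap(["A", "B"], [[0, io.MISSING, 1], [0, 1, io.MISSING]])
        est = kinship.pairwise_mismatch_rate(m, ("A", "B"),
                                             autosomes_only=False)
        assert (est.n_overlap, est.pmr) == (1, 0.0)

    def test_zero_overlap_raises(self):
        m = hap(["A", "B"], [[0, io.MISSING], [io.MISSING, 1]])
        with pytest.raises(kinship.NoOverlapError, match="A, B"):
            kinship.pairwise_mismatch_rate(m, ("A", "B"),
                                           autosomes_only=False)

    def test_matches_naive_loop_oracle(self, rng):
        """Vectorized counts equal a per-site loop on random data."""
        calls = rng.integers(-1, 2, size=(2, 10_000)).astype(np.int8)
        m = hap(["A", "B"], calls)
        est = kinship.pairwise_mismatch_rate(m, ("A", "B"),
                                             autosomes_only=False)
        n_overlap = n_mismatch = 0
        for s in range(10_000):
            a, b = calls[0, s], calls[1, s]
            if a != io.MISSING and b != io.MISSING:
                n_overlap += 1
                n_mismatch += int(a != b)
        assert (est.n_overlap, est.n_mismatch) == (n_overlap, n_mismatch)

    def test_autosomes_only_uses_panel(self):
        panel = simulate.synthetic_snp_panel(46)
        chrom = panel.chromosome.copy()
        chrom[:2] = ["X", "Y"]  # first two SNPs off-autosome
        panel = io.SnpPanel(panel.snp_id, chrom, panel.position, panel.ref,
                            panel.alt, panel.genetic_pos)
        calls = np.zeros((2, 46), dtype=np.int8)
        calls[1, :2] = 1  # mismatches only on X/Y
        m = hap(["A", "B"], calls)
        est = kinship.pairwise_mismatch_rate(m, ("A", "B"), panel)
        assert est.n_overlap == 44 and est.n_mismatch == 0

    def test_matrix_agrees_with_per_pair(self, rng):
        calls = rng.integers(-1, 2, size=(5, 2_000)).astype(np.int8)
        m = hap([f"i{k}" for k in range(5)], calls)
        overlap, mismatch = kinship.pairwise_mismatch_matrix(m)
        for i, j in itertools.combinations(range(5), 2):
            est = kinship.pairwise_mismatch_rate(
                m, (f"i{i}", f"i{j}"), autosomes_only=False)
            assert overlap[i, j] == est.n_overlap
            assert mismatch[i, j] == est.n_mismatch


class TestBackgroundPmr:
    def test_unrelated_panel_at_half_frequency(self):
        n = 100_000
        g, _ = simulate.sample_individuals_from_freqs(
            {"P": np.full(n, 0.5)}, 12, seed=1)
        h = io.pseudo_haploidize(g, seed=2)
        summ = kinship.background_pmr(h)
        assert abs(summ.baseline - 0.5) < 3 * np.sqrt(0.25 / n)
        assert not summ.suspicious

    def test_identical_twin_panel_flagged(self):
        n = 50_000
        g, _ = simulate.sample_individuals_from_freqs(
            {"P": np.full(n, 0.5)}, 1, seed=3)
        twin = io.GenotypeMatrix(["t1", "t2"], "diploid",
                                 np.vstack([g.calls, g.calls]))
        h = io.pseudo_haploidize(twin, seed=4)
        # two pseudo-haploid copies of one genotype mismatch at half the
        # het sites: PMR ~ (1 - kappa) * b = 0.5 * 0.5 = 0.25; against the
        # known expected heterozygosity the baseline is flagged
        summ = kinship.background_pmr(h, expected_het=0.5)
        assert abs(summ.baseline - 0.25) < 0.01
        assert summ.suspicious

    def test_embedded_relatives_flagged_internally(self):
        n = 50_000
        g, _ = simulate.sample_individuals_from_freqs(
            {"P": np.full(n, 0.5)}, 6, seed=5)
        calls = np.vstack([g.calls, g.calls[:1]])  # duplicate one individual
        dup = io.GenotypeMatrix([f"i{k}" for k in range(7)], "diploid", calls)
        h = io.pseudo_haploidize(dup, seed=6)
        summ = kinship.background_pmr(h)
        assert summ.suspicious
        assert ("i0", "i6") in summ.low_pairs

    def test_single_pair_panel_is_exact(self):
        m = hap(["A", "B"], [[0, 0, 1, 1], [0, 1, 1, 0]])
        summ = kinship.background_pmr(m)
        assert summ.baseline == 0.5 and summ.n_pairs == 1

    def test_too_few_individuals(self):
        m = hap(["A"], [[0, 1]])
        with pytest.raises(kinship.InsufficientPanelError):
            kinship.background_pmr(m)

    def test_exclusions_respected(self):
        m = hap(["A", "B", "C"], [[0, 0], [0, 0], [1, 1]])
        summ = kinship.background_pmr(
            m, exclude_pairs=[("A", "B")])
        assert summ.n_pairs == 2


class TestClassifyDegree:
    @pytest.mark.parametrize("norm,degree", [
        (0.50, "identical"), (0.74, "first"), (0.85, "second"),
        (0.93, "third"), (0.99, "unrelated"),
        (0.90625, "third"),    # boundary tie -> more distant degree
        (0.96875, "unrelated"),
    ])
    def test_midpoint_partition(self, norm, degree):
        # n_overlap chosen so pmr/baseline is exactly representable
        n = 64_000
        est = kinship.PmrEstimate(("a", "b"), n, int(norm * 0.5 * n))
        call = kinship.classify_degree(est, 0.5)
        assert call.degree == degree
        assert call.normalized_pmr == norm

    def test_low_confidence_flag(self):
        est = kinship.PmrEstimate(("a", "b"), 500, 250)
        assert kinship.classify_degree(est, 0.5).low_confidence
        assert not kinship.classify_degree(
            kinship.PmrEstimate(("a", "b"), 20_000, 10_000), 0.5).low_confidence

    def test_nonpositive_baseline_rejected(self):
        est = kinship.PmrEstimate(("a", "b"), 10, 5)
        with pytest.raises(ValueError, match="baseline"):
            kinship.classify_degree(est, 0.0)

    def test_degree_recovery_across_replicates(self):
        """PO, half-sib, cousin-grade and unrelated pairs are recovered in
        >= 95% of replicates at 1e5 overlapping SNPs."""
        n = 100_000
        ped = Pedigree()
        ped.add_member("gf", sex="M")
        ped.add_member("gm", sex="F")
        ped.add_member("m1", sex="F")
        ped.add_member("m2", sex="F")
        ped.add_member("p1", sex="M", father="gf", mother="gm")
        ped.add_member("p2", sex="M", father="gf", mother="gm")
        ped.add_member("w2", sex="F")
        ped.add_member("c1", sex="M", father="p1", mother="m1")
        ped.add_member("c2", sex="M", father="p2", mother="m2")
        ped.add_member("g2", sex="M", father="c2", mother="w2")
        ped.add_member("u", sex="M")
        pairs = {("p1", "c1"): "first", ("c1", "c2"): "third",
                 ("p1", "g2"): "third", ("p1", "c2"): "second",
                 ("p1", "u"): "unrelated"}
        freqs = np.full(n, 0.5)
        hits = {p: 0 for p in pairs}
        reps = 25
        for rep in range(reps):
            g, truth = simulate.simulate_pedigree_genotypes(
                ped, freqs, seed=1000 + rep)
            h = io.pseudo_haploidize(g, seed=2000 + rep)
            for pair, want in pairs.items():
                assert truth.degree(*pair) == want
                est = kinship.pairwise_mismatch_rate(h, pair,
                                                     autosomes_only=False)
                call = kinship.classify_degree(est, 0.5)
                hits[pair] += call.degree == want
        for pair, n_hit in hits.items():
            assert n_hit >= int(0.95 * reps), (pair, n_hit)


class TestGenotypeLikelihoods:
    def test_no_reads_uninformative(self):
        gl = kinship.genotype_likelihoods([0], [0], 0.01)
        assert np.allclose(gl, 1 / 3)

    def test_balanced_reads_favor_het(self):
        gl = kinship.genotype_likelihoods([5], [5], 0.01)
        assert gl[0].argmax() == 1

    def test_matches_binomial_formula(self, rng):
        """Closed-form oracle via scipy binomial pmf, to 1e-12."""
        ref = rng.integers(0, 30, size=200)
        alt = rng.integers(0, 30, size=200)
        e = 0.013
        gl = kinship.genotype_likelihoods(ref, alt, e)
        for s in range(200):
            n = ref[s] + alt[s]
            if n == 0:
                expected = np.full(3, 1 / 3)
            else:
                raw = np.array([sps.binom.pmf(alt[s], n, p)
                                for p in (e, 0.5, 1 - e)])
                expected = raw / raw.sum()
            assert np.allclose(gl[s], expected, atol=1e-12)

    def test_error_out_of_range(self):
        with pytest.raises(ValueError, match="base_error"):
            kinship.genotype_likelihoods([1], [1], 0.0)


def _pair_gls(genos_a, genos_b, freqs, depth, seed, base_error=0.001):
    """Reads + likelihoods for two diploid genotype vectors."""
    g = io.GenotypeMatrix(["a", "b"], "diploid",
                          np.vstack([genos_a, genos_b]).astype(np.int8))
    cfg = simulate.SimConfig(n_snps=len(freqs), mean_depth=depth,
                             base_error=base_error)
    rc = simulate.simulate_reads(g, cfg, seed=seed)
    return (kinship.genotype_likelihoods(*rc.row("a"), base_error),
            kinship.genotype_likelihoods(*rc.row("b"), base_error))


class TestIbdCoefficients:
    def setup_method(self):
        self.n = 30_000
        self.freqs = np.random.default_rng(7).uniform(0.05, 0.95, self.n)

    def test_identical_copies_estimate_k2(self):
        g = np.random.default_rng(8).binomial(2, self.freqs)
        gla, glb = _pair_gls(g, g, self.freqs, depth=8.0, seed=1)
        r = kinship.estimate_ibd_coefficients(gla, glb, self.freqs)
        assert r.k2 >= 0.95

    def test_parent_offspring(self):
        ped = Pedigree()
        ped.add_member("F", sex="M")
        ped.add_member("M", sex="F")
        ped.add_member("C", sex="M", father="F", mother="M")
        g, _ = simulate.simulate_pedigree_genotypes(ped, self.freqs, seed=9)
        gla, glb = _pair_gls(g.row("F"), g.row("C"), self.freqs, 5.0, seed=2)
        r = kinship.estimate_ibd_coefficients(gla, glb, self.freqs)
        assert r.k0 <= 0.05 and r.k1 >= 0.9

    def test_unrelated_pair(self):
        rng = np.random.default_rng(10)
        ga = rng.binomial(2, self.freqs)
        gb = rng.binomial(2, self.freqs)
        gla, glb = _pair_gls(ga, gb, self.freqs, 5.0, seed=3)
        r = kinship.estimate_ibd_coefficients(gla, glb, self.freqs)
        assert r.k0 >= 0.9

    def test_simplex_and_monotone_loglik(self):
        """EM keeps (k0,k1,k2) on the simplex; log-likelihood never drops."""
        rng = np.random.default_rng(11)
        ga = rng.binomial(2, self.freqs)
        gb = rng.binomial(2, self.freqs)
        gla, glb = _pair_gls(ga, gb, self.freqs, 2.0, seed=4)
        lls = []
        for iters in (1, 2, 5, 10, 30, 100):
            r = kinship.estimate_ibd_coefficients(
                gla, glb, self.freqs, max_iter=iters, tol=0.0)
            assert abs(r.k0 + r.k1 + r.k2 - 1.0) < 1e-9
            assert min(r.k0, r.k1, r.k2) >= 0
            lls.append(r.log_likelihood)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))
        assert 0.0 <= r.kappa <= 0.5

    def test_too_few_sites_rejected(self):
        gl = np.full((50, 3), 1 / 3)
        with pytest.raises(ValueError, match="informative sites"):
            kinship.estimate_ibd_coefficients(gl, gl, np.full(50, 0.5))


class TestDisambiguateFirstDegree:
    @pytest.mark.parametrize("k,expected", [
        ((0.01, 0.97, 0.02), "parent_offspring"),
        ((0.25, 0.50, 0.25), "full_sibling"),
        ((0.07, 0.85, 0.08), "undetermined"),
    ])
    def test_rule_application(self, k, expected):
        ibd = kinship.IbdCoefficients(("a", "b"), *k, log_likelihood=0.0,
                                      n_sites_used=1000)
        assert kinship.disambiguate_first_degree(ibd) == expected


def _call(a, b, degree):
    return kinship.DegreeCall((a, b), 1.0, degree, 50_000)


class TestPruneRelatives:
    def test_jar_coffin_degrees_keep_three(self):
        """The observed degree matrix admits a maximum unrelated set of 3."""
        first = [("GUC002", "GUC001"), ("GUC002", "GUC007"),
                 ("GUC004", "GUC001"), ("GUC004", "GUC007"),
                 ("GUC001", "GUC007"), ("GUC004", "GUC005")]
        second = [("GUC005", "GUC001"), ("GUC005", "GUC007")]
        third = [("GUC002", "GUC003")]
        ids = ["GUC001", "GUC002", "GUC003", "GUC004", "GUC005", "GUC007"]
        calls = [_call(a, b, "first") for a, b in first]
        calls += [_call(a, b, "second") for a, b in second]
        calls += [_call(a, b, "third") for a, b in third]
        for a, b in itertools.combinations(ids, 2):
            if not any({a, b} == set(p) for p in first + second + third):
                calls.append(_call(a, b, "unrelated"))
        coverage = {"GUC001": 1.2, "GUC002": 5.4, "GUC003": 2.1,
                    "GUC004": 2.6, "GUC005": 6.8, "GUC007": 5.4}
        retained = kinship.prune_relatives(calls, coverage)
        assert len(retained) == 3
        assert retained == ["GUC002", "GUC003", "GUC005"]

    def test_unrelated_set_fully_retained(self):
        calls = [_call(a, b, "unrelated")
                 for a, b in itertools.combinations("abcd", 2)]
        assert kinship.prune_relatives(calls) == list("abcd")

    def test_matches_exhaustive_oracle_on_random_graphs(self, rng):
        """Retained set size equals brute-force max independent set."""
        for trial in range(20):
            n = int(rng.integers(3, 11))
            ids = [f"i{k}" for k in range(n)]
            calls = []
            edges = set()
            for a, b in itertools.combinations(ids, 2):
                related = rng.random() < 0.3
                calls.append(_call(a, b, "first" if related else "unrelated"))
                if related:
                    edges.add(frozenset({a, b}))
            best = 0
            for size in range(n, 0, -1):
                if any(all(frozenset({a, b}) not in edges
                           for a, b in itertools.combinations(sub, 2))
                       for sub in itertools.combinations(ids, size)):
                    best = size
                    break
            retained = kinship.prune_relatives(calls)
            assert len(retained) == best
            for a, b in itertools.combinations(retained, 2):
                assert frozenset({a, b}) not in edges
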