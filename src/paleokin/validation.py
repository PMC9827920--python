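"""Replicate simulation studies validating the estimators' calibration.

These studies are the package's own acceptance surface: each simulates data
with known ground truth under the jar-coffin study conditions (or a small
admixture graph), runs the corresponding estimator end to end, and reports
recovery/calibration rates.  They are used both by the test suite and by
``scripts/acceptance.py``.

All randomness in a study derives from its single ``seed`` via
``numpy.random.SeedSequence`` spawning, so results are reproducible and
replicates are independent.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import fstats, io, kinship, pipeline, simulate
from .pedigree import co_maximal, enumerate_pedigrees


def _seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)


def two_source_graph(alpha: float = 0.3) -> dict:
    """Small calibrated admixture graph: outgroup, two source branches with
    one sister ("right") population each, and an admixed target."""
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


def degree_pattern_study(seed, n_reps: int = 100, n_snps: int = 100_000,
                         missingness: float = 0.5, panel_size: int = 102
                         ) -> dict:
    """How often does the PMR classifier report the exact 6/2/1 pattern?

    Each replicate simulates the jar-coffin pedigree, pseudo-haploidizes
    with independent per-individual missingness, normalizes against a
    simulated unrelated panel and classifies all 15 pairs.  The exact
    pattern requires 6 first-, 2 second-, 1 third-degree and 6 unrelated
    calls.  Note the two kappa = 1/32 pairs (GUC003 vs the quartet
    children) whose expected normalized PMR lies exactly on the
    third/unrelated midpoint; see the methods note.
    """
    children = _seedseq(seed).spawn(n_reps)
    n_exact = 0
    patterns = []
    for child in children:
        r = pipeline.scenario_degree_counts(child, n_snps=n_snps,
                                            missingness=missingness,
                                            panel_size=panel_size)
        o = r["observed"]
        pattern = (o["first"], o["second"], o["third"], o["unrelated"])
        patterns.append(pattern)
        n_exact += pattern == (6, 2, 1, 6)
    return {"n_reps": n_reps, "n_exact": n_exact,
            "fraction_exact": n_exact / n_reps, "patterns": patterns}


def first_degree_study(seed, n_snps: int = 100_000, mean_depth: float = 2.0
                       ) -> dict:
    """Read-level disambiguation of the first-degree pairs, plus the
    pedigree search and relative pruning, on one fixed-seed replicate."""
    scen = pipeline.simulate_jar_coffin_scenario(
        seed, n_snps=n_snps, missingness=0.0, panel_size=2,
        mean_depth=mean_depth)
    truth = scen["truth"]
    rc = scen["read_counts"]
    freqs = np.clip(scen["freqs"], 1e-3, 1 - 1e-3)
    base_error = simulate.SimConfig().base_error
    ids = rc.individual_ids
    gls = {i: kinship.genotype_likelihoods(*rc.row(i), base_error)
           for i in ids}

    po_k0, sib = [], None
    types = {}
    for a, b in itertools.combinations(ids, 2):
        pair = frozenset({a, b})
        if truth.degree(a, b) != "first":
            continue
        ibd = kinship.estimate_ibd_coefficients(gls[a], gls[b], freqs,
                                                pair=(a, b))
        types[pair] = kinship.disambiguate_first_degree(ibd)
        if truth.k_coefficients[pair][1] == 1.0:   # parent-offspring truth
            po_k0.append(ibd.k0)
        else:
            sib = ibd

    degrees = {frozenset({a, b}): truth.degree(a, b)
               for a, b in itertools.combinations(ids, 2)}
    reports = enumerate_pedigrees(scen["meta"], degrees, types,
                                  max_latent=2, max_generations=3)
    top = co_maximal(reports)

    def is_truth(ped):
        return ("GUC004" in ped.parents("GUC005")
                and set(ped.parents("GUC001")) == {"GUC002", "GUC004"}
                and set(ped.parents("GUC007")) == {"GUC002", "GUC004"}
                and ped.y_clans()["GUC003"] == ped.y_clans()["GUC002"])

    calls = [kinship.DegreeCall((a, b), 1.0, degrees[frozenset({a, b})],
                                n_snps)
             for a, b in itertools.combinations(ids, 2)]
    retained = kinship.prune_relatives(calls)

    return {
        "po_k0_max": max(po_k0), "n_po_pairs": len(po_k0),
        "sibling_k0": sib.k0, "sibling_k2": sib.k2,
        "sibling_called": types[frozenset({"GUC001", "GUC007"})],
        "truth_in_co_maximal": any(is_truth(r.pedigree) for r in top),
        "maternal_option_ranked_first":
            bool(reports and "GUC004" in reports[0].pedigree.parents("GUC005")),
        "n_alternates": len(reports),
        "pruned_set": retained,
    }


def f4_null_study(seed, n_reps: int = 100, n_snps: int = 50_000,
                  n_per_pop: int = 10) -> dict:
    """|Z| of f4 under cladality: (C, D) a clade relative to (A, B)."""
    panel = simulate.synthetic_snp_panel(n_snps)
    blocks = fstats.assign_blocks(panel)
    children = _seedseq(seed).spawn(n_reps)
    zs = []
    for child in children:
        rng_g, rng_s = simulate.split_rng(child, 2)
        graph = {"anc": ("root",), "A": ("drift", "anc", 0.05),
                 "mid": ("drift", "anc", 0.03), "B": ("drift", "mid", 0.02),
                 "cd": ("drift", "mid", 0.02), "C": ("drift", "cd", 0.01),
                 "D": ("drift", "cd", 0.01)}
        cfg = simulate.SimConfig(n_snps=n_snps)
        pf = simulate.simulate_admixture_freqs(graph, cfg, seed=rng_g)
        mat, labels = simulate.sample_individuals_from_freqs(
            {k: pf[k] for k in ["A", "B", "C", "D"]}, n_per_pop, seed=rng_s)
        groups = fstats.group_frequencies(mat, labels)
        zs.append(fstats.f4(groups, "A", "B", "C", "D", blocks).z)
    zs = np.abs(zs)
    return {"n_reps": n_reps, "fraction_z_lt_3": float((zs < 3).mean()),
            "max_abs_z": float(zs.max())}


def qpadm_recovery_study(seed, n_reps: int = 100, n_snps: int = 100_000,
                         alpha: float = 0.3, n_per_pop: int = 15) -> dict:
    """Does qpAdm recover the simulated mixture proportion within 2 s.e.?"""
    panel = simulate.synthetic_snp_panel(n_snps)
    blocks = fstats.assign_blocks(panel)
    children = _seedseq(seed).spawn(n_reps)
    hits, estimates = 0, []
    for child in children:
        rng_g, rng_s = simulate.split_rng(child, 2)
        cfg = simulate.SimConfig(n_snps=n_snps)
        pf = simulate.simulate_admixture_freqs(two_source_graph(alpha), cfg,
                                               seed=rng_g)
        mat, labels = simulate.sample_individuals_from_freqs(
            {k: pf[k] for k in ["O", "A", "B", "R1", "R2", "adm"]},
            n_per_pop, seed=rng_s)
        groups = fstats.group_frequencies(mat, labels)
        r = fstats.qpadm_weights(groups, "adm", ["A", "B"],
                                 ["O", "R1", "R2"], blocks)
        estimates.append(r.weights[0])
        hits += abs(r.weights[0] - alpha) <= 2 * r.se[0]
    return {"n_reps": n_reps, "fraction_within_2se": hits / n_reps,
            "mean_alpha_hat": float(np.mean(estimates)),
            "alpha_true": alpha}


def qpwave_null_study(seed, n_reps: int = 200, n_snps: int = 50_000,
                      n_per_pop: int = 10) -> dict:
    """Uniformity of the rank-0 qpWave p-value when the two left
    populations are independent samples of identical frequencies."""
    panel = simulate.synthetic_snp_panel(n_snps)
    blocks = fstats.assign_blocks(panel)
    children = _seedseq(seed).spawn(n_reps)
    pvals = []
    for child in children:
        rng_g, rng_s = simulate.split_rng(child, 2)
        graph = {"anc": ("root",), "O": ("drift", "anc", 0.1),
                 "mid": ("drift", "anc", 0.02), "L": ("drift", "mid", 0.01),
                 "R1": ("drift", "mid", 0.02), "R2": ("drift", "anc", 0.05)}
        cfg = simulate.SimConfig(n_snps=n_snps)
        pf = simulate.simulate_admixture_freqs(graph, cfg, seed=rng_g)
        pf["L2"] = pf["L"]
        mat, labels = simulate.sample_individuals_from_freqs(
            {k: pf[k] for k in ["O", "L", "L2", "R1", "R2"]}, n_per_pop,
            seed=rng_s)
        groups = fstats.group_frequencies(mat, labels)
        pvals.append(fstats.qpwave_rank_test(
            groups, ["L", "L2"], ["O", "R1", "R2"], blocks, rank=0).p_value)
    pvals = np.array(pvals)
    return {"n_reps": n_reps,
            "fraction_below_0.05": float((pvals < 0.05).mean()),
            "median_p": float(np.median(pvals))}
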