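"""End-to-end orchestration: kinship chain, popgen chain, reporting.

The kinship chain mirrors the standard low-coverage aDNA workflow:
pseudo-haploid calls -> all-pairs PMR -> baseline normalization against a
reference panel -> degree classification -> genotype-likelihood IBD
coefficients for first-degree pairs -> exhaustive pedigree enumeration.
The popgen chain runs outgroup-f3 affinity ranking, an f4 symmetry scan,
qpWave cladality tests and qpAdm models with smallest-submodel reduction.

Everything is deterministic given the master seed, and every number in a
report traces to a module output.  Reports carry a provenance block
(package version, config hash, seed) sufficient to re-run exactly.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import MISSING, GenotypeMatrix, IndividualMeta, ReadCounts, SnpPanel
from . import fstats, io, kinship, simulate, pedigree as ped_mod


@dataclass
class RunConfig:
    """Run-level knobs shared by the pipeline stages."""

    seed: int = 0
    window_cm: float = 5.0
    base_error: float = 0.001
    min_overlap: int = 10_000
    max_latent: int = 4
    max_generations: int = 3
    submodel_alpha: float = 0.05

    def validate(self) -> None:
        if self.window_cm <= 0:
            raise ValueError("jackknife window must be positive")
        if self.seed is None:
            raise ValueError("a master seed is required")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.validate()
        return cfg


def _provenance(config: RunConfig) -> dict:
    return {"version": __version__, "config_hash": config.hash(),
            "seed": config.seed}


@dataclass
class KinshipReport:
    kinship_table: pd.DataFrame
    baseline: kinship.BaselineSummary | None
    degree_counts: dict[str, int]
    first_degree_types: dict
    pedigree_reports: list
    provenance: dict

    def to_jsonable(self) -> dict:
        peds = []
        for rep in self.pedigree_reports:
            peds.append({
                "score": rep.score,
                "violations": rep.violations,
                "trios": rep.pedigree.to_trio_table().to_dict("records"),
                "diagram": rep.pedigree.render(),
            })
        return {
            "kinship_table": self.kinship_table.to_dict("records"),
            "baseline": (asdict(self.baseline) if self.baseline else None),
            "degree_counts": self.degree_counts,
            "first_degree_types": {"|".join(sorted(k)): v for k, v
                                   in self.first_degree_types.items()},
            "pedigrees": peds,
            "provenance": self.provenance,
        }


def panel_allele_frequencies(panel_matrix: GenotypeMatrix,
                             eps: float = 1e-3) -> np.ndarray:
    """Pooled sample alt frequencies of a reference panel, clipped away from
    0/1 so they can serve as the IBD-likelihood reference frequencies."""
    calls = panel_matrix.calls
    mult = 1 if panel_matrix.ploidy == "haploid" else 2
    ok = calls != MISSING
    alt = np.where(ok, calls, 0).sum(axis=0).astype(float)
    tot = ok.sum(axis=0) * mult if mult == 1 else ok.sum(axis=0) * 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), 0.5)
    return np.clip(p, eps, 1.0 - eps)


def run_kinship_pipeline(sample: GenotypeMatrix, meta: list[IndividualMeta],
                         panel_matrix: GenotypeMatrix, snp_panel: SnpPanel,
                         config: RunConfig,
                         read_counts: ReadCounts | None = None,
                         allele_freqs: np.ndarray | None = None,
                         enumerate_pedigrees: bool = True) -> KinshipReport:
    """PMR -> baseline -> degrees -> k-coefficients -> pedigree search."""
    config.validate()
    ids = sample.individual_ids
    meta_by_id = {m.id: m for m in meta}
    rows = []
    calls: dict[frozenset, kinship.DegreeCall] = {}
    if len(ids) >= 2:
        baseline = kinship.background_pmr(panel_matrix, panel=snp_panel)
        for a, b in itertools.combinations(ids, 2):
            est = kinship.pairwise_mismatch_rate(sample, (a, b), snp_panel)
            call = kinship.classify_degree(est, baseline.baseline,
                                           min_overlap=config.min_overlap)
            calls[frozenset({a, b})] = call
            rows.append({
                "individual_a": a, "individual_b": b,
                "n_overlap": est.n_overlap, "pmr": est.pmr, "se": est.se,
                "normalized_pmr": call.normalized_pmr, "degree": call.degree,
                "low_confidence": call.low_confidence,
                "k0": np.nan, "k1": np.nan, "k2": np.nan, "call": call.degree,
            })
    else:
        baseline = None

    table = pd.DataFrame(rows, columns=[
        "individual_a", "individual_b", "n_overlap", "pmr", "se",
        "normalized_pmr", "degree", "low_confidence", "k0", "k1", "k2",
        "call"])

    first_types: dict[frozenset, str] = {}
    if read_counts is not None and len(ids) >= 2:
        freqs = (allele_freqs if allele_freqs is not None
                 else panel_allele_frequencies(panel_matrix))
        gls = {i: kinship.genotype_likelihoods(
            *read_counts.row(i), config.base_error) for i in ids}
        for idx, row in table.iterrows():
            if row["degree"] != "first":
                continue
            a, b = row["individual_a"], row["individual_b"]
            ibd = kinship.estimate_ibd_coefficients(
                gls[a], gls[b], freqs, pair=(a, b))
            kind = kinship.disambiguate_first_degree(ibd)
            first_types[frozenset({a, b})] = kind
            table.loc[idx, ["k0", "k1", "k2"]] = (ibd.k0, ibd.k1, ibd.k2)
            table.loc[idx, "call"] = kind

    counts = {d: 0 for d in kinship.DEGREE_NAMES}
    for call in calls.values():
        counts[call.degree] += 1

    reports = []
    if enumerate_pedigrees and len(ids) >= 2:
        degrees = {k: v.degree for k, v in calls.items()}
        reports = ped_mod.enumerate_pedigrees(
            [meta_by_id[i] for i in ids], degrees, first_types,
            max_latent=config.max_latent,
            max_generations=config.max_generations)

    return KinshipReport(kinship_table=table, baseline=baseline,
                         degree_counts=counts, first_degree_types=first_types,
                         pedigree_reports=reports,
                         provenance=_provenance(config))


@dataclass
class PopgenReport:
    f3_ranking: pd.DataFrame
    f4_scan: pd.DataFrame
    qpwave_tests: list
    qpadm_models: list
    provenance: dict

    def to_jsonable(self) -> dict:
        return {
            "f3_ranking": self.f3_ranking.to_dict("records"),
            "f4_scan": self.f4_scan.to_dict("records"),
            "qpwave": [asdict(q) for q in self.qpwave_tests],
            "qpadm": [_qpadm_jsonable(m) for m in self.qpadm_models],
            "provenance": self.provenance,
        }


def _qpadm_jsonable(res: fstats.QpAdmResult) -> dict:
    d = asdict(res)
    d["weights"] = [float(x) for x in res.weights]
    d["se"] = [float(x) for x in res.se]
    return d


def reduce_qpadm_model(groups, target, sources, rights, block_ids,
                       alpha: float = 0.05) -> list[fstats.QpAdmResult]:
    """Fit a qpAdm model, then greedily drop sources that are not needed.

    Starting from the full source list, each single-source removal is
    tried; if the best-fitting reduced model still passes the rank test
    (p > alpha), it replaces the current model, until no source can be
    dropped.  Returns the trail of accepted fits, smallest model last.
    """
    trail = [fstats.qpadm_weights(groups, target, sources, rights, block_ids)]
    current = list(sources)
    while len(current) > 1:
        candidates = []
        for drop in current:
            sub = [s for s in current if s != drop]
            try:
                fit = fstats.qpadm_weights(groups, target, sub, rights,
                                           block_ids)
            except (fstats.InsufficientDataError, ValueError):
                continue
            candidates.append(fit)
        passing = [c for c in candidates if c.p_value > alpha]
        if not passing:
            break
        best = max(passing, key=lambda c: c.p_value)
        trail.append(best)
        current = list(best.sources)
    return trail


def run_popgen_pipeline(groups: dict[str, fstats.GroupFreqs],
                        block_ids: np.ndarray, outgroup: str, target: str,
                        comparisons: list[str], reference: str,
                        qpadm_models: list[dict], config: RunConfig
                        ) -> PopgenReport:
    """f3 affinity ranking, f4 symmetry scan, qpWave and reduced qpAdm."""
    config.validate()
    f3_rows = []
    for pop in comparisons:
        r = fstats.f3_outgroup(groups, outgroup, target, pop, block_ids)
        f3_rows.append({"population": pop, "f3": r.estimate, "se": r.se,
                        "z": r.z, "n_snps": r.n_snps})
    f3_df = pd.DataFrame(f3_rows).sort_values(
        "f3", ascending=False, ignore_index=True) if f3_rows else \
        pd.DataFrame(columns=["population", "f3", "se", "z", "n_snps"])

    f4_rows = []
    for pop in comparisons:
        if pop in (target, reference, outgroup):
            continue
        r = fstats.f4(groups, outgroup, pop, target, reference, block_ids)
        f4_rows.append({"population": pop, "f4": r.estimate, "se": r.se,
                        "z": r.z, "significant": abs(r.z) >= 3,
                        "n_snps": r.n_snps})
    f4_df = pd.DataFrame(f4_rows) if f4_rows else pd.DataFrame(
        columns=["population", "f4", "se", "z", "significant", "n_snps"])

    qpwave_tests = []
    rights = qpadm_models[0]["rights"] if qpadm_models else None
    if rights:
        qpwave_tests.append(fstats.qpwave_rank_test(
            groups, [target, reference], rights, block_ids, rank=0))

    qpadm_results = []
    for model in qpadm_models:
        trail = reduce_qpadm_model(
            groups, model.get("target", target), model["sources"],
            model["rights"], block_ids, alpha=config.submodel_alpha)
        qpadm_results.extend(trail)

    return PopgenReport(f3_ranking=f3_df, f4_scan=f4_df,
                        qpwave_tests=qpwave_tests, qpadm_models=qpadm_results,
                        provenance=_provenance(config))


def write_report(report, out_dir) -> Path:
    """Write a report's JSON body (and TSV tables) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    body = report.to_jsonable()
    path = out / "report.json"
    path.write_text(json.dumps(body, indent=2, sort_keys=True,
                               default=_json_default) + "\n")
    if isinstance(report, KinshipReport):
        report.kinship_table.to_csv(out / "kinship_table.tsv", sep="\t",
                                    index=False)
    if isinstance(report, PopgenReport):
        report.f3_ranking.to_csv(out / "f3_ranking.tsv", sep="\t", index=False)
        report.f4_scan.to_csv(out / "f4_scan.tsv", sep="\t", index=False)
    return path


def simulate_jar_coffin_scenario(seed, n_snps: int = 100_000,
                                 missingness: float = 0.5,
                                 panel_size: int = 102,
                                 mean_depth: float | None = None) -> dict:
    """Build the jar-coffin family scenario with a reference panel.

    The six observed family members are pseudo-haploidized from the
    simulated diploid truth with independent per-individual site dropout
    (``missingness``); the baseline panel is ``panel_size`` unrelated
    individuals drawn from the same allele frequencies and pseudo-haploidized
    without dropout (a high-coverage present-day panel).  With ``mean_depth``
    set, Poisson read counts for the family are included for the
    genotype-likelihood stage.  All streams derive from the one seed.
    """
    rngs = simulate.split_rng(seed, 7)
    cfg = simulate.SimConfig(n_snps=n_snps)
    freqs = simulate.draw_allele_frequencies(cfg, seed=rngs[0])
    ped = simulate.gunsan_jar_coffin_pedigree()
    diploid, truth = simulate.simulate_pedigree_genotypes(ped, freqs,
                                                          seed=rngs[1])
    observed = sorted(i for i in ped.nodes if ped.nodes[i].observed)
    obs_idx = [diploid.individual_ids.index(i) for i in observed]
    obs_diploid = io.GenotypeMatrix(observed, "diploid",
                                    diploid.calls[obs_idx])
    sample = io.pseudo_haploidize(obs_diploid, seed=rngs[2])
    if missingness > 0:
        calls = sample.calls.copy()
        calls[rngs[3].random(calls.shape) < missingness] = MISSING
        sample = io.GenotypeMatrix(observed, "haploid", calls)
    panel_dip, _ = simulate.sample_individuals_from_freqs(
        {"panel": freqs}, panel_size, seed=rngs[4])
    panel = io.pseudo_haploidize(panel_dip, seed=rngs[5])
    meta = simulate.observed_meta_from_truth(ped, truth)
    out = {"pedigree": ped, "truth": truth, "diploid": obs_diploid,
           "sample": sample, "panel": panel, "meta": meta, "freqs": freqs,
           "snp_panel": simulate.synthetic_snp_panel(n_snps)}
    if mean_depth is not None:
        read_cfg = simulate.SimConfig(n_snps=n_snps, mean_depth=mean_depth)
        out["read_counts"] = simulate.simulate_reads(obs_diploid, read_cfg,
                                                     seed=rngs[6])
    return out


def scenario_degree_counts(seed, n_snps: int = 100_000,
                           missingness: float = 0.5, panel_size: int = 102
                           ) -> dict:
    """Simulate the jar-coffin scenario once and classify all 15 pairs.

    Returns the per-degree pair counts from the PMR classifier together
    with the true counts implied by the pedigree, for recovery-rate
    studies across seeds.
    """
    scen = simulate_jar_coffin_scenario(seed, n_snps=n_snps,
                                        missingness=missingness,
                                        panel_size=panel_size)
    cfg = RunConfig(seed=seed if isinstance(seed, int) else 0)
    report = run_kinship_pipeline(scen["sample"], scen["meta"], scen["panel"],
                                  scen["snp_panel"], cfg,
                                  enumerate_pedigrees=False)
    truth = scen["truth"]
    true_counts = {d: 0 for d in kinship.DEGREE_NAMES}
    ids = scen["sample"].individual_ids
    for a, b in itertools.combinations(ids, 2):
        true_counts[truth.degree(a, b)] += 1
    return {"observed": report.degree_counts, "true": true_counts,
            "table": report.kinship_table}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
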