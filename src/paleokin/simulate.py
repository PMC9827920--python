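"""Synthetic genotype, read-count and allele-frequency generators.

Everything downstream (PMR kinship, IBD coefficients, pedigree search,
f-statistics) can be exercised end-to-end on data with known ground truth:

* pedigree-structured diploid genotypes: founders drawn under Hardy-Weinberg
  equilibrium, children by Mendelian transmission at unlinked SNPs;
* low-coverage sequencing reads: Poisson depth, per-read base error, an
  optional contaminant allele-frequency profile, extra forced missingness;
* admixture-graph population frequencies: Brownian (Balding-Nichols-style)
  drift with variance ``d * p (1 - p)`` per branch and frequency mixing
  ``alpha * p1 + (1 - alpha) * p2`` at admixture events.

SNPs are simulated unlinked -- sufficient for mismatch-rate and k-coefficient
moments; IBD *segment* structure is deliberately not modelled.  Genetic
positions for jackknife blocks are assigned synthetically: SNPs evenly
spaced at 0.01 cM on 22 pseudo-chromosomes.

All randomness flows from one seed: each operation derives independent
streams with ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, IndividualMeta, ReadCounts, SnpPanel
from .pedigree import Pedigree

_EPS = 1e-9


def _rng(seed):
    """Accept an int seed or a ready Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def split_rng(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


@dataclass
class SimConfig:
    """Knobs of the low-coverage sequencing emulation.

    Defaults mirror a well-preserved 1240K-captured ancient sample: around
    one read per targeted site, Q30-filtered bases (0.1% error), negligible
    contamination, no extra site dropout beyond the Poisson zeros.
    """

    n_snps: int = 100_000
    freq_model: tuple = ("beta", 1.0, 1.0)  # or an explicit vector
    mean_depth: float = 1.0
    base_error: float = 0.001
    contamination_rate: float = 0.0
    contaminant_freqs: np.ndarray | None = None
    missingness: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base_error must lie in [0, 0.5)")
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must lie in [0, 1)")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")
        if self.contamination_rate > 0 and self.contaminant_freqs is None:
            raise ValueError("contamination requires contaminant_freqs")


@dataclass
class TruthSet:
    """Ground truth attached to a pedigree simulation."""

    genotypes: GenotypeMatrix
    kappa: dict[frozenset, float]
    k_coefficients: dict[frozenset, tuple[float, float, float]]
    mt_haplogroup: dict[str, str]
    y_haplogroup: dict[str, str]

    def degree(self, a: str, b: str) -> str:
        from .kinship import degree_from_normalized_pmr
        return degree_from_normalized_pmr(1.0 - self.kappa[frozenset({a, b})])


def draw_allele_frequencies(config: SimConfig, seed=None) -> np.ndarray:
    """Per-SNP alt-allele frequencies from the configured model."""
    config.validate()
    model = config.freq_model
    if not (isinstance(model, tuple) and model and model[0] == "beta"):
        vec = np.asarray(model, dtype=float)
        if len(vec) != config.n_snps:
            raise ValueError("explicit frequency vector has wrong length")
        if not ((vec > 0) & (vec < 1)).all():
            raise ValueError("explicit frequencies must lie in (0, 1)")
        return vec.copy()
    _, a, b = model
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be positive")
    rng = _rng(config.seed if seed is None else seed)
    return np.clip(rng.beta(a, b, size=config.n_snps), _EPS, 1.0 - _EPS)


def synthetic_snp_panel(n_snps: int, n_chromosomes: int = 22,
                        cm_spacing: float = 0.01) -> SnpPanel:
    """Evenly spaced biallelic SNPs on pseudo-chromosomes 1..22."""
    idx = np.arange(n_snps)
    chrom = (idx % n_chromosomes) + 1
    within = idx // n_chromosomes
    return SnpPanel(
        snp_id=np.array([f"snp{i}" for i in idx], dtype=object),
        chromosome=chrom.astype(str).astype(object),
        position=(within + 1) * 50_000,
        ref=np.full(n_snps, "A", dtype=object),
        alt=np.full(n_snps, "G", dtype=object),
        genetic_pos=(within + 1) * cm_spacing)


def simulate_pedigree_genotypes(ped: Pedigree, freqs: np.ndarray, seed=None
                                ) -> tuple[GenotypeMatrix, TruthSet]:
    """Drop genes through a pedigree at unlinked SNPs.

    Founders are Binomial(2, p) under HWE; each child receives one uniformly
    chosen allele from each parent, independently per SNP.  Every member
    must record either no parents or both.  The returned truth carries the
    path-counting kinship coefficient and (k0, k1, k2) for every pair, plus
    maternally/paternally transmitted haplogroup labels.
    """
    ped.validate()
    freqs = np.asarray(freqs, dtype=float)
    n = len(freqs)
    for i in ped.nodes:
        if len(ped.parents(i)) == 1:
            raise ValueError(
                f"{i}: one recorded parent; record both or neither")
    if not ped.nodes:
        raise ValueError("empty pedigree")
    rng = _rng(seed)

    depth = ped._depths()
    order = sorted(ped.nodes, key=lambda i: (depth[i], i))
    haplo: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    mt: dict[str, str] = {}
    y: dict[str, str] = {}
    for i in order:
        node = ped.nodes[i]
        f, m = ped.father[i], ped.mother[i]
        if f is None:
            h1 = (rng.random(n) < freqs).astype(np.int8)
            h2 = (rng.random(n) < freqs).astype(np.int8)
            mt[i] = node.mt_hg if node.mt_hg != "unknown" else f"mt-{i}"
            y[i] = (node.y_hg if node.y_hg != "unknown" else f"y-{i}") \
                if node.sex == "M" else "unknown"
        else:
            h1 = np.where(rng.random(n) < 0.5, *haplo[f]).astype(np.int8)
            h2 = np.where(rng.random(n) < 0.5, *haplo[m]).astype(np.int8)
            mt[i] = mt[m]
            y[i] = y[f] if node.sex == "M" else "unknown"
        haplo[i] = (h1, h2)

    calls = np.stack([haplo[i][0] + haplo[i][1] for i in order])
    matrix = GenotypeMatrix(order, "diploid", calls)
    kappa, kcoef = {}, {}
    for a, b in itertools.combinations(order, 2):
        kap, k0, k1, k2 = ped.expected_kinship(a, b)
        key = frozenset({a, b})
        kappa[key] = kap
        kcoef[key] = (k0, k1, k2)
    return matrix, TruthSet(matrix, kappa, kcoef, mt, y)


def simulate_reads(genotypes: GenotypeMatrix, config: SimConfig, seed=None
                   ) -> ReadCounts:
    """Poisson-depth read counts with base error and contamination.

    Each read comes from the contaminant frequency profile with probability
    ``contamination_rate``, otherwise from the individual's genotype, and is
    mis-read with probability ``base_error``.  A further ``missingness``
    fraction of sites (independently per individual) is forced to zero
    depth, emulating capture dropout beyond the Poisson zeros.
    """
    config.validate()
    if genotypes.ploidy != "diploid":
        raise ValueError("read simulation expects diploid genotypes")
    rng = _rng(config.seed if seed is None else seed)
    g = genotypes.calls
    shape = g.shape
    depth = rng.poisson(config.mean_depth, size=shape)
    if config.missingness > 0:
        depth[rng.random(shape) < config.missingness] = 0
    p_true = np.clip(g, 0, 2) / 2.0
    c = config.contamination_rate
    if c > 0:
        pc = np.asarray(config.contaminant_freqs, dtype=float)
        p_raw = (1.0 - c) * p_true + c * pc[None, :]
    else:
        p_raw = p_true
    e = config.base_error
    p_alt = p_raw * (1.0 - e) + (1.0 - p_raw) * e
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    ref[g == -1] = 0
    alt[g == -1] = 0
    return ReadCounts(genotypes.individual_ids, ref, alt)


def simulate_admixture_freqs(graph: dict, config: SimConfig, seed=None
                             ) -> dict[str, np.ndarray]:
    """Population frequency vectors from a drift/admixture graph.

    ``graph`` maps population name -> event, in an order where parents
    precede children:

    * ``("root",)`` -- frequencies drawn from ``config.freq_model``;
    * ``("drift", parent, d)`` -- Normal perturbation with variance
      ``d * p (1 - p)``, truncated to [0, 1];
    * ``("admix", src1, src2, alpha, d)`` -- frequency mixture
      ``alpha * p1 + (1 - alpha) * p2`` followed by its own drift ``d``.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed)
    out: dict[str, np.ndarray] = {}

    def drift(p, d):
        if d < 0:
            raise ValueError("drift parameter must be >= 0")
        if d == 0:
            return p.copy()
        return np.clip(p + rng.normal(0.0, np.sqrt(d * p * (1.0 - p))), 0.0, 1.0)

    for name, event in graph.items():
        kind = event[0]
        if kind == "root":
            out[name] = draw_allele_frequencies(config, seed=rng)
        elif kind == "drift":
            _, parent, d = event
            out[name] = drift(out[parent], d)
        elif kind == "admix":
            _, s1, s2, alpha, d = event
            if not 0.0 <= alpha <= 1.0:
                raise ValueError("admixture proportion must lie in [0, 1]")
            out[name] = drift(alpha * out[s1] + (1.0 - alpha) * out[s2], d)
        else:
            raise ValueError(f"unknown graph event {kind!r}")
    return out


def sample_individuals_from_freqs(freqs: dict[str, np.ndarray], n_per_pop,
                                  seed=None
                                  ) -> tuple[GenotypeMatrix, dict[str, str]]:
    """HWE diploid individuals, Binomial(2, p) per site, per population."""
    rng = _rng(seed)
    if isinstance(n_per_pop, int):
        n_per_pop = {pop: n_per_pop for pop in freqs}
    ids, rows, labels = [], [], {}
    for pop, p in freqs.items():
        n = n_per_pop[pop]
        if n < 1:
            raise ValueError(f"{pop}: need at least one individual")
        pc = np.clip(p, 0.0, 1.0)
        # Binomial(2, p) as two Bernoulli draws: much faster at this scale
        g = ((rng.random((n, len(p))) < pc).astype(np.int8)
             + (rng.random((n, len(p))) < pc).astype(np.int8))
        for i in range(n):
            ind = f"{pop}{i}"
            ids.append(ind)
            labels[ind] = pop
        rows.append(g)
    matrix = GenotypeMatrix(ids, "diploid", np.vstack(rows))
    return matrix, labels


# ---------------------------------------------------------------------------
# The jar-coffin family scenario


def gunsan_jar_coffin_pedigree() -> Pedigree:
    """The six-individual extended family recovered from the Gunsan jar coffin.

    Core quartet: couple GUC002 x GUC004 with children GUC001 (adult male)
    and GUC007 (subadult female).  GUC005 is GUC004's son by another father
    (maternal half-sibling of the children); GUC003 is a third-degree
    paternal relative of GUC002 (son of GUC002's paternal half-brother).
    Latent connectors carry ``~`` prefixes.
    """
    ped = Pedigree()
    # founders
    ped.add_member("~gf", sex="M", observed=False, y_hg="Y-O2b")
    ped.add_member("~gm1", sex="F", observed=False, mt_hg="mt-B4")
    ped.add_member("~gm2", sex="F", observed=False, mt_hg="mt-M7")
    ped.add_member("GUC004", sex="F", age_class="adult", mt_hg="mt-D4")
    ped.add_member("~w", sex="F", observed=False, mt_hg="mt-F1")
    ped.add_member("~f2", sex="M", observed=False, y_hg="Y-C2")
    # middle generation
    ped.add_member("GUC002", sex="M", age_class="adult",
                   father="~gf", mother="~gm1")
    ped.add_member("~hb", sex="M", observed=False,
                   father="~gf", mother="~gm2")
    # youngest generation
    ped.add_member("GUC001", sex="M", age_class="adult",
                   father="GUC002", mother="GUC004")
    ped.add_member("GUC007", sex="F", age_class="subadult",
                   father="GUC002", mother="GUC004")
    ped.add_member("GUC005", sex="M", age_class="adult",
                   father="~f2", mother="GUC004")
    ped.add_member("GUC003", sex="M", age_class="adult",
                   father="~hb", mother="~w")
    ped.validate()
    return ped


def observed_meta_from_truth(ped: Pedigree, truth: TruthSet
                             ) -> list[IndividualMeta]:
    """IndividualMeta records for the observed members of a simulation."""
    out = []
    for i in sorted(ped.nodes):
        node = ped.nodes[i]
        if not node.observed:
            continue
        sex = {"M": "XY", "F": "XX"}.get(node.sex, "unassigned")
        out.append(IndividualMeta(
            id=i, genetic_sex=sex, age_class=node.age_class,
            mt_haplogroup=truth.mt_haplogroup[i],
            y_haplogroup=truth.y_haplogroup.get(i, "unknown"),
            population="ancient"))
    return out
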