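"""Pairwise relatedness from pseudo-haploid calls and genotype likelihoods.

Two complementary estimators are implemented:

* the pairwise mismatch rate (PMR): the fraction of overlapping SNPs at which
  two individuals' single sampled alleles differ.  For a pair with kinship
  coefficient kappa its expectation is ``(1 - kappa) * b`` where ``b`` is the
  unrelated-pair mismatch rate of the population, so PMR normalized by a
  reference baseline classifies relationship degrees
  (identical 0.5, 1st 0.75, 2nd 0.875, 3rd 0.9375, unrelated 1.0);

* maximum-likelihood IBD coefficients (k0, k1, k2) from genotype
  likelihoods, in the style of lcMLkin, which separate parent-offspring
  (k = (0, 1, 0)) from full siblings ((0.25, 0.5, 0.25)) where the PMR
  cannot.

``prune_relatives`` extracts a maximum set of mutually unrelated (beyond
second degree) individuals for group-level analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix, SnpPanel

DEGREE_NAMES = ["identical", "first", "second", "third", "unrelated"]
#: expected PMR relative to the unrelated baseline, per degree
EXPECTED_NORMALIZED_PMR = {"identical": 0.5, "first": 0.75, "second": 0.875,
                           "third": 0.9375, "unrelated": 1.0}
#: midpoints between consecutive degree expectations
_DEGREE_BOUNDARIES = np.array([0.625, 0.8125, 0.90625, 0.96875])


def degree_from_normalized_pmr(x: float) -> str:
    """Nearest-expectation degree; boundary ties go to the more distant one."""
    return DEGREE_NAMES[int(np.searchsorted(_DEGREE_BOUNDARIES, x,
                                            side="right"))]


class NoOverlapError(ValueError):
    pass


class InsufficientPanelError(ValueError):
    pass


@dataclass
class PmrEstimate:
    pair: tuple[str, str]
    n_overlap: int
    n_mismatch: int

    def __post_init__(self):
        if not 0 <= self.n_mismatch <= self.n_overlap:
            raise ValueError("mismatch count outside [0, n_overlap]")

    @property
    def pmr(self) -> float:
        return self.n_mismatch / self.n_overlap

    @property
    def se(self) -> float:
        p = self.pmr
        return float(np.sqrt(p * (1.0 - p) / self.n_overlap))


@dataclass
class DegreeCall:
    pair: tuple[str, str]
    normalized_pmr: float
    degree: str
    n_overlap: int
    low_confidence: bool = False


@dataclass
class IbdCoefficients:
    pair: tuple[str, str]
    k0: float
    k1: float
    k2: float
    log_likelihood: float
    n_sites_used: int
    converged: bool = True

    @property
    def kappa(self) -> float:
        return self.k1 / 4.0 + self.k2 / 2.0


@dataclass
class BaselineSummary:
    """Unrelated-pair PMR baseline of a reference panel."""

    baseline: float          # median pairwise PMR
    minimum: float
    maximum: float
    iqr: float
    n_pairs: int
    low_pairs: list = field(default_factory=list)  # pairs <= 2nd-degree-like
    suspicious: bool = False   # relatives in the panel, or baseline off the
    #                            externally expected heterozygosity


# ---------------------------------------------------------------------------
# PMR


def _valid_alt(matrix: GenotypeMatrix, mask=None):
    calls = matrix.calls if mask is None else matrix.calls[:, mask]
    valid = calls != MISSING
    alt = (calls == 1) & valid
    return valid, alt


def pairwise_mismatch_rate(matrix: GenotypeMatrix, pair, panel: SnpPanel = None,
                           autosomes_only: bool = True) -> PmrEstimate:
    """PMR for one pair, counting only sites called in both individuals.

    With ``autosomes_only`` (the default) a ``panel`` restricts the count to
    chromosome labels 1-22; without a panel all columns are used.
    """
    if matrix.ploidy != "haploid":
        raise ValueError("PMR is defined on pseudo-haploid calls")
    a, b = pair
    mask = panel.autosomal_mask if (autosomes_only and panel is not None) else None
    ca = matrix.row(a) if mask is None else matrix.row(a)[mask]
    cb = matrix.row(b) if mask is None else matrix.row(b)[mask]
    both = (ca != MISSING) & (cb != MISSING)
    n = int(both.sum())
    if n == 0:
        raise NoOverlapError(f"pair ({a}, {b}) shares no called sites")
    return PmrEstimate((a, b), n, int((ca[both] != cb[both]).sum()))


def pairwise_mismatch_matrix(matrix: GenotypeMatrix, panel: SnpPanel = None,
                             autosomes_only: bool = True
                             ) -> tuple[np.ndarray, np.ndarray]:
    """(n_overlap, n_mismatch) matrices for all pairs at once.

    Uses float32 matrix products; exact for any realistic SNP count.
    """
    mask = panel.autosomal_mask if (autosomes_only and panel is not None) else None
    valid, alt = _valid_alt(matrix, mask)
    v = valid.astype(np.float32)
    a = alt.astype(np.float32)
    r = v - a  # ref calls
    overlap = v @ v.T
    mismatch = a @ r.T + r @ a.T
    return (np.round(overlap).astype(np.int64),
            np.round(mismatch).astype(np.int64))


def background_pmr(panel_matrix: GenotypeMatrix, exclude_pairs=(), *,
                   panel: SnpPanel = None, autosomes_only: bool = True,
                   expected_het: float | None = None) -> BaselineSummary:
    """Baseline ``b`` = median pairwise PMR of a reference panel.

    The median is robust to a few undetected relatives, and a dispersion
    check reports when the panel itself looks contaminated by relatives:
    any pair whose PMR falls below the second-degree boundary
    (``0.90625 * median``) is listed in ``low_pairs`` and flags the summary.
    When the expected unrelated mismatch rate ``expected_het``
    (``mean_s 2 p_s (1 - p_s)`` from external frequencies) is supplied, a
    median more than 5% away from it also flags -- this is the only way a
    panel that is *mostly* relatives (e.g. duplicated genotypes) can be
    caught, since the internal check is relative to the panel's own median.
    """
    ids = panel_matrix.individual_ids
    if len(ids) < 2:
        raise InsufficientPanelError("need >= 2 reference individuals")
    overlap, mismatch = pairwise_mismatch_matrix(panel_matrix, panel,
                                                 autosomes_only)
    excl = {frozenset(p) for p in exclude_pairs}
    vals, pairs = [], []
    for i, j in itertools.combinations(range(len(ids)), 2):
        if frozenset({ids[i], ids[j]}) in excl:
            continue
        if overlap[i, j] == 0:
            continue
        vals.append(mismatch[i, j] / overlap[i, j])
        pairs.append((ids[i], ids[j]))
    if not vals:
        raise InsufficientPanelError("no usable reference pairs after exclusions")
    vals = np.array(vals)
    b = float(np.median(vals))
    low = [pairs[i] for i in np.flatnonzero(vals < 0.90625 * b)]
    suspicious = bool(low)
    if expected_het is not None:
        suspicious |= bool(abs(b - expected_het) > 0.05 * expected_het)
    q25, q75 = np.percentile(vals, [25, 75])
    return BaselineSummary(baseline=b, minimum=float(vals.min()),
                           maximum=float(vals.max()), iqr=float(q75 - q25),
                           n_pairs=len(vals), low_pairs=low,
                           suspicious=suspicious)


def classify_degree(est: PmrEstimate, baseline: float, *,
                    min_overlap: int = 10_000) -> DegreeCall:
    """Assign a relationship degree from the baseline-normalized PMR.

    Class boundaries sit midway between consecutive degree expectations;
    an exactly-boundary value goes to the more distant degree (conservative
    against over-claiming kinship).  Pairs with fewer than ``min_overlap``
    shared SNPs are still classified but flagged low-confidence.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    norm = est.pmr / baseline
    return DegreeCall(pair=est.pair, normalized_pmr=norm,
                      degree=degree_from_normalized_pmr(norm),
                      n_overlap=est.n_overlap,
                      low_confidence=est.n_overlap < min_overlap)


# ---------------------------------------------------------------------------
# Genotype likelihoods and IBD coefficients


def genotype_likelihoods(ref_count, alt_count, base_error: float) -> np.ndarray:
    """Normalized likelihoods over genotypes {0, 1, 2} from read counts.

    ``L(g) \\propto e_g^alt (1 - e_g)^ref`` with alt-read probability
    ``e_g in {err, 1/2, 1 - err}``; zero-depth sites get (1/3, 1/3, 1/3).
    """
    if not 0.0 < base_error < 0.5:
        raise ValueError("base_error must lie in (0, 0.5)")
    ref = np.asarray(ref_count, dtype=np.float64)
    alt = np.asarray(alt_count, dtype=np.float64)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    e = np.array([base_error, 0.5, 1.0 - base_error])
    with np.errstate(divide="ignore"):
        loglik = (alt[..., None] * np.log(e)
                  + ref[..., None] * np.log1p(-e))
    loglik -= loglik.max(axis=-1, keepdims=True)
    lik = np.exp(loglik)
    lik /= lik.sum(axis=-1, keepdims=True)
    lik[(ref + alt) == 0] = 1.0 / 3.0
    return lik


def _pair_tables(freqs: np.ndarray) -> np.ndarray:
    """P(g_i, g_j | IBD = m, p) tables, shape (n_sites, 3, 3, 3) for m=0,1,2.

    m=0: independent HWE genotypes; m=2: HWE on the diagonal; m=1: one allele
    shared IBD (drawn uniformly from the first individual's genotype), the
    other drawn from the population.  The m=1 table is symmetric, so the
    two sharing directions coincide.
    """
    p = np.asarray(freqs, dtype=np.float64)
    q = 1.0 - p
    hwe = np.stack([q * q, 2 * p * q, p * p], axis=-1)  # (n, 3)
    n = len(p)
    m0 = hwe[:, :, None] * hwe[:, None, :]
    m2 = np.zeros((n, 3, 3))
    for g in range(3):
        m2[:, g, g] = hwe[:, g]
    # transition P(g_j | g_i, share one allele)
    t = np.zeros((n, 3, 3))
    t[:, 0, 0], t[:, 0, 1] = q, p
    t[:, 1, 0], t[:, 1, 1], t[:, 1, 2] = 0.5 * q, 0.5, 0.5 * p
    t[:, 2, 1], t[:, 2, 2] = q, p
    m1 = hwe[:, :, None] * t
    return np.stack([m0, m1, m2], axis=1)


def estimate_ibd_coefficients(gl_i: np.ndarray, gl_j: np.ndarray,
                              freqs: np.ndarray, pair=("i", "j"), *,
                              tol: float = 1e-6, max_iter: int = 1000,
                              min_sites: int = 100) -> IbdCoefficients:
    """Maximum-likelihood (k0, k1, k2) by EM over the probability simplex.

    ``gl_i``/``gl_j`` are (n_sites, 3) genotype likelihoods; sites where
    either individual is uninformative (uniform likelihood) carry no signal
    and are dropped.  The EM treats the IBD state of each site as the latent
    variable; the log-likelihood is non-decreasing and iteration stops when
    it gains less than ``tol``.
    """
    gl_i = np.asarray(gl_i, dtype=np.float64)
    gl_j = np.asarray(gl_j, dtype=np.float64)
    p = np.asarray(freqs, dtype=np.float64)
    if not ((p > 0) & (p < 1)).all():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    info = ((np.ptp(gl_i, axis=1) > 1e-12)
            & (np.ptp(gl_j, axis=1) > 1e-12))
    if info.sum() < min_sites:
        raise ValueError(
            f"only {int(info.sum())} informative sites (< {min_sites})")
    gi, gj, p = gl_i[info], gl_j[info], p[info]
    tables = _pair_tables(p)  # (n, 3, 3, 3)
    # P_m(site) = sum_{gi,gj} GL_i(gi) GL_j(gj) P(gi,gj|m)
    pm = np.einsum("na,nmab,nb->nm", gi, tables, gj)

    # multi-start: EM from the best-scoring canonical relationship point
    # (near-boundary truths such as parent-offspring converge slowly from
    # the uniform start)
    starts = np.array([[1 / 3, 1 / 3, 1 / 3],      # uninformative
                       [0.98, 0.01, 0.01],         # unrelated
                       [0.01, 0.98, 0.01],         # parent-offspring
                       [0.25, 0.50, 0.25],         # full siblings
                       [0.495, 0.495, 0.01],       # second degree
                       [0.01, 0.01, 0.98]])        # identical
    start_ll = [np.log(pm @ s).sum() for s in starts]
    k = starts[int(np.argmax(start_ll))].copy()
    last = -np.inf
    converged = False
    for _ in range(max_iter):
        mix = pm @ k
        ll = float(np.log(mix).sum())
        resp = pm * k / mix[:, None]
        k = resp.mean(axis=0)
        k = np.clip(k, 0.0, None)
        k /= k.sum()
        if ll - last < tol and np.isfinite(last):
            converged = True
            break
        last = ll
    return IbdCoefficients(pair=tuple(pair), k0=float(k[0]), k1=float(k[1]),
                           k2=float(k[2]), log_likelihood=ll,
                           n_sites_used=int(info.sum()), converged=converged)


def disambiguate_first_degree(ibd: IbdCoefficients, age_classes=None) -> str:
    """Split a first-degree pair into parent-offspring vs full siblings.

    Parent-offspring share exactly one allele at every SNP (near-zero k0 and
    k2); full siblings show substantial k0 and k2.  Age classes are advisory
    context only and never override the genetic call.
    """
    if ibd.k0 < 0.05 and ibd.k2 < 0.1:
        return "parent_offspring"
    if ibd.k0 >= 0.1 and ibd.k2 >= 0.1:
        return "full_sibling"
    return "undetermined"


# ---------------------------------------------------------------------------
# Relative pruning


def prune_relatives(degree_calls, coverage: dict[str, float] | None = None
                    ) -> list[str]:
    """Maximum subset with no pair related at second degree or closer.

    Solves the exact maximum independent set on the relatedness graph
    (groups here are small); among maximum sets, ties are broken by higher
    total site coverage, then by lexicographic ids.
    """
    ids: set[str] = set()
    edges: set[frozenset] = set()
    for call in degree_calls:
        a, b = call.pair
        ids.update((a, b))
        if call.degree in ("identical", "first", "second"):
            edges.add(frozenset({a, b}))
    order = sorted(ids)
    adj = {i: set() for i in order}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)

    best: list[list[str]] = [[]]

    def extend(chosen, remaining):
        if len(chosen) + len(remaining) < len(best[0]):
            return
        if not remaining:
            if len(chosen) > len(best[0]):
                best[0] = list(chosen)
            elif len(chosen) == len(best[0]) and chosen:
                best.append(list(chosen))
            return
        i, rest = remaining[0], remaining[1:]
        extend(chosen + [i], [r for r in rest if r not in adj[i]])
        extend(chosen, rest)

    extend([], order)
    size = len(best[0])
    candidates = sorted({tuple(sorted(s)) for s in best if len(s) == size})
    if coverage:
        candidates.sort(
            key=lambda s: (-sum(coverage.get(i, 0.0) for i in s), s))
    retained = list(candidates[0])
    for a, b in itertools.combinations(retained, 2):
        assert frozenset({a, b}) not in edges
    return retained
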