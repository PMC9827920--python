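"""Allele-frequency statistics: f3/f4, block jackknife, qpWave and qpAdm.

All statistics are simple averages of per-SNP products of sample allele
frequency differences:

    f3(O; A, B) = mean_s (o - a)(o - b)        (shared drift of A and B
                                                relative to outgroup O)
    f4(A, B; C, D) = mean_s (a - b)(c - d)     (treeness/symmetry test)

Standard errors come from a weighted delete-one-block jackknife over
contiguous genetic-map windows (default 5 cM), with block weights
proportional to their SNP counts.  A SNP enters a statistic only when every
population involved has data at it (the strict intersection rule), and
per-statistic SNP counts are always reported.  No small-sample
heterozygosity corrections are applied: the intended use is ranking and
testing on pseudo-haploid data, documented as a divergence from qp3Pop's
corrected mode.

qpWave tests the rank of the matrix ``F[i, j] = f4(l0, li; r0, rj)``;
qpAdm solves the generalized-least-squares condition that the target's f4
profile with the "right" populations equals a mixture of the sources',
subject to the weights summing to one.  Weights may be negative (flagged
infeasible), which is itself informative -- e.g. a small negative component
can capture a contamination artifact rather than true admixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import MISSING, GenotypeMatrix, SnpPanel


class InsufficientDataError(ValueError):
    pass


@dataclass
class GroupFreqs:
    """Per-SNP sample alt-allele frequency and observed allele count."""

    population: str
    freq: np.ndarray   # NaN where no alleles observed
    count: np.ndarray

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.count = np.asarray(self.count, dtype=np.int64)
        if self.freq.shape != self.count.shape:
            raise ValueError("freq and count must have the same shape")
        if np.any(np.isfinite(self.freq) != (self.count >= 1)):
            raise ValueError("frequency must be present iff count >= 1")


@dataclass
class FStatResult:
    name: str
    populations: tuple[str, ...]
    estimate: float
    se: float
    n_snps: int
    n_blocks: int

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else np.inf


@dataclass
class QpWaveResult:
    left: tuple[str, ...]
    right: tuple[str, ...]
    rank: int
    statistic: float
    dof: int
    p_value: float
    n_snps: int
    n_blocks: int


@dataclass
class QpAdmResult:
    target: str
    sources: tuple[str, ...]
    rights: tuple[str, ...]
    weights: np.ndarray
    se: np.ndarray
    p_value: float
    feasible: bool
    n_snps: int
    n_blocks: int

    def __post_init__(self):
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-8:
            raise ValueError("admixture weights must sum to 1")


# ---------------------------------------------------------------------------
# Group frequencies and jackknife blocks


def group_frequencies(matrices, labels) -> dict[str, GroupFreqs]:
    """Sample alt-allele frequencies per population label.

    ``matrices`` is one GenotypeMatrix or a list (e.g. a haploid ancient
    matrix plus a diploid modern one).  Haploid calls contribute one
    observed allele, diploid calls two; missing calls contribute nothing.
    """
    if isinstance(matrices, GenotypeMatrix):
        matrices = [matrices]
    n_snps = matrices[0].n_snps
    pops: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    seen = set()
    for mat in matrices:
        if mat.n_snps != n_snps:
            raise ValueError("matrices cover different SNP sets")
        mult = 1 if mat.ploidy == "haploid" else 2
        for row, ind in enumerate(mat.individual_ids):
            if ind not in labels:
                raise ValueError(f"individual {ind!r} has no population label")
            seen.add(ind)
            pop = labels[ind]
            alt_n, tot_n = pops.setdefault(
                pop, (np.zeros(n_snps), np.zeros(n_snps)))
            calls = mat.calls[row]
            ok = calls != MISSING
            alt_n[ok] += calls[ok]
            tot_n[ok] += mult
    unknown = set(labels) - seen
    if unknown:
        raise ValueError(f"labelled individuals absent from data: "
                         f"{sorted(unknown)}")
    out = {}
    for pop, (alt_n, tot_n) in pops.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(tot_n >= 1, alt_n / np.maximum(tot_n, 1), np.nan)
        out[pop] = GroupFreqs(pop, freq, tot_n.astype(np.int64))
    return out


def assign_blocks(panel: SnpPanel, window_cm: float = 5.0,
                  fallback_mb: float = 5.0) -> np.ndarray:
    """Contiguous jackknife blocks: >= ``window_cm`` windows per chromosome.

    Falls back to ``fallback_mb`` physical windows on chromosomes without
    genetic positions (logged via warning).  Returns one block id per SNP.
    """
    if window_cm <= 0:
        raise ValueError("window must be positive")
    blocks = np.zeros(len(panel), dtype=np.int64)
    next_id = 0
    warned = False
    for chrom in pd_unique(panel.chromosome):
        sel = np.flatnonzero(panel.chromosome == chrom)
        gpos = panel.genetic_pos[sel]
        if np.isnan(gpos).any():
            if not warned:
                warnings.warn("genetic positions absent; using "
                              f"{fallback_mb} Mb physical windows")
                warned = True
            pos = panel.position[sel].astype(float)
            idx = ((pos - pos[0]) // (fallback_mb * 1e6)).astype(np.int64)
        else:
            idx = ((gpos - gpos[0]) // window_cm).astype(np.int64)
        # renumber within chromosome to consecutive ids
        _, dense = np.unique(idx, return_inverse=True)
        blocks[sel] = dense + next_id
        next_id = blocks[sel].max() + 1
    return blocks


def pd_unique(arr):
    """Order-preserving unique (chromosomes in file order)."""
    seen, out = set(), []
    for x in arr:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


# ---------------------------------------------------------------------------
# Weighted delete-one-block jackknife


def _block_deletes(terms: np.ndarray, block_ids: np.ndarray):
    """Full mean, delete-one-block means, and block sizes.

    ``terms`` is (n_snps,) or (n_snps, q); empty blocks are dropped.
    """
    terms = np.asarray(terms, dtype=float)
    flat = terms.reshape(len(terms), -1)
    uniq, dense = np.unique(block_ids, return_inverse=True)
    g = len(uniq)
    sizes = np.bincount(dense, minlength=g).astype(float)
    sums = np.zeros((g, flat.shape[1]))
    for q in range(flat.shape[1]):
        sums[:, q] = np.bincount(dense, weights=flat[:, q], minlength=g)
    total = flat.sum(axis=0)
    n = sizes.sum()
    full = total / n
    deletes = (total[None, :] - sums) / (n - sizes)[:, None]
    return full, deletes, sizes


def block_jackknife(terms: np.ndarray, block_ids: np.ndarray
                    ) -> tuple[float, float]:
    """Weighted delete-one-block jackknife (estimate, standard error).

    Uses the weighted-jackknife formulas with block weights proportional to
    SNP counts: with ``h_j = n / m_j``, pseudovalues
    ``theta*_j = h_j theta - (h_j - 1) theta_(j)`` and variance
    ``(1/g) sum_j (theta*_j - theta_J)^2 / (h_j - 1)``.  Reduces to the
    classic delete-one jackknife for equal block sizes.
    """
    full, deletes, sizes = _block_deletes(np.asarray(terms, float), block_ids)
    g = len(sizes)
    if g < 2:
        raise InsufficientDataError(
            "need >= 2 non-empty jackknife blocks; use a smaller window "
            "or more data")
    n = sizes.sum()
    h = n / sizes
    theta_j = g * full - ((1.0 - sizes / n)[:, None] * deletes).sum(axis=0)
    pseudo = h[:, None] * full[None, :] - (h - 1.0)[:, None] * deletes
    var = (((pseudo - theta_j[None, :]) ** 2)
           / (h - 1.0)[:, None]).sum(axis=0) / g
    return float(full[0]), float(np.sqrt(var[0]))


def block_jackknife_cov(terms: np.ndarray, block_ids: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, int]:
    """Vector-valued analogue: (full mean, jackknife covariance, n_blocks)."""
    full, deletes, sizes = _block_deletes(np.asarray(terms, float), block_ids)
    g = len(sizes)
    if g < 2:
        raise InsufficientDataError("need >= 2 non-empty jackknife blocks")
    n = sizes.sum()
    h = n / sizes
    theta_j = g * full - ((1.0 - sizes / n)[:, None] * deletes).sum(axis=0)
    pseudo = h[:, None] * full[None, :] - (h - 1.0)[:, None] * deletes
    dev = pseudo - theta_j[None, :]
    cov = (dev.T * (1.0 / (h - 1.0))) @ dev / g
    return full, cov, g


# ---------------------------------------------------------------------------
# f3 / f4


def _usable(groups, pops):
    masks = [np.isfinite(groups[p].freq) for p in dict.fromkeys(pops)]
    return np.logical_and.reduce(masks)


def f3_outgroup(groups: dict[str, GroupFreqs], outgroup: str, pop_a: str,
                pop_b: str, block_ids: np.ndarray) -> FStatResult:
    """Outgroup-f3: shared drift of A and B relative to the outgroup.

    Higher values mean closer affinity of A and B.  SNPs are used only when
    all three populations have data; no heterozygosity correction.
    """
    mask = _usable(groups, [outgroup, pop_a, pop_b])
    if mask.sum() == 0:
        raise InsufficientDataError("no SNPs shared by all three populations")
    o = groups[outgroup].freq[mask]
    a = groups[pop_a].freq[mask]
    b = groups[pop_b].freq[mask]
    est, se = block_jackknife((o - a) * (o - b), block_ids[mask])
    g = len(np.unique(block_ids[mask]))
    return FStatResult("f3", (outgroup, pop_a, pop_b), est, se,
                       int(mask.sum()), g)


def f4(groups: dict[str, GroupFreqs], pop_a: str, pop_b: str, pop_c: str,
       pop_d: str, block_ids: np.ndarray) -> FStatResult:
    """f4(A, B; C, D) = mean (a - b)(c - d); zero when (C, D) is a clade
    with respect to (A, B)."""
    mask = _usable(groups, [pop_a, pop_b, pop_c, pop_d])
    if mask.sum() == 0:
        raise InsufficientDataError("no SNPs shared by all four populations")
    a, b, c, d = (groups[p].freq[mask] for p in (pop_a, pop_b, pop_c, pop_d))
    est, se = block_jackknife((a - b) * (c - d), block_ids[mask])
    g = len(np.unique(block_ids[mask]))
    return FStatResult("f4", (pop_a, pop_b, pop_c, pop_d), est, se,
                       int(mask.sum()), g)


# ---------------------------------------------------------------------------
# qpWave / qpAdm


def _f4_term_matrix(groups, left, right, block_ids):
    """Per-SNP f4 terms T[s, (i, j)] = (l0 - li)(r0 - rj), strict overlap."""
    mask = _usable(groups, list(left) + list(right))
    if mask.sum() == 0:
        raise InsufficientDataError("no SNPs shared by all populations")
    l0 = groups[left[0]].freq[mask]
    r0 = groups[right[0]].freq[mask]
    dl = np.stack([l0 - groups[l].freq[mask] for l in left[1:]], axis=1)
    dr = np.stack([r0 - groups[r].freq[mask] for r in right[1:]], axis=1)
    terms = dl[:, :, None] * dr[:, None, :]
    a, b = dl.shape[1], dr.shape[1]
    return terms.reshape(-1, a * b), (a, b), mask


def _regularize(cov: np.ndarray) -> np.ndarray:
    if np.linalg.cond(cov) > 1e12:
        scale = np.trace(cov) / len(cov)
        warnings.warn("near-singular f4 covariance; adding ridge")
        cov = cov + 1e-9 * max(scale, 1.0) * np.eye(len(cov))
    return cov


def qpwave_rank_test(groups: dict[str, GroupFreqs], left, right,
                     block_ids: np.ndarray, rank: int = 0) -> QpWaveResult:
    """Chi-square test that the left/right f4 matrix has the given rank.

    Builds ``F[i, j] = f4(l0, li; r0, rj)``, estimates its covariance by
    block jackknife, minimizes the quadratic form over rank-``rank``
    approximations (alternating generalized least squares), and refers the
    minimum to chi-square with ``(|L|-1-r)(|R|-1-r)`` degrees of freedom.
    """
    left, right = list(left), list(right)
    if len(left) < 2:
        raise ValueError("need at least two left populations")
    if len(right) < len(left):
        raise ValueError("need at least as many right as left populations")
    terms, (a, b), mask = _f4_term_matrix(groups, left, right, block_ids)
    m, cov, g = block_jackknife_cov(terms, block_ids[mask])
    cov = _regularize(cov)
    cinv = np.linalg.inv(cov)
    r = rank
    if r < 0 or r > min(a, b):
        raise ValueError("rank out of range")
    if r >= min(a, b):
        stat, dof = 0.0, 0
        p = 1.0
    elif r == 0:
        stat = float(m @ cinv @ m)
        dof = a * b
        p = float(sps.chi2.sf(stat, dof))
    else:
        stat = _rank_minimum(m.reshape(a, b), cinv, r)
        dof = (a - r) * (b - r)
        p = float(sps.chi2.sf(stat, dof))
    return QpWaveResult(tuple(left), tuple(right), r, stat, dof, p,
                        int(mask.sum()), g)


def _rank_minimum(M: np.ndarray, cinv: np.ndarray, r: int,
                  max_iter: int = 500, tol: float = 1e-10) -> float:
    """min over rank-r E of (vec(M-E))' Cinv (vec(M-E)), by alternating GLS."""
    a, b = M.shape
    u, s, vt = np.linalg.svd(M)
    A = u[:, :r] * s[:r]
    B = vt[:r, :]
    m = M.reshape(-1)
    last = np.inf
    for _ in range(max_iter):
        # solve for B given A: vec(AB) = kron(A, I_b) vec(B) (row-major)
        X = np.kron(A, np.eye(b))
        B = np.linalg.solve(X.T @ cinv @ X,
                            X.T @ cinv @ m).reshape(r, b)
        # solve for A given B: vec(AB) = kron(I_a, B') vec(A)
        X = np.kron(np.eye(a), B.T)
        A = np.linalg.solve(X.T @ cinv @ X,
                            X.T @ cinv @ m).reshape(a, r)
        resid = m - (A @ B).reshape(-1)
        stat = float(resid @ cinv @ resid)
        if last - stat < tol:
            break
        last = stat
    return stat


def qpadm_weights(groups: dict[str, GroupFreqs], target: str, sources,
                  rights, block_ids: np.ndarray) -> QpAdmResult:
    """Admixture weights for the target as a mixture of the sources.

    Solves, by generalized least squares with the jackknife covariance of
    the f4 vector, the condition that
    ``f4(target - sum_i w_i source_i, *; r0, rj) = 0`` for every right pair,
    subject to ``sum w_i = 1``.  Weight standard errors come from
    delete-one-block refits; the model p-value is the chi-square tail of the
    residual quadratic form with ``(|R|-1) - (K-1)`` degrees of freedom.
    """
    sources, rights = list(sources), list(rights)
    K = len(sources)
    if K < 1:
        raise ValueError("need at least one source")
    if target in rights or set(sources) & set(rights):
        raise ValueError("right populations must be disjoint from the left set")
    if len(rights) - 1 < K:
        raise InsufficientDataError(
            "need at least |sources| + 1 right populations")
    pops = [target] + sources + rights
    mask = _usable(groups, pops)
    if mask.sum() == 0:
        raise InsufficientDataError("no SNPs shared by all populations")
    r0 = groups[rights[0]].freq[mask]
    dr = np.stack([r0 - groups[r].freq[mask] for r in rights[1:]], axis=1)
    t = groups[target].freq[mask]
    sK = groups[sources[-1]].freq[mask]
    d_terms = (t - sK)[:, None] * dr                      # (n, b)
    D_terms = [(groups[s].freq[mask] - sK)[:, None] * dr
               for s in sources[:-1]]                     # K-1 of (n, b)
    blocks = block_ids[mask]
    b = dr.shape[1]

    def fit(cov_inv, d_vec, D_mat):
        if K == 1:
            return np.zeros(0)
        A = D_mat.T @ cov_inv @ D_mat
        if np.linalg.cond(A) > 1e12:
            warnings.warn(f"collinear sources (condition number "
                          f"{np.linalg.cond(A):.2e})")
        return np.linalg.solve(A, D_mat.T @ cov_inv @ d_vec)

    d_full, cov_d, g = block_jackknife_cov(d_terms, blocks)
    D_full = np.stack(
        [_block_deletes(Dt, blocks)[0] for Dt in D_terms], axis=1) \
        if K > 1 else np.zeros((b, 0))
    cinv = np.linalg.inv(_regularize(cov_d))
    w0 = fit(cinv, d_full, D_full)
    # re-estimate the covariance at the fitted weights, then refit
    resid_terms = d_terms - sum(w0[i] * D_terms[i] for i in range(K - 1)) \
        if K > 1 else d_terms
    r_full, cov_e, _ = block_jackknife_cov(resid_terms, blocks)
    einv = np.linalg.inv(_regularize(cov_e))
    w = fit(einv, d_full, D_full)

    # delete-one-block refits for weight standard errors
    _, d_del, sizes = _block_deletes(d_terms, blocks)
    D_del = np.stack([_block_deletes(Dt, blocks)[1] for Dt in D_terms],
                     axis=2) if K > 1 else np.zeros((g, b, 0))
    w_dels = np.stack([
        np.append(wd := fit(einv, d_del[j], D_del[j]), 1.0 - wd.sum())
        for j in range(g)])
    w_all = np.append(w, 1.0 - w.sum())
    n = sizes.sum()
    h = n / sizes
    theta_j = g * w_all - ((1.0 - sizes / n)[:, None] * w_dels).sum(axis=0)
    pseudo = h[:, None] * w_all[None, :] - (h - 1.0)[:, None] * w_dels
    var = (((pseudo - theta_j[None, :]) ** 2)
           / (h - 1.0)[:, None]).sum(axis=0) / g
    se = np.sqrt(var)

    resid = d_full - (D_full @ w if K > 1 else 0.0)
    stat = float(resid @ einv @ resid)
    dof = b - (K - 1)
    p = float(sps.chi2.sf(stat, dof))
    feasible = bool(np.all((w_all >= 0) & (w_all <= 1)))
    return QpAdmResult(target, tuple(sources), tuple(rights), w_all, se, p,
                       feasible, int(mask.sum()), g)
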