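"""Genotype containers and EIGENSTRAT text I/O.

The EIGENSTRAT trio (``.geno``/``.snp``/``.ind``) is the de-facto exchange
format of the 1240K ancient-DNA ecosystem.  A ``.geno`` file holds one line
per SNP and one character per individual, each character counting copies of
the *first-listed* allele in the ``.snp`` file (``9`` = missing).  Internally
we store alt-allele dosage (diploid ``0/1/2``) or alt-allele calls (haploid
``0/1``) with ``-1`` as the missing value, so reading converts ``v -> ploidy - v``.

Pseudo-haploid calling (one randomly sampled allele per site per individual)
and coverage-ratio genetic-sex assignment live here too: both are part of the
standard low-coverage aDNA genotype-preparation step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1
#: chromosome labels treated as autosomes
AUTOSOMES = frozenset(str(c) for c in range(1, 23))


class EigenstratParseError(ValueError):
    """Structured parse failure naming the offending file/line/column."""

    def __init__(self, message: str, path=None, line: int | None = None,
                 column: int | None = None):
        self.path, self.line, self.column = path, line, column
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column}")
        super().__init__(f"{message} ({', '.join(loc)})" if loc else message)


@dataclass
class SnpPanel:
    """Ordered SNP metadata: ids, chromosome labels, positions and alleles.

    Positions are 1-based base pairs; ``genetic_pos`` is in centimorgans and
    may be NaN when no genetic map is available.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genetic_pos: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.genetic_pos is None:
            self.genetic_pos = np.full(len(self.snp_id), np.nan)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.snp_id)
        for name in ("chromosome", "position", "ref", "alt", "genetic_pos"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SnpPanel field {name!r} has wrong length")
        if len(set(self.snp_id)) != n:
            raise ValueError("SNP ids are not unique")
        if np.any(self.ref == self.alt):
            raise ValueError("ref and alt alleles must differ")
        for chrom in pd.unique(self.chromosome):
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValueError(
                    f"positions not non-decreasing on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def autosomal_mask(self) -> np.ndarray:
        if not hasattr(self, "_autosomal_mask"):
            self._autosomal_mask = np.isin(self.chromosome.astype(str),
                                           list(AUTOSOMES))
        return self._autosomal_mask

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id, "chromosome": self.chromosome,
            "genetic_pos": self.genetic_pos, "position": self.position,
            "ref": self.ref, "alt": self.alt,
        })


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs calls tied (by column order) to a :class:`SnpPanel`.

    ``ploidy`` is ``"haploid"`` (calls 0=ref, 1=alt) or ``"diploid"``
    (alt-allele dosage 0/1/2); missing is ``MISSING``.
    """

    individual_ids: list[str]
    ploidy: str
    calls: np.ndarray

    def __post_init__(self):
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x SNPs)")
        if self.calls.shape[0] != len(self.individual_ids):
            raise ValueError("row count does not match individual_ids")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError(f"unknown ploidy mode {self.ploidy!r}")
        hi = 1 if self.ploidy == "haploid" else 2
        bad = (self.calls != MISSING) & ((self.calls < 0) | (self.calls > hi))
        if bad.any():
            raise ValueError(f"calls outside 0..{hi}/missing for {self.ploidy}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids are not unique")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self.individual_ids.index(individual)]


@dataclass
class IndividualMeta:
    """Per-individual labels consumed by kinship and pedigree inference."""

    id: str
    genetic_sex: str = "unassigned"  # XX | XY | unassigned
    age_class: str = "unknown"       # adult | subadult | unknown
    mt_haplogroup: str = "unknown"
    y_haplogroup: str = "unknown"
    population: str = "unknown"

    def __post_init__(self):
        if self.genetic_sex not in ("XX", "XY", "unassigned"):
            raise ValueError(f"bad genetic_sex {self.genetic_sex!r}")
        if self.age_class not in ("adult", "subadult", "unknown"):
            raise ValueError(f"bad age_class {self.age_class!r}")
        if self.y_haplogroup != "unknown" and self.genetic_sex == "XX":
            raise ValueError(
                f"{self.id}: Y haplogroup recorded for an XX individual")


@dataclass
class ReadCounts:
    """Per-site (ref, alt) read counts for one or more individuals."""

    individual_ids: list[str]
    ref: np.ndarray  # (n_ind, n_snp)
    alt: np.ndarray

    def __post_init__(self):
        self.ref = np.asarray(self.ref, dtype=np.int32)
        self.alt = np.asarray(self.alt, dtype=np.int32)
        if self.ref.shape != self.alt.shape or self.ref.ndim != 2:
            raise ValueError("ref/alt count arrays must share a 2-D shape")
        if self.ref.shape[0] != len(self.individual_ids):
            raise ValueError("row count does not match individual_ids")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    def row(self, individual: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.individual_ids.index(individual)
        return self.ref[i], self.alt[i]


@dataclass
class CoverageSummary:
    """Mean sequencing depth per individual on autosomal, X and Y panel sites."""

    individual_ids: list[str]
    autosome: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.autosome = np.asarray(self.autosome, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        for arr in (self.autosome, self.x, self.y):
            if len(arr) != len(self.individual_ids):
                raise ValueError("coverage arrays must match individual_ids")
            if not np.all(np.isfinite(arr)) or (arr < 0).any():
                raise ValueError("coverage values must be finite and >= 0")


# ---------------------------------------------------------------------------
# EIGENSTRAT reading/writing


def _read_snp_file(path) -> SnpPanel:
    rows = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            parts = raw.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise EigenstratParseError(
                    f"expected 6 columns, got {len(parts)}", path, ln)
            rows.append(parts)
    if not rows:
        return SnpPanel(np.array([], dtype=object), np.array([], dtype=object),
                        np.array([], dtype=np.int64), np.array([], dtype=object),
                        np.array([], dtype=object))
    arr = np.array(rows, dtype=object)
    gpos = arr[:, 2].astype(float) * 100.0  # Morgans in file -> cM
    gpos[gpos == 0.0] = np.nan              # 0 conventionally means "no map"
    return SnpPanel(snp_id=arr[:, 0], chromosome=arr[:, 1],
                    position=arr[:, 3].astype(np.int64),
                    ref=arr[:, 4], alt=arr[:, 5], genetic_pos=gpos)


def read_eigenstrat(prefix_or_geno, snp_path=None, ind_path=None
                    ) -> tuple[SnpPanel, GenotypeMatrix, list[IndividualMeta]]:
    """Read an EIGENSTRAT ``.geno``/``.snp``/``.ind`` trio.

    Accepts either a single path prefix or the three explicit paths.  Dosages
    in the file count the first-listed (ref) allele and are converted to
    alt-dosage; ``9`` becomes the internal missing value.  A ``.ploidy``
    sidecar (written by :func:`write_eigenstrat`) selects haploid decoding;
    without it the matrix is read as diploid.
    """
    if snp_path is None and ind_path is None:
        prefix = str(prefix_or_geno)
        geno_path, snp_path, ind_path = (
            prefix + ".geno", prefix + ".snp", prefix + ".ind")
        ploidy_path = Path(prefix + ".ploidy")
    else:
        geno_path = prefix_or_geno
        ploidy_path = Path(str(geno_path)).with_suffix(".ploidy")
    panel = _read_snp_file(snp_path)

    meta: list[IndividualMeta] = []
    with open(ind_path) as fh:
        for ln, raw in enumerate(fh, 1):
            parts = raw.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise EigenstratParseError(
                    f"expected 3 columns, got {len(parts)}", ind_path, ln)
            sex = {"M": "XY", "F": "XX"}.get(parts[1], "unassigned")
            meta.append(IndividualMeta(id=parts[0], genetic_sex=sex,
                                       population=parts[2]))

    ploidy = "diploid"
    if ploidy_path.exists():
        ploidy = ploidy_path.read_text().strip()
    hi = 1 if ploidy == "haploid" else 2

    n_ind = len(meta)
    calls = np.full((n_ind, len(panel)), MISSING, dtype=np.int8)
    with open(geno_path) as fh:
        row = -1
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line and n_ind > 0:
                continue
            row += 1
            if row >= len(panel):
                raise EigenstratParseError(
                    "more genotype rows than SNPs", geno_path, ln)
            if len(line) != n_ind:
                raise EigenstratParseError(
                    f"expected {n_ind} genotype columns, got {len(line)}",
                    geno_path, ln)
            vals = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
            bad = ~(((vals <= hi)) | (vals == 9))
            if bad.any():
                col = int(np.argmax(bad)) + 1
                raise EigenstratParseError(
                    f"illegal genotype character {line[col - 1]!r}",
                    geno_path, ln, col)
            out = hi - vals.astype(np.int8)   # first-allele count -> alt dosage
            out[vals == 9] = MISSING
            calls[:, row] = out
    if row + 1 != len(panel):
        raise EigenstratParseError(
            f"{row + 1} genotype rows for {len(panel)} SNPs", geno_path)
    matrix = GenotypeMatrix([m.id for m in meta], ploidy, calls)
    return panel, matrix, meta


def write_eigenstrat(panel: SnpPanel, matrix: GenotypeMatrix,
                     meta: Sequence[IndividualMeta], out_prefix) -> dict:
    """Write panel/matrix/meta as an EIGENSTRAT trio plus a ploidy sidecar.

    Output round-trips bit-identically through :func:`read_eigenstrat`.
    """
    if matrix.n_snps != len(panel):
        raise ValueError("matrix column count does not match panel length")
    if len(meta) != matrix.n_individuals:
        raise ValueError("metadata rows do not match matrix rows")
    prefix = str(out_prefix)
    paths = {ext: prefix + "." + ext for ext in ("geno", "snp", "ind", "ploidy")}

    gpos = np.where(np.isnan(panel.genetic_pos), 0.0, panel.genetic_pos / 100.0)
    with open(paths["snp"], "w") as fh:
        for i in range(len(panel)):
            fh.write(f"{panel.snp_id[i]}\t{panel.chromosome[i]}\t{gpos[i]:.6f}"
                     f"\t{panel.position[i]}\t{panel.ref[i]}\t{panel.alt[i]}\n")
    with open(paths["ind"], "w") as fh:
        for m in meta:
            sex = {"XY": "M", "XX": "F"}.get(m.genetic_sex, "U")
            fh.write(f"{m.id}\t{sex}\t{m.population}\n")
    hi = 1 if matrix.ploidy == "haploid" else 2
    enc = (hi - matrix.calls).astype(np.uint8)     # alt dosage -> ref count
    enc[matrix.calls == MISSING] = 9
    digits = enc + ord("0")
    with open(paths["geno"], "w") as fh:
        for s in range(matrix.n_snps):
            fh.write(digits[:, s].tobytes().decode("ascii") + "\n")
    Path(paths["ploidy"]).write_text(matrix.ploidy + "\n")
    return paths


META_COLUMNS = ["id", "genetic_sex", "age_class", "mt_hg", "y_hg", "population"]


def read_individual_meta(path) -> list[IndividualMeta]:
    """Read the tab-separated individual metadata table (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    return [IndividualMeta(id=r.id, genetic_sex=r.genetic_sex,
                           age_class=r.age_class, mt_haplogroup=r.mt_hg,
                           y_haplogroup=r.y_hg, population=r.population)
            for r in df.itertuples()]


def write_individual_meta(meta: Sequence[IndividualMeta], path) -> None:
    pd.DataFrame(
        [[m.id, m.genetic_sex, m.age_class, m.mt_haplogroup, m.y_haplogroup,
          m.population] for m in meta],
        columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pseudo-haploid calling


def pseudo_haploidize(source, seed=None) -> GenotypeMatrix:
    """Draw one allele per site per individual, mimicking random-base calling.

    ``source`` is either a diploid :class:`GenotypeMatrix` (heterozygotes
    resolve to ref/alt with probability 1/2 each) or a :class:`ReadCounts`
    object (one read sampled uniformly; zero-depth sites become missing).
    Deterministic given ``seed`` (an int or a :class:`numpy.random.Generator`).
    """
    rng = np.random.default_rng(seed)
    if isinstance(source, GenotypeMatrix):
        if source.ploidy != "diploid":
            raise ValueError("pseudo_haploidize expects a diploid matrix")
        g = source.calls
        out = np.where(g == 2, 1, 0).astype(np.int8)
        het = g == 1
        out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        out[g == MISSING] = MISSING
        return GenotypeMatrix(source.individual_ids, "haploid", out)
    if isinstance(source, ReadCounts):
        depth = source.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(depth > 0, source.alt / np.maximum(depth, 1), 0.0)
        out = (rng.random(depth.shape) < p_alt).astype(np.int8)
        out[depth == 0] = MISSING
        return GenotypeMatrix(source.individual_ids, "haploid", out)
    raise TypeError(f"cannot pseudo-haploidize {type(source).__name__}")


# ---------------------------------------------------------------------------
# Genetic sex from coverage ratios


def assign_genetic_sex(cov: CoverageSummary, x_female_min: float = 0.8,
                       x_male_max: float = 0.6, y_male_min: float = 0.3,
                       y_female_max: float = 0.1) -> list[str]:
    """Assign XX/XY/unassigned from X and Y coverage relative to autosomes.

    XX requires X/autosome >= ``x_female_min`` and Y/autosome <=
    ``y_female_max``; XY requires X/autosome <= ``x_male_max`` and
    Y/autosome >= ``y_male_min``.  Anything else (including zero autosomal
    depth) is unassigned.  Ratios make the call scale-invariant.
    """
    out = []
    for i, ind in enumerate(cov.individual_ids):
        auto = cov.autosome[i]
        if auto <= 0:
            warnings.warn(f"{ind}: zero autosomal depth, sex unassigned")
            out.append("unassigned")
            continue
        rx, ry = cov.x[i] / auto, cov.y[i] / auto
        if rx >= x_female_min and ry <= y_female_max:
            out.append("XX")
        elif rx <= x_male_max and ry >= y_male_min:
            out.append("XY")
        else:
            out.append("unassigned")
    return out
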