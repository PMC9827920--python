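"""Pedigree representation, expected IBD coefficients, and pedigree search.

A pedigree is a directed acyclic parent->child graph over observed and latent
(unsampled connector) individuals.  For an outbred pedigree the expected IBD
coefficients of a pair follow from recursive kinship:

    phi(a, b) = 1/2 * sum over parents p of the deeper node of phi(p, other)
    k2        = phi(f_a, f_b) phi(m_a, m_b) + phi(f_a, m_b) phi(m_a, f_b)
    k1        = 4 kappa - 2 k2,   k0 = 1 - k1 - k2,   kappa = phi(a, b)

``enumerate_pedigrees`` searches exhaustively, within declared bounds on
latent connectors and generation depth, for pedigrees whose expected degrees
reproduce an observed degree matrix, then ranks the survivors by how many
uniparental-haplogroup and age observations they explain.  Co-maximal
alternatives are always all returned; the search never silently picks one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import IndividualMeta

#: expected kinship coefficient for each nameable relationship degree
KAPPA_BY_DEGREE = {"identical": 0.5, "first": 0.25, "second": 0.125,
                   "third": 0.0625, "unrelated": 0.0}


class UnsupportedPedigreeError(ValueError):
    """Raised for structures outside the outbred model (inbreeding loops)."""


@dataclass
class PedNode:
    id: str
    sex: str = "U"                # M | F | U
    age_class: str = "unknown"    # adult | subadult | unknown
    observed: bool = True
    mt_hg: str = "unknown"
    y_hg: str = "unknown"


class Pedigree:
    """Directed parent->child graph with per-node sex/age/haplogroup labels."""

    def __init__(self):
        self.nodes: dict[str, PedNode] = {}
        self.father: dict[str, str | None] = {}
        self.mother: dict[str, str | None] = {}

    # -- construction ------------------------------------------------------
    def add_member(self, id: str, sex: str = "U", father: str | None = None,
                   mother: str | None = None, age_class: str = "unknown",
                   observed: bool = True, mt_hg: str = "unknown",
                   y_hg: str = "unknown") -> None:
        if id in self.nodes:
            raise ValueError(f"duplicate member {id!r}")
        self.nodes[id] = PedNode(id, sex, age_class, observed, mt_hg, y_hg)
        self.father[id] = father
        self.mother[id] = mother

    def parents(self, i: str) -> tuple[str, ...]:
        return tuple(p for p in (self.father[i], self.mother[i]) if p is not None)

    def children(self, i: str) -> list[str]:
        return [c for c in self.nodes
                if self.father[c] == i or self.mother[c] == i]

    def members(self) -> list[str]:
        return list(self.nodes)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for i in self.nodes:
            for p in self.parents(i):
                if p not in self.nodes:
                    raise ValueError(f"{i}: unknown parent {p!r}")
            f, m = self.father[i], self.mother[i]
            if f is not None and self.nodes[f].sex == "F":
                raise ValueError(f"{i}: father {f} is female")
            if m is not None and self.nodes[m].sex == "M":
                raise ValueError(f"{i}: mother {m} is male")
            if f is not None and f == m:
                raise ValueError(f"{i}: identical parents")
        self._depths()  # raises on cycles

    def _depths(self) -> dict[str, int]:
        depth: dict[str, int] = {}

        def rec(i, stack):
            if i in depth:
                return depth[i]
            if i in stack:
                raise ValueError(f"pedigree cycle through {i!r}")
            stack.add(i)
            ps = self.parents(i)
            depth[i] = 0 if not ps else 1 + max(rec(p, stack) for p in ps)
            stack.discard(i)
            return depth[i]

        for i in self.nodes:
            rec(i, set())
        return depth

    # -- kinship -----------------------------------------------------------
    def kinship(self, a: str, b: str, _memo=None, _depth=None) -> float:
        """Kinship coefficient phi: P(random allele from each is IBD)."""
        if _memo is None:
            _memo, _depth = {}, self._depths()
        key = (a, b) if a <= b else (b, a)
        if key in _memo:
            return _memo[key]
        if a == b:
            fa, mo = self.father[a], self.mother[a]
            inb = (self.kinship(fa, mo, _memo, _depth)
                   if fa is not None and mo is not None else 0.0)
            val = 0.5 * (1.0 + inb)
        else:
            # recurse on the deeper node: its parents cannot include a
            # descendant of the other, so the recursion is well founded
            x, y = (a, b) if _depth[a] >= _depth[b] else (b, a)
            ps = self.parents(x)
            if not ps:
                val = 0.0
            else:
                val = 0.5 * sum(self.kinship(p, y, _memo, _depth) for p in ps)
        _memo[key] = val
        return val

    def is_inbred(self) -> bool:
        memo, depth = {}, self._depths()
        for i in self.nodes:
            fa, mo = self.father[i], self.mother[i]
            if fa is not None and mo is not None:
                if self.kinship(fa, mo, memo, depth) > 0:
                    return True
        return False

    def expected_kinship(self, a: str, b: str
                         ) -> tuple[float, float, float, float]:
        """Expected (kappa, k0, k1, k2) for a pair under the outbred model."""
        for i in (a, b):
            if i not in self.nodes:
                raise KeyError(f"unknown individual {i!r}")
        if self.is_inbred():
            raise UnsupportedPedigreeError(
                "inbreeding loop detected; expected IBD coefficients are "
                "only defined here for outbred pedigrees")
        if a == b:
            return 0.5, 0.0, 0.0, 1.0
        memo, depth = {}, self._depths()
        kappa = self.kinship(a, b, memo, depth)
        fa, ma, fb, mb = (self.father[a], self.mother[a],
                          self.father[b], self.mother[b])

        def phi(x, y):
            return (self.kinship(x, y, memo, depth)
                    if x is not None and y is not None else 0.0)

        k2 = phi(fa, fb) * phi(ma, mb) + phi(fa, mb) * phi(ma, fb)
        k1 = 4.0 * kappa - 2.0 * k2
        k0 = 1.0 - k1 - k2
        return kappa, max(k0, 0.0), max(k1, 0.0), k2

    # -- haplogroup clans ---------------------------------------------------
    def mt_clans(self) -> dict[str, int]:
        """Connected components of the mother->child graph (mtDNA lineages)."""
        return self._clans(lambda c: self.mother[c], lambda c: True)

    def y_clans(self) -> dict[str, int]:
        """Components of father->son links among males (Y lineages)."""
        return self._clans(lambda c: self.father[c],
                           lambda c: self.nodes[c].sex == "M")

    def _clans(self, parent_of, carries) -> dict[str, int]:
        root: dict[str, str] = {}

        def find(i):
            while root.get(i, i) != i:
                root[i] = root.get(root[i], root[i])
                i = root[i]
            return i

        for c in self.nodes:
            p = parent_of(c)
            if p is not None and carries(c):
                ra, rb = find(c), find(p)
                if ra != rb:
                    root[ra] = rb
        labels, out = {}, {}
        for i in self.nodes:
            r = find(i)
            out[i] = labels.setdefault(r, len(labels))
        return out

    # -- rendering ---------------------------------------------------------
    def to_trio_table(self) -> pd.DataFrame:
        """One row per member: (id, father, mother), '.' for absent parents."""
        depth = self._depths()
        rows = [(i, self.father[i] or ".", self.mother[i] or ".",
                 self.nodes[i].sex, depth[i])
                for i in sorted(self.nodes, key=lambda i: (depth[i], i))]
        return pd.DataFrame(rows, columns=["id", "father", "mother", "sex",
                                           "generation"])

    def render(self) -> str:
        depth = self._depths()
        lines = []
        for g in sorted(set(depth.values())):
            members = sorted(i for i in self.nodes if depth[i] == g)
            lines.append(f"generation {g}:")
            for i in members:
                n = self.nodes[i]
                par = self.parents(i)
                origin = (" <- " + " x ".join(par)) if par else " (founder)"
                tag = "" if n.observed else " [latent]"
                lines.append(f"  {i} ({n.sex}){tag}{origin}")
        return "\n".join(lines)

    @classmethod
    def from_trio_table(cls, table: pd.DataFrame,
                        meta: dict[str, PedNode] | None = None) -> "Pedigree":
        ped = cls()
        for r in table.itertuples():
            node = (meta or {}).get(r.id)
            ped.add_member(
                r.id,
                sex=node.sex if node else getattr(r, "sex", "U"),
                father=None if r.father == "." else r.father,
                mother=None if r.mother == "." else r.mother,
                age_class=node.age_class if node else "unknown",
                observed=node.observed if node else True,
                mt_hg=node.mt_hg if node else "unknown",
                y_hg=node.y_hg if node else "unknown")
        ped.validate()
        return ped


def render_pedigree(ped: Pedigree) -> tuple[str, pd.DataFrame]:
    """Text diagram plus the machine-readable trio table."""
    return ped.render(), ped.to_trio_table()


# ---------------------------------------------------------------------------
# Shared pedigree-spec text format (one member per line)

SPEC_COLUMNS = ["id", "sex", "father", "mother", "generation", "mt_hg", "y_hg"]


def read_pedigree_spec(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    missing = set(SPEC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree spec missing columns: {sorted(missing)}")
    ped = Pedigree()
    for r in df.itertuples():
        ped.add_member(r.id, sex=r.sex,
                       father=None if r.father == "." else r.father,
                       mother=None if r.mother == "." else r.mother,
                       mt_hg=r.mt_hg, y_hg=r.y_hg)
    ped.validate()
    return ped


def write_pedigree_spec(ped: Pedigree, path) -> None:
    depth = ped._depths()
    rows = [[i, ped.nodes[i].sex, ped.father[i] or ".", ped.mother[i] or ".",
             depth[i], ped.nodes[i].mt_hg, ped.nodes[i].y_hg]
            for i in sorted(ped.nodes, key=lambda i: (depth[i], i))]
    pd.DataFrame(rows, columns=SPEC_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Exhaustive pedigree enumeration


@dataclass
class ConsistencyReport:
    """A candidate pedigree with its constraint bookkeeping."""

    pedigree: Pedigree
    score: int
    satisfied: list[str] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)
    degree_mismatches: list[str] = field(default_factory=list)
    expected_degrees: dict = field(default_factory=dict)


def _degree_from_kappa(kappa: float) -> str:
    from .kinship import degree_from_normalized_pmr
    return degree_from_normalized_pmr(1.0 - kappa)


def enumerate_pedigrees(meta, degrees, first_degree_types=None, *,
                        max_latent: int = 4, max_generations: int = 3,
                        max_relaxation: int = 2) -> list[ConsistencyReport]:
    """Enumerate pedigrees reproducing an observed degree matrix.

    Parameters
    ----------
    meta
        ``IndividualMeta`` records for the observed individuals (sex, age
        class, mt/Y haplogroups).
    degrees
        Mapping ``frozenset({a, b}) -> degree`` with degree one of
        ``identical/first/second/third/unrelated`` for every observed pair.
    first_degree_types
        Optional mapping ``frozenset({a, b}) -> 'parent_offspring' |
        'full_sibling' | 'undetermined'`` from the k-coefficient step.
        Determined types become hard structural constraints.
    max_latent, max_generations
        Search bounds: number of unsampled connector individuals and
        generation depth.  The search is exhaustive within them; a node may
        carry 0, 1 or 2 recorded parents (a single recorded parent means the
        other parent exists but is unrelated to everyone else).
    max_relaxation
        If no pedigree satisfies every degree constraint, the search is
        re-run allowing 1, then up to this many degree mismatches, and the
        best near-misses are returned with their violations listed.

    Returns
    -------
    Reports ranked by constraint-satisfaction score (haplogroup sharing
    explained, age consistency); all co-maximal alternates are included.
    """
    meta = list(meta)
    if len(meta) < 2:
        raise ValueError("need at least two observed individuals")
    obs = sorted(m.id for m in meta)
    minfo = {m.id: m for m in meta}
    sex_of = {m.id: {"XY": "M", "XX": "F"}.get(m.genetic_sex, "U")
              for m in meta}
    req: dict[frozenset, str] = {}
    for a, b in itertools.combinations(obs, 2):
        key = frozenset({a, b})
        if key not in degrees:
            raise ValueError(f"degree call missing for pair ({a}, {b})")
        req[key] = degrees[key]
    ptype = dict(first_degree_types or {})

    for budget in range(max_relaxation + 1):
        found: dict[str, ConsistencyReport] = {}
        for n_lat in range(max_latent + 1):
            for lat_sexes in itertools.combinations_with_replacement(
                    "MF", n_lat):
                _search(obs, sex_of, req, ptype, lat_sexes,
                        max_generations, budget, found)
        if found:
            reports = sorted(found.values(),
                             key=lambda r: (-r.score, r.pedigree.render()))
            for r in reports:
                _score_report(r, minfo)
            reports.sort(key=lambda r: (-r.score, r.pedigree.render()))
            return reports
    return []


def co_maximal(reports: list[ConsistencyReport]) -> list[ConsistencyReport]:
    """All reports sharing the maximal constraint-satisfaction score."""
    if not reports:
        return []
    top = reports[0].score
    return [r for r in reports if r.score == top]


def _search(obs, sex_of, req, ptype, lat_sexes, max_gen, budget, found):
    lats = [f"~{i + 1}" for i in range(len(lat_sexes))]
    nodes = obs + lats
    sexes = dict(sex_of, **{l: s for l, s in zip(lats, lat_sexes)})
    n = len(nodes)

    # --- candidate generation-depth labellings, with cheap pair pruning ----
    po_pairs = {k for k, v in ptype.items() if v == "parent_offspring"}
    fs_pairs = {k for k, v in ptype.items() if v == "full_sibling"}

    def level_ok(levels):
        lev = dict(zip(nodes, levels))
        used = set(levels)
        if 0 not in used:
            return False
        if any(l > 0 and (l - 1) not in used for l in used):
            return False
        for k in po_pairs:
            a, b = tuple(k)
            if a in lev and b in lev and lev[a] == lev[b]:
                return False
        for k in fs_pairs:
            a, b = tuple(k)
            if a in lev and b in lev and lev[a] != lev[b]:
                return False
        # same-sex latents are interchangeable: order by level
        for s in "MF":
            ls = [lev[l] for l in lats if sexes[l] == s]
            if any(x > y for x, y in zip(ls, ls[1:])):
                return False
        return True

    for levels in itertools.product(range(max_gen), repeat=n):
        if not level_ok(levels):
            continue
        lev = dict(zip(nodes, levels))
        order = sorted(nodes, key=lambda i: (lev[i], i in lats, i))
        _assign(order, 0, lev, sexes, obs, req, ptype, lats, budget,
                {}, {}, [], found)


def _assign(order, k, lev, sexes, obs, req, ptype, lats, budget,
            parent_map, phi, mismatches, found):
    """DFS over parent assignments in generation order.

    ``phi`` maps sorted node pairs to kinship, filled as nodes are placed, so
    every observed-pair constraint is checked at the earliest possible point.
    """
    if k == len(order):
        _finalize(order, lev, sexes, obs, req, ptype, lats, parent_map,
                  phi, mismatches, found)
        return
    x = order[k]
    lx = lev[x]
    placed = order[:k]
    if lx == 0:
        options = [()]
    else:
        below = [p for p in placed if lev[p] < lx]
        anchor = [p for p in below if lev[p] == lx - 1]
        options = [(p,) for p in anchor]
        for a, b in itertools.combinations(below, 2):
            if max(lev[a], lev[b]) != lx - 1:
                continue
            sa, sb = sexes[a], sexes[b]
            if sa != "U" and sa == sb:
                continue
            # no-inbreeding rule: reject related couples outright
            if phi.get((a, b) if a <= b else (b, a), 0.0) > 0:
                continue
            options.append((a, b))

    for parents in options:
        new_phi = {}
        x_mis = []
        ok = True
        for y in placed:
            key = (x, y) if x <= y else (y, x)
            val = 0.0
            for p in parents:
                if p == y:
                    val += 0.5  # phi(y, y) for a non-inbred parent
                else:
                    pk = (p, y) if p <= y else (y, p)
                    val += phi.get(pk, 0.0)
            val *= 0.5
            new_phi[key] = val
            if x in obs and y in obs:
                pk = frozenset({x, y})
                want = req[pk]
                t = ptype.get(pk)
                good = True
                if t == "parent_offspring":
                    good = y in parents
                elif t == "full_sibling":
                    good = (len(parents) == 2
                            and set(parents) == set(parent_map.get(y, ())))
                if good:
                    good = _degree_from_kappa(val) == want
                if not good:
                    x_mis.append(f"{x}-{y}: expected {want}")
                    if len(mismatches) + len(x_mis) > budget:
                        ok = False
                        break
        if not ok:
            continue
        phi.update(new_phi)
        parent_map[x] = parents
        mismatches.extend(x_mis)
        _assign(order, k + 1, lev, sexes, obs, req, ptype, lats, budget,
                parent_map, phi, mismatches, found)
        del parent_map[x]
        for key in new_phi:
            del phi[key]
        for _ in x_mis:
            mismatches.pop()


def _finalize(order, lev, sexes, obs, req, ptype, lats, parent_map, phi,
              mismatches, found):
    # every latent must be a genuine connector: at least one child, and a
    # parentless latent with a single child is removable (drop it and record
    # the child with one parent fewer -- same kinship everywhere)
    children: dict[str, list[str]] = {i: [] for i in order}
    for c, ps in parent_map.items():
        for p in ps:
            children[p].append(c)
    for l in lats:
        if not children[l]:
            return
        if not parent_map[l] and len(children[l]) == 1:
            return

    ped = Pedigree()
    for i in order:
        ps = parent_map[i]
        father = mother = None
        if len(ps) == 1:
            if sexes[ps[0]] == "F":
                mother = ps[0]
            else:
                father = ps[0]
        elif len(ps) == 2:
            a, b = ps
            if sexes[a] == "F" or sexes[b] == "M":
                a, b = b, a
            father, mother = a, b
        ped.add_member(i, sex=sexes[i], father=father, mother=mother,
                       observed=i in obs)
    sig = _canonical_signature(ped, lats, sexes)
    if sig in found:
        return
    expected = {}
    for a, b in itertools.combinations(obs, 2):
        key = (a, b) if a <= b else (b, a)
        expected[frozenset({a, b})] = _degree_from_kappa(phi.get(key, 0.0))
    found[sig] = ConsistencyReport(
        pedigree=ped, score=0, degree_mismatches=list(mismatches),
        expected_degrees=expected)


def _canonical_signature(ped: Pedigree, lats, sexes) -> str:
    """Edge serialization minimized over relabelings of same-sex latents."""
    males = [l for l in lats if sexes[l] == "M"]
    females = [l for l in lats if sexes[l] == "F"]
    best = None
    for pm in itertools.permutations(males):
        for pf in itertools.permutations(females):
            ren = {**{a: b for a, b in zip(males, pm)},
                   **{a: b for a, b in zip(females, pf)}}

            def nm(i):
                return ren.get(i, i)

            rows = sorted(
                f"{nm(i)}<{','.join(sorted(nm(p) for p in ped.parents(i)))}"
                f":{sexes[i]}"
                for i in ped.nodes)
            sig = ";".join(rows)
            if best is None or sig < best:
                best = sig
    return best


def _score_report(report: ConsistencyReport,
                  minfo: dict[str, IndividualMeta]) -> None:
    """Count explained haplogroup sharing and age-consistent edges."""
    ped = report.pedigree
    obs = [i for i in ped.nodes if ped.nodes[i].observed]
    satisfied, violations = [], []

    for clans, label_of, tag, eligible in (
            (ped.mt_clans(),
             lambda i: minfo[i].mt_haplogroup, "mt", lambda i: True),
            (ped.y_clans(),
             lambda i: minfo[i].y_haplogroup, "Y",
             lambda i: ped.nodes[i].sex == "M")):
        for a, b in itertools.combinations(sorted(obs), 2):
            if not (eligible(a) and eligible(b)):
                continue
            la, lb = label_of(a), label_of(b)
            if "unknown" in (la, lb) or clans[a] != clans[b]:
                continue
            if la == lb:
                satisfied.append(f"{tag} identity {a}-{b}")
            else:
                violations.append(f"{tag} mismatch {a}-{b}: {la} vs {lb}")

    for c in ped.nodes:
        for p in ped.parents(c):
            if ped.nodes[c].observed and ped.nodes[p].observed:
                if (minfo[p].age_class == "subadult"
                        and minfo[c].age_class == "adult"):
                    violations.append(f"age: subadult {p} parent of adult {c}")
                else:
                    satisfied.append(f"age ok {p}->{c}")

    report.satisfied = satisfied
    report.violations = violations + [
        f"degree {m}" for m in report.degree_mismatches]
    report.score = len(satisfied) - len(report.violations)
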