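"""Minimum number of individuals (MNI) from skeletal element counts.

The count-based MNI bound: elements are sorted into lefts, rights and
unsided pieces within each age class, the per-element estimate is the
greatest of those counts, and the assemblage estimate is the maximum over
elements, summed across age classes (each age class may take its maximum
from a different element).  Severely fragmented elements (ribs, vertebrae,
phalanges) are conventionally excluded upstream; the module computes the
bound from whatever rows it is given.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

AGE_CLASSES = ("adult", "subadult")
SIDES = ("left", "right", "unsided")


@dataclass
class ElementCountTable:
    """Rows keyed by (element, age_class) with left/right/unsided counts."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        required = {"element", "age_class", *SIDES}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        for side in SIDES:
            df[side] = df[side].astype(int)
            if (df[side] < 0).any():
                raise ValueError(f"negative counts in column {side!r}")
        bad = set(df["age_class"]) - set(AGE_CLASSES)
        if bad:
            raise ValueError(f"unknown age classes: {sorted(bad)}")
        if df.duplicated(["element", "age_class"]).any():
            raise ValueError("duplicate (element, age_class) rows")
        self.table = df

    @property
    def elements(self) -> list[str]:
        return list(dict.fromkeys(self.table["element"]))


def read_element_counts(path) -> ElementCountTable:
    return ElementCountTable(pd.read_csv(path, sep="\t"))


def per_element_mni(counts: ElementCountTable, element: str) -> dict:
    """Per-age-class MNI for one element and their sum (the table-row MNI)."""
    rows = counts.table[counts.table["element"] == element]
    if rows.empty:
        raise KeyError(f"unknown element {element!r}")
    out = {}
    for age in AGE_CLASSES:
        sub = rows[rows["age_class"] == age]
        out[age] = int(sub[list(SIDES)].to_numpy().max()) if len(sub) else 0
    out["combined"] = sum(out[a] for a in AGE_CLASSES)
    return out


def total_mni(counts: ElementCountTable) -> dict:
    """Assemblage MNI: per age class the max over elements, then the sum.

    The age-class maxima may come from different elements, so the total can
    exceed every single element's combined value.
    """
    if counts.table.empty:
        raise ValueError("empty element count table")
    per = {age: 0 for age in AGE_CLASSES}
    for element in counts.elements:
        vals = per_element_mni(counts, element)
        for age in AGE_CLASSES:
            per[age] = max(per[age], vals[age])
    return {"adult": per["adult"], "subadult": per["subadult"],
            "total": per["adult"] + per["subadult"]}


def gunsan_jar_coffin_counts() -> ElementCountTable:
    """Skeletal element counts of the Gunsan jar coffin assemblage.

    Paired elements carry left/right counts; midline bones (frontal,
    occipital) are carried in the unsided column.
    """
    rows = [
        # element, adult (R, L, unsided), subadult (R, L, unsided)
        ("Frontal", (0, 0, 6), (0, 0, 2)),
        ("Parietal", (6, 6, 0), (2, 1, 0)),
        ("Temporal", (6, 6, 0), (2, 2, 0)),
        ("Occipital", (0, 0, 6), (0, 0, 1)),
        ("Maxilla", (5, 3, 0), (1, 1, 0)),
        ("Mandible", (4, 5, 0), (2, 1, 0)),
        ("Clavicle", (5, 4, 0), (0, 0, 0)),
        ("Scapula", (5, 5, 0), (0, 0, 0)),
        ("Humerus", (5, 5, 0), (3, 2, 0)),
        ("Radius", (5, 4, 0), (2, 1, 0)),
        ("Ulna", (5, 5, 0), (3, 2, 0)),
        ("Os coxae", (6, 5, 0), (2, 0, 0)),
        ("Femur", (5, 5, 0), (3, 3, 0)),
        ("Tibia", (5, 5, 0), (2, 3, 0)),
        ("Fibula", (5, 5, 0), (0, 0, 0)),
    ]
    records = []
    for element, adult, subadult in rows:
        for age, (r, l, u) in (("adult", adult), ("subadult", subadult)):
            records.append((element, age, l, r, u))
    return ElementCountTable(pd.DataFrame(
        records, columns=["element", "age_class", "left", "right", "unsided"]))
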