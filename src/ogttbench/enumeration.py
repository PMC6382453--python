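"""Exhaustive enumeration of candidate marker-set models.

A candidate model is a :class:`VariableSet` — an ordered, duplicate-free set
of marker names. Models are generated family by family: a
:class:`ModelFamily` has a fixed base, plus one or more pools of optional
*units*, where a unit is either a single marker or an atomic block of markers
that always enter together. The four clinical risk factors (age, sex, BMI,
family history) form one such block: they are always reported as a bundle,
and the published family sizes (e.g. the 252 models built from 1-h PG, >=1 of
6 metabolites, optional HbA1c and optional clinical factors:
(2^6 - 1) * 2 * 2) only come out under that convention.

Enumeration is exact — every admissible combination is listed, none sampled —
and the family size always equals the closed-form product of per-pool subset
counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import pandas as pd

__all__ = [
    "CLINICAL_BLOCK",
    "VariableSet",
    "Pool",
    "ModelFamily",
    "enumerate_family",
    "family_size",
    "enumerate_grid",
    "default_grid",
]

#: The clinical risk factors, treated as one atomic combinatorial unit.
CLINICAL_BLOCK = ("age", "sex", "bmi", "fh")

Unit = tuple[str, ...]


def as_unit(u) -> Unit:
    """Normalize a unit spec (name or iterable of names) to a tuple."""
    if isinstance(u, str):
        return (u,)
    return tuple(u)


@dataclass(frozen=True)
class VariableSet:
    """One candidate model: an ordered set of marker names.

    Canonically sorted so equality and hashing are well-defined regardless of
    the order units were drawn in.
    """

    members: tuple[str, ...]

    def __init__(self, members) -> None:
        members = tuple(members)
        if not members:
            raise ValueError("a variable set must be non-empty")
        if len(set(members)) != len(members):
            raise ValueError(f"duplicate members in variable set: {members}")
        object.__setattr__(self, "members", tuple(sorted(members)))

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __str__(self) -> str:
        return "+".join(self.members)

    @property
    def label(self) -> str:
        return str(self)


@dataclass(frozen=True)
class Pool:
    """A pool of optional units with bounds on how many are drawn."""

    units: tuple[Unit, ...]
    min_take: int = 0
    max_take: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "units", tuple(as_unit(u) for u in self.units)
        )
        hi = len(self.units) if self.max_take is None else self.max_take
        if not 0 <= self.min_take <= hi <= len(self.units):
            raise ValueError(
                f"unsatisfiable pool constraint: {self.min_take}..{hi} "
                f"from {len(self.units)} units"
            )

    @property
    def n_choices(self) -> int:
        hi = len(self.units) if self.max_take is None else self.max_take
        return sum(comb(len(self.units), k) for k in range(self.min_take, hi + 1))

    def subsets(self):
        hi = len(self.units) if self.max_take is None else self.max_take
        for k in range(self.min_take, hi + 1):
            yield from itertools.combinations(self.units, k)


def optional_unit(u) -> Pool:
    """A single unit that may be present or absent (two choices)."""
    return Pool(units=(as_unit(u),), min_take=0)


@dataclass(frozen=True)
class ModelFamily:
    """Base markers plus pools of optional units; the Cartesian span of one
    published model family."""

    name: str
    base: tuple[str, ...] = ()
    pools: tuple[Pool, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "base", tuple(self.base))
        object.__setattr__(self, "pools", tuple(self.pools))
        if not self.base and not self.pools:
            raise ValueError(f"family {self.name!r} is empty (no base, no pools)")


def family_size(family: ModelFamily) -> int:
    """Closed-form family size: the product of per-pool subset counts."""
    size = 1
    for pool in family.pools:
        size *= pool.n_choices
    return size


def enumerate_family(family: ModelFamily) -> list[VariableSet]:
    """List every variable set in the family, exactly once.

    The Cartesian product of per-pool subset choices, each flattened together
    with the base markers. Raises if a combination would be empty (possible
    only when the base is empty and every pool allows zero draws).
    """
    out: list[VariableSet] = []
    for choice in itertools.product(*(pool.subsets() for pool in family.pools)):
        members = list(family.base)
        for subset in choice:
            for unit in subset:
                members.extend(unit)
        if not members:
            raise ValueError(
                f"family {family.name!r} generates an empty variable set; "
                "give it a base or a pool with min_take >= 1"
            )
        out.append(VariableSet(members))
    assert len(out) == family_size(family)
    return out


def enumerate_grid(
    families,
) -> tuple[list[VariableSet], pd.DataFrame]:
    """Union of family enumerations, deduplicated by canonical set equality.

    Returns the ordered unique sets (first-seen order) and a provenance table
    with one row per (set, family) pair plus per-family raw counts.
    """
    families = list(families)
    if not families:
        raise ValueError("need at least one family")
    seen: dict[VariableSet, list[str]] = {}
    order: list[VariableSet] = []
    for family in families:
        for vs in enumerate_family(family):
            if vs not in seen:
                seen[vs] = []
                order.append(vs)
            seen[vs].append(family.name)
    rows = [
        {
            "model_id": i,
            "variables": vs.label,
            "n_variables": len(vs),
            "families": ";".join(seen[vs]),
        }
        for i, vs in enumerate(order)
    ]
    return order, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shipped default grid
# ---------------------------------------------------------------------------

PG_UNITS = ("pg0", "pg30", "pg60", "pg120")
INS_UNITS = ("ins0", "ins30", "ins60", "ins120")
METABOLITE_UNITS = (
    "mannose", "ahb", "hyp3_bk", "a_tocopherol", "carnitine_10_1", "x12063",
)


def pg_metabolite_family(pg: str) -> ModelFamily:
    """One glucose time point with >=1 of the six metabolites and optional
    HbA1c and clinical-factor block — the published 252-model layout."""
    return ModelFamily(
        name=f"{pg}+metabolites",
        base=(pg,),
        pools=(
            Pool(units=METABOLITE_UNITS, min_take=1),
            optional_unit("hba1c"),
            optional_unit(CLINICAL_BLOCK),
        ),
    )


def base_metabolite_family() -> ModelFamily:
    """No glucose variable: >=1 metabolite with optional HbA1c and clinical
    block — the 252 base models tested for improvement when 1-h PG is added."""
    return ModelFamily(
        name="metabolites_base",
        pools=(
            Pool(units=METABOLITE_UNITS, min_take=1),
            optional_unit("hba1c"),
            optional_unit(CLINICAL_BLOCK),
        ),
    )


def default_grid() -> list[ModelFamily]:
    """The shipped families: glucose combinations, insulin combinations,
    glucose + clinical factors, HbA1c pairings, metabolite subsets, and the
    per-time-point glucose x metabolite x HbA1c x clinical families.

    The grid reports its own deduplicated total; the published benchmark
    spanned 1527 models whose exact family composition is defined in
    supplementary tables, so the default grid is a configuration, not an
    assertion of that count.
    """
    families = [
        ModelFamily("pg_combinations", pools=(Pool(PG_UNITS, min_take=1),)),
        ModelFamily("ins_combinations", pools=(Pool(INS_UNITS, min_take=1),)),
        ModelFamily(
            "pg+clinical",
            base=CLINICAL_BLOCK,
            pools=(Pool(PG_UNITS, min_take=1),),
        ),
        ModelFamily(
            "ins+clinical",
            base=CLINICAL_BLOCK,
            pools=(Pool(INS_UNITS, min_take=1),),
        ),
        ModelFamily("clinical_only", base=CLINICAL_BLOCK),
        ModelFamily(
            "hba1c_combinations",
            base=("hba1c",),
            pools=(
                Pool(PG_UNITS, min_take=0),
                optional_unit(CLINICAL_BLOCK),
            ),
        ),
        ModelFamily(
            "metabolite_subsets", pools=(Pool(METABOLITE_UNITS, min_take=1),)
        ),
        base_metabolite_family(),
    ]
    families += [pg_metabolite_family(pg) for pg in PG_UNITS]
    return families
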