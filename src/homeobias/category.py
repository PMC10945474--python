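"""Classification of additive and non-additive expression in allotetraploids.

Each gene is compared, within one allotetraploid group, against the two
diploid progenitor groups through three pairwise differential-expression
verdicts: allotetraploid vs Cg2, allotetraploid vs Co2, and Cg2 vs Co2.
The triple of verdicts (each ``up``/``down``/``ns``) maps
deterministically onto ten categories ``a``-``j``:

===  =========================================================
a    additive, no parental differentiation (all three ns)
b    partial dominance / additive with parental differentiation
c/d  up-/down-regulated expression-level dominance toward Cg2
e/f  up-/down-regulated expression-level dominance toward Co2
g/h  up-regulated transgressive expression (parents equal / differ)
i/j  down-regulated transgressive expression (parents equal / differ)
===  =========================================================

"Equal" is operationalized as a non-significant DE verdict at the
configured fold-change and FDR thresholds; no equivalence testing is
attempted.  Every pattern not matching a-j (expression between the
parents, or opposite-direction verdicts) falls into the catch-all b.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

__all__ = [
    "SignificancePattern",
    "ExpressionCategory",
    "classify_gene",
    "classify_all",
    "tally_categories",
    "shared_eld",
    "VERDICTS",
]

VERDICTS = ("ns", "up", "down")

_SUMMARY = {**{c: "ELD" for c in "cdef"}, **{c: "TRE" for c in "ghij"}, "a": "ADD", "b": "ADD"}
_DIRECTION = {**{c: "up" for c in "cegh"}, **{c: "down" for c in "dfij"}, "a": "none", "b": "none"}
_SIDE = {"c": "Cg", "d": "Cg", "e": "Co", "f": "Co"}


@dataclass(frozen=True)
class SignificancePattern:
    """DE verdicts for one gene in one allotetraploid group.

    ``v_x_cg``: allotetraploid vs Cg2; ``v_x_co``: allotetraploid vs Co2;
    ``v_cg_co``: Cg2 vs Co2.  ``up`` means the first member is higher.
    """

    v_x_cg: str
    v_x_co: str
    v_cg_co: str

    def __post_init__(self) -> None:
        for v in (self.v_x_cg, self.v_x_co, self.v_cg_co):
            if v not in VERDICTS:
                raise ValueError(f"verdict {v!r} not in {VERDICTS}")


@dataclass(frozen=True)
class ExpressionCategory:
    category: str                  # a..j
    summary_class: str             # ADD | ELD | TRE
    direction: str                 # up | down | none
    dominance_side: str            # Cg | Co | none
    parental_differentiation: bool


def classify_gene(pattern: SignificancePattern) -> ExpressionCategory:
    """Map one verdict triple onto its expression category (total function)."""
    x_cg, x_co, cg_co = pattern.v_x_cg, pattern.v_x_co, pattern.v_cg_co
    if x_cg == "ns" and x_co == "ns":
        cat = "a" if cg_co == "ns" else "b"
    elif x_cg == "ns" and x_co == "up":
        cat = "c"
    elif x_cg == "ns" and x_co == "down":
        cat = "d"
    elif x_co == "ns" and x_cg == "up":
        cat = "e"
    elif x_co == "ns" and x_cg == "down":
        cat = "f"
    elif x_cg == "up" and x_co == "up":
        cat = "g" if cg_co == "ns" else "h"
    elif x_cg == "down" and x_co == "down":
        cat = "i" if cg_co == "ns" else "j"
    else:  # opposite directions: expression between the parents
        cat = "b"
    return ExpressionCategory(
        category=cat,
        summary_class=_SUMMARY[cat],
        direction=_DIRECTION[cat],
        dominance_side=_SIDE.get(cat, "none"),
        parental_differentiation=(cg_co != "ns"),
    )


def all_patterns() -> list[SignificancePattern]:
    """The full 27-pattern domain, in lexicographic verdict order."""
    return [SignificancePattern(*t) for t in product(VERDICTS, repeat=3)]


def classify_all(
    de_x_cg: pd.DataFrame,
    de_x_co: pd.DataFrame,
    de_cg_co: pd.DataFrame,
    group: str | None = None,
) -> pd.DataFrame:
    """Classify every gene of one allotetraploid group.

    Takes the three DE tables (columns must include ``verdict``); genes
    missing from any contrast are excluded (their number is reported in
    the result's ``attrs['n_excluded']``).
    """
    common = de_x_cg.index.intersection(de_x_co.index).intersection(de_cg_co.index)
    n_excluded = (
        len(de_x_cg.index.union(de_x_co.index).union(de_cg_co.index)) - len(common)
    )
    rows = {
        gene: classify_gene(
            SignificancePattern(
                de_x_cg.loc[gene, "verdict"],
                de_x_co.loc[gene, "verdict"],
                de_cg_co.loc[gene, "verdict"],
            )
        )
        for gene in common
    }
    out = pd.DataFrame(
        {
            "category": {g: c.category for g, c in rows.items()},
            "summary_class": {g: c.summary_class for g, c in rows.items()},
            "direction": {g: c.direction for g, c in rows.items()},
            "dominance_side": {g: c.dominance_side for g, c in rows.items()},
            "parental_differentiation": {g: c.parental_differentiation for g, c in rows.items()},
        }
    ).reindex(common)
    out.index.name = "gene"
    if group is not None:
        out.insert(0, "group", group)
    out.attrs["n_excluded"] = n_excluded
    return out


def tally_categories(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Count genes by (group, summary class, direction, dominance side)."""
    rows = []
    for group, table in tables.items():
        counts = (
            table.groupby(["summary_class", "direction", "dominance_side"], observed=True)
            .size()
            .rename("n_genes")
            .reset_index()
        )
        counts.insert(0, "group", group)
        rows.append(counts)
    if not rows:
        return pd.DataFrame(columns=["group", "summary_class", "direction", "dominance_side", "n_genes"])
    return pd.concat(rows, ignore_index=True)


def shared_eld(tables: dict[str, pd.DataFrame]) -> dict[tuple[str, str], dict[frozenset, set]]:
    """Venn regions of complete-ELD genes across allotetraploid groups.

    A gene counts as shared between groups only when its dominance side
    AND direction agree.  For each (dominance_side, direction) key the
    value maps a frozenset of group names to the genes found in exactly
    those groups; the region keyed by all groups is the full intersection.
    """
    if len(tables) < 2:
        raise ValueError("need at least two groups")
    keys = [(side, direction) for side in ("Cg", "Co") for direction in ("up", "down")]
    groups = list(tables)
    out: dict[tuple[str, str], dict[frozenset, set]] = {}
    for side, direction in keys:
        sets = {
            g: set(
                t.index[
                    (t["summary_class"] == "ELD")
                    & (t["dominance_side"] == side)
                    & (t["direction"] == direction)
                ]
            )
            for g, t in tables.items()
        }
        regions: dict[frozenset, set] = {}
        universe = set().union(*sets.values())
        for gene in universe:
            members = frozenset(g for g in groups if gene in sets[g])
            regions.setdefault(members, set()).add(gene)
        regions.setdefault(frozenset(groups), set())
        out[(side, direction)] = regions
    return out
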