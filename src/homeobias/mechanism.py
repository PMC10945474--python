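"""Diagnostics for the mechanism behind expression-level dominance.

For an ELD gene, the EL-dominant homoeolog is the one inherited from
the diploid parent that the gene's total expression matches; the other
homoeolog is EL-recessive.  Comparing each homoeolog's expression
change relative to its own parent — log2FC(cg/Cg2) and log2FC(co/Co2)
from phased differential expression against phasing-rescaled diploids —
separates three candidate mechanisms:

* ``copy_driven`` — extra copies of the dominant homoeolog (homoeologous
  exchange): dominant homoeolog up, recessive down, in both up- and
  down-regulated ELD classes.
* ``random_effects`` — stochastic regulatory perturbations (e.g. new TE
  insertions): dominant and recessive homoeologs change similarly on
  average.
* ``trans_driven`` — divergent trans-acting regulators act on both
  homoeologs: the dominant homoeolog barely changes while the recessive
  one moves toward the dominant parent's level.

The decision compares per-class average fold changes against a
tolerance ``tau`` (default 0.25 log2 units); the location estimate is a
10 % trimmed mean, because complete expression loss and whole-block
copy-number changes put a few extreme fold changes in the tails of every
class.  A Welch two-sample t-test comparing dominant and recessive fold
changes is reported alongside, but the verdict is never based on
significance alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HomoeologFoldChange", "ScenarioVerdict", "homoeolog_foldchanges", "scenario_diagnostic"]

#: the four complete-ELD classes: (dominance side, direction)
ELD_CLASSES = [("Cg", "up"), ("Cg", "down"), ("Co", "up"), ("Co", "down")]


HomoeologFoldChange = pd.DataFrame  # gene-indexed: log2fc_cg, log2fc_co, category, ...


@dataclass
class ScenarioVerdict:
    """Per-class summaries and the combined mechanistic verdict."""

    per_class: pd.DataFrame
    scenario: str
    tau: float
    n_genes: int = 0


def homoeolog_foldchanges(
    de_cg: pd.DataFrame,
    de_co: pd.DataFrame,
    categories: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-homoeolog fold changes with expression categories.

    ``de_cg`` / ``de_co`` are DE tables of the group's cg (co) homoeolog
    expression against the rescaled Cg2 (Co2) diploid expression, with a
    ``log2FC`` column oriented allotetraploid-over-diploid.  Genes
    missing any of the three tables are skipped; the skipped count is in
    ``attrs['n_skipped']``.
    """
    common = de_cg.index.intersection(de_co.index).intersection(categories.index)
    union = de_cg.index.union(de_co.index).union(categories.index)
    out = pd.DataFrame(
        {
            "log2fc_cg": de_cg.loc[common, "log2FC"],
            "log2fc_co": de_co.loc[common, "log2FC"],
            "category": categories.loc[common, "category"],
            "summary_class": categories.loc[common, "summary_class"],
            "direction": categories.loc[common, "direction"],
            "dominance_side": categories.loc[common, "dominance_side"],
        }
    )
    is_eld = out["summary_class"] == "ELD"
    out["dominant"] = np.where(
        is_eld, np.where(out["dominance_side"] == "Cg", "cg", "co"), "none"
    )
    out["log2fc_dominant"] = np.where(
        is_eld, np.where(out["dominant"] == "cg", out["log2fc_cg"], out["log2fc_co"]), np.nan
    )
    out["log2fc_recessive"] = np.where(
        is_eld, np.where(out["dominant"] == "cg", out["log2fc_co"], out["log2fc_cg"]), np.nan
    )
    out.attrs["n_skipped"] = len(union) - len(common)
    return out


def _class_row(sub: pd.DataFrame, side: str, direction: str, tau: float, min_genes: int) -> dict:
    dom = sub["log2fc_dominant"].to_numpy(dtype=float)
    rec = sub["log2fc_recessive"].to_numpy(dtype=float)
    n = len(sub)
    # the decision statistic is a 10% trimmed mean: complete-loss and
    # whole-block copy-number genes put extreme fold changes in the tails
    row = {
        "dominance_side": side,
        "direction": direction,
        "n": n,
        "mean_dominant": float(np.mean(dom)) if n else np.nan,
        "mean_recessive": float(np.mean(rec)) if n else np.nan,
        "trimmed_dominant": float(stats.trim_mean(dom, 0.1)) if n else np.nan,
        "trimmed_recessive": float(stats.trim_mean(rec, 0.1)) if n else np.nan,
        "t": np.nan,
        "df": np.nan,
        "p": np.nan,
    }
    if n >= 2:
        if np.allclose(dom, rec):
            row.update(t=0.0, df=float(2 * n - 2), p=1.0)
        else:
            res = stats.ttest_ind(dom, rec, equal_var=False)
            nd = len(dom)
            vd, vr = np.var(dom, ddof=1), np.var(rec, ddof=1)
            if vd + vr > 0:
                df_w = (vd / nd + vr / nd) ** 2 / (
                    (vd / nd) ** 2 / (nd - 1) + (vr / nd) ** 2 / (nd - 1)
                )
            else:
                df_w = float(2 * nd - 2)
            row.update(t=float(res.statistic), df=float(df_w), p=float(res.pvalue))
    if n < min_genes:
        row["class_verdict"] = "other: insufficient"
        return row
    md, mr = row["trimmed_dominant"], row["trimmed_recessive"]
    moved_toward_dominant = mr >= tau if direction == "up" else mr <= -tau
    if md > tau and mr < -tau:
        row["class_verdict"] = "copy_driven"
    elif abs(md - mr) < tau:
        row["class_verdict"] = "random_effects"
    elif abs(md) < tau and moved_toward_dominant:
        row["class_verdict"] = "trans_driven"
    else:
        row["class_verdict"] = "other"
    return row


def scenario_diagnostic(
    hfc: pd.DataFrame,
    tau: float = 0.25,
    min_genes: int = 20,
) -> ScenarioVerdict:
    """Assign the best-fitting ELD mechanism from homoeolog fold changes.

    Complete-ELD genes are split into the four (side, direction) classes;
    per class, mean dominant and recessive fold changes are computed and
    matched to the scenario patterns with tolerance ``tau``.  The overall
    scenario is the one whose pattern holds in every class with at least
    ``min_genes`` genes (classes below that are ignored); conflicting
    classes yield ``other``.  Transgressive genes are excluded from the
    decision.
    """
    eld = hfc[hfc["summary_class"] == "ELD"]
    rows = [
        _class_row(
            eld[(eld["dominance_side"] == side) & (eld["direction"] == direction)],
            side, direction, tau, min_genes,
        )
        for side, direction in ELD_CLASSES
    ]
    per_class = pd.DataFrame(rows)
    informative = per_class[~per_class["class_verdict"].str.startswith("other: insufficient")]
    if informative.empty:
        scenario = "other: insufficient"
    else:
        verdicts = set(informative["class_verdict"])
        scenario = verdicts.pop() if len(verdicts) == 1 else "other"
    return ScenarioVerdict(
        per_class=per_class, scenario=scenario, tau=tau, n_genes=int(len(eld))
    )
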