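"""Detection of homoeolog-specific expression loss.

The most extreme homoeolog expression bias is the complete silence of
one homoeolog.  A gene is screened for loss of its ``cg`` (or ``co``)
homoeolog only when it shows solid expression — CPM strictly above
``hi`` (default 5) — in every individual of the corresponding diploid
group; a loss event is then called for each allotetraploid individual
in which that homoeolog's CPM falls strictly below ``lo`` (default
0.5).  Expression data alone cannot distinguish physical homoeolog loss
from silencing; events should be read as loss of homoeolog *expression*.

Homoeolog CPM uses, by default, the subgenome's own library size (the
sum of that subgenome's assigned reads in the individual), which makes
the statistic robust to genome-wide bias between subgenomes; the
combined cg + co library is available as an alternative denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .counts_io import CountMatrix, PhasedCounts, cpm

__all__ = ["LossEvent", "detect_loss"]

_DIPLOID_OF = {"cg": "Cg2", "co": "Co2"}


@dataclass(frozen=True)
class LossEvent:
    gene: str
    individual: str
    lost_subgenome: str   # 'cg' | 'co'
    diploid_min_cpm: float
    allotetraploid_cpm: float


def detect_loss(
    diploid: CountMatrix,
    phased: PhasedCounts,
    hi: float = 5.0,
    lo: float = 0.5,
    denominator: str = "subgenome",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Find homoeolog expression-loss events.

    Parameters
    ----------
    diploid
        Unphased counts containing both diploid groups (``Cg2``, ``Co2``
        in the sample metadata ``group`` column).
    phased
        Homoeolog counts of the allotetraploid individuals.
    hi, lo
        Eligibility and loss CPM thresholds; both strict inequalities.
    denominator
        ``"subgenome"`` (default) computes homoeolog CPM against the
        subgenome's own assigned-read total, ``"combined"`` against the
        cg + co total of the individual.

    Returns
    -------
    events, per_individual
        ``events``: one row per (gene, individual, lost subgenome);
        ``per_individual``: loss counts per individual × subgenome.
    """
    if denominator not in ("subgenome", "combined"):
        raise ValueError("denominator must be 'subgenome' or 'combined'")
    meta = diploid.sample_meta
    events: list[LossEvent] = []
    for sub in ("cg", "co"):
        group = _DIPLOID_OF[sub]
        dip_samples = diploid.samples_in_group(group)
        if not dip_samples:
            raise ValueError(f"diploid group {group!r} missing from input")
        dip_cpm = cpm(diploid.counts[dip_samples])
        eligible = (dip_cpm > hi).all(axis=1)
        dip_min = dip_cpm.min(axis=1)

        counts = getattr(phased, sub)
        if denominator == "subgenome":
            lib = counts.sum(axis=0)
        else:
            lib = (phased.cg + phased.co).sum(axis=0)
        tet_cpm = counts / lib * 1e6

        shared = counts.index.intersection(dip_cpm.index[eligible])
        low = tet_cpm.loc[shared] < lo
        for ind in low.columns:
            for gene in low.index[low[ind]]:
                events.append(
                    LossEvent(
                        gene=gene,
                        individual=ind,
                        lost_subgenome=sub,
                        diploid_min_cpm=float(dip_min[gene]),
                        allotetraploid_cpm=float(tet_cpm.loc[gene, ind]),
                    )
                )
    table = pd.DataFrame(
        [e.__dict__ for e in events],
        columns=["gene", "individual", "lost_subgenome", "diploid_min_cpm", "allotetraploid_cpm"],
    )
    counts_tbl = (
        table.groupby(["individual", "lost_subgenome"], observed=True).size().rename("n_events")
        if len(table)
        else pd.Series(dtype=int, name="n_events")
    )
    per_individual = (
        counts_tbl.reset_index()
        if len(table)
        else pd.DataFrame(columns=["individual", "lost_subgenome", "n_events"])
    )
    # individuals with zero events still appear in the per-individual table
    full = pd.MultiIndex.from_product(
        [list(phased.individuals), ["cg", "co"]], names=["individual", "lost_subgenome"]
    )
    per_individual = (
        per_individual.set_index(["individual", "lost_subgenome"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    return table, per_individual
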