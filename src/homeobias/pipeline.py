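"""End-to-end orchestration: simulate/load -> normalize -> DE -> classify
-> HEB segmentation -> loss -> mechanism.

All thresholds flow from one :class:`PipelineConfig` so no stage invents
its own defaults.  Each tissue is one independent run.  With an output
directory every stage writes a TSV and the run ends with a JSON manifest
(seed, configuration, per-stage gene counts) so two runs with the same
seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .category import classify_all, shared_eld, tally_categories
from .counts_io import (
    CountMatrix,
    PhasedCounts,
    downsample,
    filter_expressed,
    rescale_diploid_by_phasing,
    tmm_factors,
    write_counts_tsv,
    write_phased_tsv,
)
from .diffexpr import estimate_dispersion, test_contrast
from .heb import (
    NATURAL_PRESET,
    RESYNTHESIZED_PRESET,
    HMMParams,
    breakpoint_stats,
    compute_heb,
    hmm_segment,
    variance_explained,
)
from .loss import detect_loss
from .mechanism import homoeolog_foldchanges, scenario_diagnostic
from .simdata import DIPLOID_GROUPS, TETRAPLOID_GROUPS, SimConfig, SimulatedDataset, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]

RESYNTHESIZED_GROUPS = ("Sd", "Sh")


@dataclass
class PipelineConfig:
    """Single source of truth for every stage's thresholds."""

    sim: SimConfig = field(default_factory=SimConfig)
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    min_cpm: float = 1.0
    min_samples: int = 2
    heb_min_cpm: float = 1.0
    loss_hi: float = 5.0
    loss_lo: float = 0.5
    loss_denominator: str = "subgenome"
    tau: float = 0.25
    em_iterations: int = 0
    do_downsample: bool = True
    seed: int = 0
    outdir: str | None = None


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    filtered: CountMatrix
    norm_factors: pd.Series
    de_unphased: dict
    categories: dict
    tallies: pd.DataFrame
    shared: dict
    de_phased: dict
    segmentations: dict
    bp_stats: dict
    r2_copy_number: float
    loss_events: pd.DataFrame
    loss_counts: pd.DataFrame
    foldchanges: dict
    verdicts: dict
    manifest: dict


def _phased_group_matrix(
    dataset: SimulatedDataset, group: str, genes: pd.Index
) -> tuple[CountMatrix, pd.Series]:
    """Combined matrix for phased DE of one allotetraploid group:
    its cg and co subgenome columns plus the phasing-rescaled diploids."""
    phased = dataset.phased
    inds = phased.individuals_in_group(group)
    sub = phased.subset_individuals(inds)
    dip_samples = [
        s for g in DIPLOID_GROUPS for s in dataset.unphased.samples_in_group(g)
    ]
    diploid = dataset.unphased.subset_samples(dip_samples)
    rescaled = rescale_diploid_by_phasing(diploid, sub)

    shared_genes = genes.intersection(rescaled.gene_ids).intersection(phased.gene_ids)
    cols = {}
    groups = {}
    for ind in inds:
        cols[f"{ind}:cg"] = sub.cg.loc[shared_genes, ind]
        groups[f"{ind}:cg"] = f"{group}_cg"
        cols[f"{ind}:co"] = sub.co.loc[shared_genes, ind]
        groups[f"{ind}:co"] = f"{group}_co"
    for s in dip_samples:
        cols[s] = rescaled.counts.loc[shared_genes, s]
        groups[s] = diploid.sample_meta.loc[s, "group"]
    frame = pd.DataFrame(cols)
    meta = pd.DataFrame({"group": pd.Series(groups)})
    return CountMatrix(frame, meta), pd.Series(groups)


def run_all(config: PipelineConfig, dataset: SimulatedDataset | None = None) -> PipelineResult:
    """Run every stage and return the bundled results.

    ``dataset`` defaults to a fresh simulation from ``config.sim``; pass
    a loaded :class:`SimulatedDataset` to analyze external data (its
    ``truth`` may be None, in which case recovery numbers are skipped).
    """
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    if dataset is None:
        logger.info("simulating dataset (seed=%d)", config.sim.seed)
        dataset = simulate_experiment(config.sim)
    unphased = dataset.unphased
    meta = unphased.sample_meta
    manifest["stages"]["input_genes"] = int(unphased.counts.shape[0])

    # --- normalization funnel -------------------------------------------
    if config.do_downsample:
        group_means = unphased.library_sizes.groupby(meta["group"]).mean()
        target = int(np.floor(group_means.min()))
        unphased = downsample(unphased, target, np.random.default_rng(config.seed))
        manifest["stages"]["downsample_target"] = target
    expressed = filter_expressed(unphased, config.min_cpm, config.min_samples)
    filtered = unphased.subset_genes(expressed)
    factors = tmm_factors(filtered)
    manifest["stages"]["expressed_genes"] = int(len(expressed))

    groups = meta["group"]
    dispersions = estimate_dispersion(filtered, groups.loc[filtered.samples], factors)

    # --- unphased DE and expression categories --------------------------
    de_unphased = {}
    de_unphased[("Cg2", "Co2")] = test_contrast(
        filtered, groups, ("Cg2", "Co2"), factors, dispersions,
        config.fc_threshold, config.fdr_threshold,
    )
    for tet in TETRAPLOID_GROUPS:
        for dip in DIPLOID_GROUPS:
            de_unphased[(tet, dip)] = test_contrast(
                filtered, groups, (tet, dip), factors, dispersions,
                config.fc_threshold, config.fdr_threshold,
            )
    categories = {
        tet: classify_all(
            de_unphased[(tet, "Cg2")], de_unphased[(tet, "Co2")], de_unphased[("Cg2", "Co2")],
            group=tet,
        )
        for tet in TETRAPLOID_GROUPS
    }
    tallies = tally_categories(categories)
    shared = shared_eld(categories)
    manifest["stages"]["classified_genes"] = {t: int(len(c)) for t, c in categories.items()}

    # --- phased DE (subgenomes vs rescaled diploids) --------------------
    de_phased = {}
    for tet in TETRAPLOID_GROUPS:
        cm, pgroups = _phased_group_matrix(dataset, tet, expressed)
        pfactors = tmm_factors(cm)
        pdisp = estimate_dispersion(cm, pgroups, pfactors)
        for sub, dip in (("cg", "Cg2"), ("co", "Co2")):
            de_phased[(tet, sub)] = test_contrast(
                cm, pgroups, (f"{tet}_{sub}", dip), pfactors, pdisp,
                config.fc_threshold, config.fdr_threshold,
            )

    # --- HEB tracks and copy-number segmentation ------------------------
    segmentations: dict[str, list] = {}
    resyn_inds = [
        i for g in RESYNTHESIZED_GROUPS for i in dataset.phased.individuals_in_group(g)
    ]
    natural_inds = dataset.phased.individuals_in_group("Cbp")
    resyn_params = HMMParams(
        e=RESYNTHESIZED_PRESET.e, strength=RESYNTHESIZED_PRESET.strength,
        em_iterations=config.em_iterations,
    )
    natural_params = HMMParams(
        e=NATURAL_PRESET.e, strength=NATURAL_PRESET.strength,
        em_iterations=config.em_iterations,
    )
    for label, inds, params, cand in (
        ("resynthesized", resyn_inds, resyn_params, False),
        ("natural", natural_inds, natural_params, True),
    ):
        if not inds:
            segmentations[label] = []
            continue
        tracks = compute_heb(
            dataset.phased.subset_individuals(inds), dataset.annotation, config.heb_min_cpm
        )
        segmentations[label] = [hmm_segment(t, params, candidate_only=cand) for t in tracks]
    bp_stats = breakpoint_stats(segmentations["resynthesized"])
    manifest["stages"]["heb_quartets"] = int(bp_stats["n_quartets"])

    # variance of HEB explained by inferred copy number (resynthesized)
    track_lookup = {
        (t.individual, t.chromosome): t
        for t in compute_heb(
            dataset.phased.subset_individuals(resyn_inds), dataset.annotation, config.heb_min_cpm
        )
    } if resyn_inds else {}
    cg_obs, tot_obs, state_obs = [], [], []
    for seg in segmentations["resynthesized"]:
        t = track_lookup[(seg.individual, seg.chromosome)]
        cg_obs.append(t.cg)
        tot_obs.append(t.cg + t.co)
        state_obs.append(seg.states)
    r2 = (
        variance_explained(
            np.concatenate(cg_obs), np.concatenate(tot_obs), np.concatenate(state_obs)
        )
        if cg_obs
        else float("nan")
    )

    # --- loss of homoeolog expression -----------------------------------
    dip_samples = [s for g in DIPLOID_GROUPS for s in dataset.unphased.samples_in_group(g)]
    loss_events, loss_counts = detect_loss(
        dataset.unphased.subset_samples(dip_samples),
        dataset.phased,
        config.loss_hi, config.loss_lo, config.loss_denominator,
    )

    # --- ELD mechanism diagnostics ---------------------------------------
    foldchanges = {}
    verdicts = {}
    for tet in TETRAPLOID_GROUPS:
        hfc = homoeolog_foldchanges(
            de_phased[(tet, "cg")], de_phased[(tet, "co")], categories[tet]
        )
        foldchanges[tet] = hfc
        verdicts[tet] = scenario_diagnostic(hfc, config.tau)
    resyn_hfc = pd.concat([foldchanges[g] for g in RESYNTHESIZED_GROUPS])
    resyn_hfc.attrs["n_skipped"] = 0
    verdicts["resynthesized"] = scenario_diagnostic(resyn_hfc, config.tau)

    result = PipelineResult(
        dataset=dataset,
        filtered=filtered,
        norm_factors=factors,
        de_unphased=de_unphased,
        categories=categories,
        tallies=tallies,
        shared=shared,
        de_phased=de_phased,
        segmentations=segmentations,
        bp_stats=bp_stats,
        r2_copy_number=r2,
        loss_events=loss_events,
        loss_counts=loss_counts,
        foldchanges=foldchanges,
        verdicts=verdicts,
        manifest=manifest,
    )
    if config.outdir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts_tsv(result.filtered, out / "counts_filtered.tsv", out / "sample_meta.tsv")
    write_phased_tsv(result.dataset.phased, out / "phased_counts.tsv")
    result.norm_factors.to_csv(out / "tmm_factors.tsv", sep="\t")
    for (a, b), table in result.de_unphased.items():
        table.to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t")
    for (tet, sub), table in result.de_phased.items():
        table.to_csv(out / f"de_phased_{tet}_{sub}.tsv", sep="\t")
    pd.concat(result.categories.values()).to_csv(out / "categories.tsv", sep="\t")
    result.tallies.to_csv(out / "category_tallies.tsv", sep="\t", index=False)
    seg_rows = []
    for label, segs in result.segmentations.items():
        for seg in segs:
            for i, gene in enumerate(seg.genes):
                seg_rows.append(
                    {
                        "set": label,
                        "individual": seg.individual,
                        "chromosome": seg.chromosome,
                        "gene": gene,
                        "state": int(seg.states[i]),
                        "candidate_only": seg.candidate_only,
                    }
                )
    pd.DataFrame(seg_rows).to_csv(out / "segmentation.tsv", sep="\t", index=False)
    result.bp_stats["per_quartet"].to_csv(out / "breakpoints_per_quartet.tsv", sep="\t", index=False)
    result.loss_events.to_csv(out / "loss_events.tsv", sep="\t", index=False)
    result.loss_counts.to_csv(out / "loss_counts.tsv", sep="\t", index=False)
    for tet, verdict in result.verdicts.items():
        verdict.per_class.assign(scenario=verdict.scenario).to_csv(
            out / f"mechanism_{tet}.tsv", sep="\t", index=False
        )
    manifest = dict(result.manifest)
    manifest["config"] = asdict(config)
    manifest["bp_mean"] = result.bp_stats["mean_breakpoints"]
    manifest["r2_copy_number"] = result.r2_copy_number
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
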