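"""Synthetic allopolyploid RNA-seq generator with known ground truth.

The generator emulates a two-parent allotetraploid study design: two
diploid progenitor groups (``Cg2``, ``Co2``), two resynthesized
allotetraploid groups (``Sd``, ``Sh``) and one natural allotetraploid
group (``Cbp``), each with a configurable number of lines and one RNA
individual per line.

Every allotetraploid individual carries, per chromosome, a latent
cg-homoeolog copy-number path over the states {0, 1, 2, 3, 4}
(co copies = 4 − cg).  Homoeologous exchange is modelled as a Poisson
number of breakpoints per chromosome quartet; segments between
breakpoints take a constant copy state.  Per-homoeolog expression
expectation scales linearly with copy number, is modulated by the
configured regulatory effects (expression-level dominance, transgressive
expression, homoeolog expression loss), and is read out as negative
binomial counts scaled to a lognormal library size.  Read phasing is
binomial thinning: each homoeolog read is assigned with probability
``phasing_efficiency``, otherwise it joins the unassigned pool, so
``cg + co + unassigned`` reconstructs the unphased count exactly.

Ground truth (copy states, breakpoints, per-gene regulatory class, loss
events) is retained in :class:`SimTruth` for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .counts_io import CountMatrix, GeneAnnotation, PhasedCounts

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "DIPLOID_GROUPS",
    "TETRAPLOID_GROUPS",
    "simulate_copy_number_blocks",
    "simulate_experiment",
    "simulate_heb_track",
]

DIPLOID_GROUPS = ("Cg2", "Co2")
TETRAPLOID_GROUPS = ("Sd", "Sh", "Cbp")

#: median homoeolog expression bias expected for 0..4 cg copies
STATE_MEDIANS = (0.01, 0.25, 0.5, 0.75, 0.99)


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults follow the emulated study design: 8 chromosomes, 6 lines per
    group, ~50 % read phasing, and 0.833 expected homoeologous-exchange
    breakpoints per chromosome quartet.
    """

    n_chromosomes: int = 8
    genes_per_chromosome: int = 400
    n_lines_per_group: int = 6
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    parental_divergence_prob: float = 0.30
    parental_divergence_sd: float = 1.0
    nb_dispersion: float = 0.05
    library_size_mean: float = 1e7
    tetraploid_library_factor: float = 1.8
    library_size_cv: float = 0.10
    phasing_efficiency: float = 0.5
    breakpoint_rate: float = 0.833
    eld_fraction: float = 0.05
    tre_fraction: float = 0.013
    loss_fraction: float = 0.01
    eld_scenario: str = "trans_driven"
    eld_min_divergence: float = 1.5
    random_effect_sd: float = 1.5
    tre_log2_effect: float = 2.0
    loss_multiplier: float = 1e-4
    tissue: str = "flower"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("parental_divergence_prob", "phasing_efficiency",
                     "eld_fraction", "tre_fraction", "loss_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.eld_fraction + self.tre_fraction + self.loss_fraction > 1.0:
            raise ValueError("eld + tre + loss fractions exceed 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("n_chromosomes", "genes_per_chromosome", "n_lines_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.breakpoint_rate < 0:
            raise ValueError("breakpoint_rate must be >= 0")
        if self.eld_scenario not in ("copy_driven", "random", "trans_driven"):
            raise ValueError(f"unknown eld_scenario {self.eld_scenario!r}")

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome


@dataclass
class SimTruth:
    """Latent ground truth retained for recovery tests."""

    copy_state: pd.DataFrame      # genes × tetraploid individuals, cg copies 0..4
    breakpoints: dict             # (individual, chromosome) -> list of within-chrom gene indices
    category_truth: pd.DataFrame  # per gene: class, eld_side, divergence (log2 Co - Cg)
    loss_truth: pd.DataFrame      # genes × tetraploid individuals, '' | 'cg' | 'co'
    expected_cg: pd.DataFrame | None = None  # expected homoeolog expression (relative units)
    expected_co: pd.DataFrame | None = None

    def unbalanced_fraction(self, individuals=None) -> float:
        """Fraction of (gene, individual) pairs with copy state != 2."""
        states = self.copy_state if individuals is None else self.copy_state[list(individuals)]
        return float((states.to_numpy() != 2).mean())

    def expression_lost(self, subgenome: str) -> pd.DataFrame:
        """Boolean genes × individuals table: is the subgenome's expression
        lost in that individual?

        True either through a regulatory loss event or through a
        copy-number block with zero copies of that subgenome (cg state 0,
        or state 4 for the co-homoeolog) — homoeologous exchange removes
        expression just as effectively as silencing.
        """
        if subgenome not in ("cg", "co"):
            raise ValueError("subgenome must be 'cg' or 'co'")
        regulatory = self.loss_truth == subgenome
        zero_copy = self.copy_state == (0 if subgenome == "cg" else 4)
        return regulatory | zero_copy

    def expected_homoeolog_cpm(self, subgenome: str) -> pd.DataFrame:
        """Noise-free homoeolog CPM implied by the generator's expectations,
        against the subgenome's own expected library size."""
        table = {"cg": self.expected_cg, "co": self.expected_co}[subgenome]
        if table is None:
            raise ValueError("expected expression tables were not recorded")
        return table / table.sum(axis=0) * 1e6


@dataclass
class SimulatedDataset:
    unphased: CountMatrix
    phased: PhasedCounts
    annotation: GeneAnnotation
    truth: SimTruth
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]


def simulate_copy_number_blocks(
    cfg: SimConfig, individual_seed: int
) -> dict[str, tuple[np.ndarray, list[int]]]:
    """Simulate per-chromosome cg copy-number paths for one individual.

    The number of breakpoints per chromosome is Poisson(``breakpoint_rate``);
    breakpoint positions are uniform without replacement.  The segment
    adjacent to one chromosome end keeps the balanced 2:2 state (state 2)
    and each subsequent segment draws uniformly from the four remaining
    states, so no two adjacent segments are equal; the orientation of the
    chromosome is randomized.  Zero breakpoints yield the constant state 2.

    Returns a mapping chromosome id -> (states array, breakpoint indices),
    a breakpoint index ``b`` meaning the state changes between genes
    ``b-1`` and ``b``.
    """
    rng = np.random.default_rng(individual_seed)
    out: dict[str, tuple[np.ndarray, list[int]]] = {}
    n = cfg.genes_per_chromosome
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        k = rng.poisson(cfg.breakpoint_rate) if n > 1 else 0
        k = min(k, n - 1)
        cuts = np.sort(rng.choice(np.arange(1, n), size=k, replace=False)) if k else np.array([], int)
        states = np.empty(n, dtype=int)
        seg_states = [2]
        for _ in range(k):
            choices = [s for s in range(5) if s != seg_states[-1]]
            seg_states.append(int(rng.choice(choices)))
        bounds = np.concatenate([[0], cuts, [n]])
        for i, s in enumerate(seg_states):
            states[bounds[i]:bounds[i + 1]] = s
        if rng.random() < 0.5:  # balanced anchor equally likely at either end
            states = states[::-1].copy()
            cuts = n - cuts[::-1]
        out[chrom] = (states, [int(b) for b in cuts])
    return out


def _assign_categories(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw each gene's regulatory class and parental divergence."""
    g = cfg.n_genes
    mu = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, g)
    delta = np.where(
        rng.random(g) < cfg.parental_divergence_prob,
        rng.normal(0.0, cfg.parental_divergence_sd, g),
        0.0,
    )
    u = rng.random(g)
    klass = np.full(g, "additive", dtype=object)
    klass[u < cfg.eld_fraction] = "eld"
    klass[(u >= cfg.eld_fraction) & (u < cfg.eld_fraction + cfg.tre_fraction)] = "tre"
    hi = cfg.eld_fraction + cfg.tre_fraction
    klass[(u >= hi) & (u < hi + cfg.loss_fraction)] = "loss"

    eld = klass == "eld"
    # ELD is only observable when the parents differ; enforce a detectable gap
    sign = rng.choice([-1.0, 1.0], size=g)
    forced = sign * (cfg.eld_min_divergence + np.abs(rng.normal(0.0, cfg.parental_divergence_sd, g)))
    delta = np.where(eld, forced, delta)
    side = np.where(eld, rng.choice(["cg", "co"], size=g), "none")
    if cfg.eld_scenario == "copy_driven":
        # dosage can only pull the total toward the higher parent while
        # staying within the fold-change band, so dominance goes to the
        # higher-expressed parent's side
        side = np.where(eld, np.where(delta < 0, "cg", "co"), "none")

    loss = klass == "loss"
    # loss detection screens on solid diploid expression; keep those genes
    # clearly expressed without pushing the silenced residual over the bound
    mu = np.where(loss, rng.normal(cfg.baseline_log2_mean + 1.0, 1.0, g), mu)
    delta = np.where(loss, rng.normal(0.0, 0.5, g), delta)
    loss_side = np.where(loss, rng.choice(["cg", "co"], size=g), "")

    tre = klass == "tre"
    tre_dir = np.where(tre, rng.choice(["up", "down"], size=g), "none")

    genes = [f"g{i + 1:05d}" for i in range(g)]
    return pd.DataFrame(
        {
            "class": klass,
            "mu_log2": mu,
            "delta_log2": delta,
            "eld_side": side,
            "tre_direction": tre_dir,
            "loss_side": loss_side,
        },
        index=pd.Index(genes, name="gene"),
    )


def _regulatory_multipliers(
    cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene multiplicative effects (r_cg, r_co) on homoeolog expectations."""
    g = len(genes)
    r_cg = np.ones(g)
    r_co = np.ones(g)
    delta = genes["delta_log2"].to_numpy()
    klass = genes["class"].to_numpy()
    side = genes["eld_side"].to_numpy()

    eld = klass == "eld"
    if cfg.eld_scenario == "trans_driven":
        # the recessive homoeolog's per-copy expression is pulled to the
        # dominant parent's per-copy level (complete ELD)
        to_cg = eld & (side == "cg")
        to_co = eld & (side == "co")
        r_co = np.where(to_cg, 2.0 ** (-delta), r_co)
        r_cg = np.where(to_co, 2.0 ** (+delta), r_cg)
    elif cfg.eld_scenario == "random":
        # mechanism with stochastic, homoeolog-symmetric effects: each
        # homoeolog shifts independently; dominance emerges by chance
        r_cg = np.where(eld, 2.0 ** rng.normal(0.0, cfg.random_effect_sd, g), r_cg)
        r_co = np.where(eld, 2.0 ** rng.normal(0.0, cfg.random_effect_sd, g), r_co)
    # copy_driven: no regulatory shift; dominance arises from copy blocks only

    tre = klass == "tre"
    up = tre & (genes["tre_direction"].to_numpy() == "up")
    down = tre & (genes["tre_direction"].to_numpy() == "down")
    # shift the whole gene beyond the higher (lower) parent by tre_log2_effect;
    # baseline tetraploid total at 2:2 is the parental sum
    total_log2 = np.log2(2.0 ** genes["mu_log2"].to_numpy() + 2.0 ** (genes["mu_log2"] + genes["delta_log2"]).to_numpy())
    hi_parent = genes["mu_log2"].to_numpy() + np.maximum(delta, 0.0)
    lo_parent = genes["mu_log2"].to_numpy() + np.minimum(delta, 0.0)
    f_up = 2.0 ** (hi_parent + cfg.tre_log2_effect - total_log2)
    f_down = 2.0 ** (lo_parent - cfg.tre_log2_effect - total_log2)
    r_cg = np.where(up, f_up, np.where(down, f_down, r_cg))
    r_co = np.where(up, f_up, np.where(down, f_down, r_co))

    lost_cg = genes["loss_side"].to_numpy() == "cg"
    lost_co = genes["loss_side"].to_numpy() == "co"
    r_cg = np.where(lost_cg, r_cg * cfg.loss_multiplier, r_cg)
    r_co = np.where(lost_co, r_co * cfg.loss_multiplier, r_co)
    return r_cg, r_co


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; var = mu + dispersion*mu^2."""
    mean = np.clip(mean, 1e-12, None)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_experiment(cfg: SimConfig) -> SimulatedDataset:
    """Simulate the full five-group experiment for one tissue.

    Returns unphased counts for all samples, phased homoeolog counts for
    the allotetraploid individuals, gene annotation, and the ground truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _assign_categories(cfg, rng)
    gene_ids = genes.index
    g = len(gene_ids)

    chroms = np.repeat([f"chr{c + 1}" for c in range(cfg.n_chromosomes)], cfg.genes_per_chromosome)
    start = np.tile(np.arange(cfg.genes_per_chromosome) * 1000 + 1, cfg.n_chromosomes)
    annotation = GeneAnnotation(
        pd.DataFrame({"chromosome": chroms, "start": start}, index=gene_ids)
    )

    r_cg, r_co = _regulatory_multipliers(cfg, genes, rng)
    mu = genes["mu_log2"].to_numpy()
    delta = genes["delta_log2"].to_numpy()
    e_cg_percopy = 2.0 ** (mu - 1.0)           # per-copy expectation, Cg parent scale
    e_co_percopy = 2.0 ** (mu + delta - 1.0)

    samples: list[str] = []
    meta_rows: list[dict] = []
    unphased_cols: dict[str, np.ndarray] = {}
    phased_cg: dict[str, np.ndarray] = {}
    phased_co: dict[str, np.ndarray] = {}
    phased_un: dict[str, np.ndarray] = {}
    copy_cols: dict[str, np.ndarray] = {}
    loss_cols: dict[str, np.ndarray] = {}
    exp_cg_cols: dict[str, np.ndarray] = {}
    exp_co_cols: dict[str, np.ndarray] = {}
    breakpoints: dict[tuple[str, str], list[int]] = {}

    def lib_size(base: float) -> float:
        sigma = np.sqrt(np.log1p(cfg.library_size_cv ** 2))
        return float(base * rng.lognormal(-sigma ** 2 / 2.0, sigma))

    # diploid groups: two copies of a single subgenome
    for group, expect in (("Cg2", 2.0 * e_cg_percopy), ("Co2", 2.0 * e_co_percopy)):
        for line in range(1, cfg.n_lines_per_group + 1):
            sample = f"{group}-{line}"
            lib = lib_size(cfg.library_size_mean)
            mean = expect / expect.sum() * lib
            unphased_cols[sample] = _nb_draw(rng, mean, cfg.nb_dispersion)
            samples.append(sample)
            meta_rows.append({"sample": sample, "group": group, "line": line, "tissue": cfg.tissue})

    # allotetraploid groups: copy-number blocks + regulatory effects + phasing
    block_seed_root = int(rng.integers(0, 2**31 - 1))
    for gi, group in enumerate(TETRAPLOID_GROUPS):
        for line in range(1, cfg.n_lines_per_group + 1):
            sample = f"{group}-{line}"
            ind_seed = (block_seed_root + 7919 * gi + line) % (2**31)
            blocks = simulate_copy_number_blocks(cfg, ind_seed)
            states = np.concatenate([blocks[f"chr{c + 1}"][0] for c in range(cfg.n_chromosomes)])
            if cfg.eld_scenario == "copy_driven":
                # flagged ELD genes carry a consistent 3:1 dosage toward the
                # dominant side in every individual (focal homoeologous
                # exchanges shared by the group); these focal states are part
                # of copy_state truth but not of the block breakpoints
                eld_mask = (genes["class"] == "eld").to_numpy()
                side_arr = genes["eld_side"].to_numpy()
                states = np.where(eld_mask & (side_arr == "cg"), 3, states)
                states = np.where(eld_mask & (side_arr == "co"), 1, states)
            for c in range(cfg.n_chromosomes):
                breakpoints[(sample, f"chr{c + 1}")] = blocks[f"chr{c + 1}"][1]
            exp_cg = e_cg_percopy * states * r_cg
            exp_co = e_co_percopy * (4 - states) * r_co
            lib = lib_size(cfg.library_size_mean * cfg.tetraploid_library_factor)
            total = exp_cg.sum() + exp_co.sum()
            y_cg = _nb_draw(rng, exp_cg / total * lib, cfg.nb_dispersion)
            y_co = _nb_draw(rng, exp_co / total * lib, cfg.nb_dispersion)
            a_cg = rng.binomial(y_cg, cfg.phasing_efficiency)
            a_co = rng.binomial(y_co, cfg.phasing_efficiency)
            unphased_cols[sample] = y_cg + y_co
            phased_cg[sample] = a_cg
            phased_co[sample] = a_co
            phased_un[sample] = (y_cg - a_cg) + (y_co - a_co)
            copy_cols[sample] = states
            loss_cols[sample] = genes["loss_side"].to_numpy()
            exp_cg_cols[sample] = exp_cg
            exp_co_cols[sample] = exp_co
            samples.append(sample)
            meta_rows.append({"sample": sample, "group": group, "line": line, "tissue": cfg.tissue})

    meta = pd.DataFrame(meta_rows).set_index("sample")
    unphased = CountMatrix(
        pd.DataFrame(unphased_cols, index=gene_ids, columns=samples), meta
    )
    tet = [s for s in samples if meta.loc[s, "group"] in TETRAPLOID_GROUPS]
    phased = PhasedCounts(
        pd.DataFrame(phased_cg, index=gene_ids, columns=tet),
        pd.DataFrame(phased_co, index=gene_ids, columns=tet),
        pd.DataFrame(phased_un, index=gene_ids, columns=tet),
        meta.loc[tet],
    )
    truth = SimTruth(
        copy_state=pd.DataFrame(copy_cols, index=gene_ids, columns=tet),
        breakpoints=breakpoints,
        category_truth=genes,
        loss_truth=pd.DataFrame(loss_cols, index=gene_ids, columns=tet),
        expected_cg=pd.DataFrame(exp_cg_cols, index=gene_ids, columns=tet),
        expected_co=pd.DataFrame(exp_co_cols, index=gene_ids, columns=tet),
    )
    return SimulatedDataset(unphased, phased, annotation, truth, cfg)


def simulate_heb_track(
    states: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator,
    medians: tuple[float, ...] = STATE_MEDIANS,
) -> np.ndarray:
    """Emit a homoeolog-expression-bias track directly from copy states.

    Each gene's value is the state's median bias ``m_k`` perturbed by
    logit-normal noise (normal noise with sd ``noise_sd`` on the logit
    scale), which keeps the support inside (0, 1).  ``noise_sd = 0``
    returns the medians exactly.
    """
    states = np.asarray(states)
    if states.min() < 0 or states.max() > 4:
        raise ValueError("states must lie in {0,...,4}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = np.asarray(medians)[states]
    if noise_sd == 0:
        return m.astype(float)
    return expit(logit(m) + rng.normal(0.0, noise_sd, size=states.shape))
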