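"""Homoeolog expression bias (HEB) and copy-number segmentation.

HEB of a gene in an allotetraploid individual is the proportion of the
total homoeolog expression contributed by the cg-homoeolog,
``cg / (cg + co)``.  Along a chromosome, HEB hovers around the value
implied by the local homoeolog copy number: an allotetraploid gene with
``k`` cg copies (and ``4 - k`` co copies) has an expected bias near the
median of state ``k``.  Homoeologous exchange at meiosis creates blocks
of unbalanced copy number (not 2:2) separated by sharp breakpoints.

Segmentation uses a five-state hidden Markov model over the states
{0, 1, 2, 3, 4} (cg copies).  Emissions are Student's-t densities on the
logit scale around the state medians ``m`` (default 0.01, 0.25, 0.5,
0.75, 0.99); the transition matrix starts with self-transition
probability ``e`` and uniform off-diagonal mass, optionally re-estimated
by EM under a Dirichlet prior of weight ``strength`` on the initial
rows.  Decoding is Viterbi in log space, chromosome by chromosome.  Two
presets mirror the biology: resynthesized allotetraploids (one meiosis,
exchanges rare: ``e = 1 - 1e-10``, ``strength = 1e12``) and natural
allotetraploids (``e = 1 - 1e-7``, ``strength = 1e7``), where the output
should be read as candidate segments only, since expression alone cannot
confidently prove copy number in long-established polyploids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit, logsumexp

from .counts_io import GeneAnnotation, PhasedCounts

__all__ = [
    "HEBTrack",
    "HMMParams",
    "CopyNumberSegmentation",
    "compute_heb",
    "hmm_segment",
    "viterbi",
    "breakpoint_stats",
    "variance_explained",
    "RESYNTHESIZED_PRESET",
    "NATURAL_PRESET",
]

N_STATES = 5
_EPS = 1e-3  # nudge for HEB exactly 0 or 1 before logit


@dataclass
class HEBTrack:
    """Ordered per-chromosome HEB values for one individual."""

    individual: str
    chromosome: str
    genes: pd.Index
    heb: np.ndarray
    cg: np.ndarray
    co: np.ndarray
    positions: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.heb)


@dataclass
class HMMParams:
    """Five-state HMM hyperparameters.

    ``m``: expected median HEB of the states (strictly increasing in
    (0,1)); ``e``: initial self-transition probability; ``strength``:
    Dirichlet prior weight on the initial transition rows during EM;
    ``scale``/``df``: Student's-t emission scale and degrees of freedom
    on the logit scale; ``em_iterations = 0`` decodes with the initial
    parameters (deterministic default).
    """

    m: tuple[float, ...] = (0.01, 0.25, 0.5, 0.75, 0.99)
    e: float = 1.0 - 1e-10
    strength: float = 1e12
    scale: float = 0.25
    df: float = 3.0
    em_iterations: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.m)
        if len(m) != N_STATES or not np.all(np.diff(m) > 0) or m[0] <= 0 or m[-1] >= 1:
            raise ValueError("m must be 5 strictly increasing values in (0, 1)")
        if not 0 < self.e < 1:
            raise ValueError("e must lie in (0, 1)")
        if self.strength <= 0 or self.scale <= 0 or self.df <= 0:
            raise ValueError("strength, scale and df must be positive")

    def transition_matrix(self) -> np.ndarray:
        a = np.full((N_STATES, N_STATES), (1.0 - self.e) / (N_STATES - 1))
        np.fill_diagonal(a, self.e)
        return a


RESYNTHESIZED_PRESET = HMMParams(e=1.0 - 1e-10, strength=1e12)
NATURAL_PRESET = HMMParams(e=1.0 - 1e-7, strength=1e7)


@dataclass
class CopyNumberSegmentation:
    """Viterbi path over cg-copy states with its breakpoints."""

    individual: str
    chromosome: str
    genes: pd.Index
    states: np.ndarray
    breakpoints: list[int]
    segment_mean_heb: list[float]
    log_prob: float
    candidate_only: bool = False

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)

    def unbalanced_fraction(self) -> float:
        return float((self.states != 2).mean())


def compute_heb(
    phased: PhasedCounts,
    annotation: GeneAnnotation,
    min_cpm: float = 1.0,
) -> list[HEBTrack]:
    """Build HEB tracks per individual × chromosome.

    Genes whose phased expression (cg + co) has CPM below ``min_cpm`` in
    ANY allotetraploid individual are excluded jointly, so every track
    covers the same gene set; CPM uses each individual's phased library
    size (sum of cg + co).  Genes absent from the annotation are dropped;
    :func:`heb_gene_set` reports how many genes the joint filter removed.
    """
    genes, _ = heb_gene_set(phased, annotation, min_cpm)
    tracks: list[HEBTrack] = []
    table = annotation.table
    for chrom in annotation.chromosomes:
        chrom_genes = [g for g in annotation.genes_on(chrom) if g in genes]
        if not chrom_genes:
            continue
        cg = phased.cg.loc[chrom_genes]
        co = phased.co.loc[chrom_genes]
        pos = table.loc[chrom_genes, "start"].to_numpy()
        for ind in phased.individuals:
            c1 = cg[ind].to_numpy(dtype=float)
            c2 = co[ind].to_numpy(dtype=float)
            tracks.append(
                HEBTrack(
                    individual=ind,
                    chromosome=chrom,
                    genes=pd.Index(chrom_genes, name="gene"),
                    heb=c1 / (c1 + c2),
                    cg=c1,
                    co=c2,
                    positions=pos,
                )
            )
    return tracks


def heb_gene_set(
    phased: PhasedCounts, annotation: GeneAnnotation, min_cpm: float = 1.0
) -> tuple[set, int]:
    """Genes eligible for HEB tracks, and the count of excluded genes."""
    totals = phased.totals()
    lib = totals.sum(axis=0)
    cpm = totals / lib * 1e6
    keep = (cpm >= min_cpm).all(axis=1)
    eligible = set(totals.index[keep])
    annotated = eligible & set(annotation.genes)
    n_excluded = len(totals.index) - len(annotated)
    return annotated, n_excluded


def _log_emissions(heb: np.ndarray, params: HMMParams, scales: np.ndarray | None = None) -> np.ndarray:
    """T × 5 matrix of log emission densities on the logit scale."""
    x = logit(np.clip(heb, _EPS, 1.0 - _EPS))
    loc = logit(np.asarray(params.m))
    s = np.full(N_STATES, params.scale) if scales is None else scales
    return stats.t.logpdf((x[:, None] - loc[None, :]) / s[None, :], params.df) - np.log(s)[None, :]


def viterbi(log_em: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray) -> tuple[np.ndarray, float]:
    """Most probable state path; ties broken toward the lower state index."""
    n, k = log_em.shape
    delta = log_init + log_em[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + log_trans  # prev × next
        back[t] = np.argmax(cand, axis=0)  # first (lowest) argmax on ties
        delta = cand[back[t], np.arange(k)] + log_em[t]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(np.max(delta))


def _forward_backward(log_em, log_trans, log_init):
    n, k = log_em.shape
    alpha = np.zeros((n, k))
    beta = np.zeros((n, k))
    alpha[0] = log_init + log_em[0]
    for t in range(1, n):
        alpha[t] = log_em[t] + logsumexp(alpha[t - 1][:, None] + log_trans, axis=0)
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(log_trans + (log_em[t + 1] + beta[t + 1])[None, :], axis=1)
    loglik = logsumexp(alpha[-1])
    gamma = np.exp(alpha + beta - loglik)
    xi = np.zeros((k, k))
    for t in range(n - 1):
        j = alpha[t][:, None] + log_trans + (log_em[t + 1] + beta[t + 1])[None, :]
        xi += np.exp(j - loglik)
    return gamma, xi, loglik


def hmm_segment(
    track: HEBTrack,
    params: HMMParams = RESYNTHESIZED_PRESET,
    candidate_only: bool = False,
) -> CopyNumberSegmentation:
    """Segment one HEB track into cg copy-number states.

    With ``em_iterations > 0`` the transition rows (under a Dirichlet
    prior of weight ``strength`` on the initial rows) and the per-state
    emission scales are re-estimated before the final Viterbi decode.
    Tracks shorter than 2 genes yield the single best state and no
    breakpoints.
    """
    heb = np.asarray(track.heb, dtype=float)
    log_init = np.full(N_STATES, -np.log(N_STATES))
    trans = params.transition_matrix()
    scales = np.full(N_STATES, params.scale)
    log_em = _log_emissions(heb, params, scales)
    if len(heb) == 1:
        state = int(np.argmax(log_init + log_em[0]))
        return CopyNumberSegmentation(
            track.individual, track.chromosome, track.genes,
            np.array([state]), [], [float(heb[0])],
            float((log_init + log_em[0])[state]), candidate_only,
        )

    prior = params.strength * trans  # Dirichlet pseudo-counts per row
    for _ in range(params.em_iterations):
        with np.errstate(divide="ignore"):
            gamma, xi, _ = _forward_backward(log_em, np.log(trans), log_init)
        rows = xi + prior
        trans = rows / rows.sum(axis=1, keepdims=True)
        x = logit(np.clip(heb, _EPS, 1.0 - _EPS))
        loc = logit(np.asarray(params.m))
        w = gamma.sum(axis=0)
        with np.errstate(invalid="ignore"):
            var = (gamma * (x[:, None] - loc[None, :]) ** 2).sum(axis=0) / np.maximum(w, 1e-12)
        scales = np.where(w > 1e-6, np.sqrt(np.maximum(var, 1e-6)), params.scale)
        log_em = _log_emissions(heb, params, scales)

    with np.errstate(divide="ignore"):
        path, logp = viterbi(log_em, np.log(trans), log_init)
    changes = np.flatnonzero(np.diff(path) != 0) + 1
    bounds = np.concatenate([[0], changes, [len(path)]])
    seg_means = [float(heb[bounds[i]:bounds[i + 1]].mean()) for i in range(len(bounds) - 1)]
    return CopyNumberSegmentation(
        track.individual, track.chromosome, track.genes,
        path, [int(b) for b in changes], seg_means, logp, candidate_only,
    )


def breakpoint_stats(segmentations: list[CopyNumberSegmentation]) -> dict:
    """Summaries over chromosome quartets (one chromosome × one individual).

    Returns per-quartet breakpoint counts, their mean ± standard error,
    the number of quartets with no homoeologous-synapsis signal (zero
    breakpoints and constant state 2), and the fraction of genes whose
    state is not 2 (unbalanced homoeolog content).
    """
    rows = []
    genes_total = 0
    genes_unbalanced = 0
    for seg in segmentations:
        no_signal = seg.n_breakpoints == 0 and bool(np.all(seg.states == 2))
        rows.append(
            {
                "individual": seg.individual,
                "chromosome": seg.chromosome,
                "n_breakpoints": seg.n_breakpoints,
                "no_synapsis_signal": no_signal,
            }
        )
        genes_total += len(seg.states)
        genes_unbalanced += int((seg.states != 2).sum())
    table = pd.DataFrame(rows)
    counts = table["n_breakpoints"].to_numpy(dtype=float)
    mean = float(counts.mean()) if len(counts) else float("nan")
    se = float(counts.std(ddof=1) / np.sqrt(len(counts))) if len(counts) > 1 else float("nan")
    return {
        "per_quartet": table,
        "mean_breakpoints": mean,
        "se_breakpoints": se,
        "n_quartets": len(counts),
        "n_no_signal": int(table["no_synapsis_signal"].sum()) if len(table) else 0,
        "fraction_unbalanced": genes_unbalanced / genes_total if genes_total else float("nan"),
    }


def variance_explained(cg: np.ndarray, total: np.ndarray, states: np.ndarray) -> float:
    """Variance of HEB explained by the inferred copy number.

    Fits a quasi-binomial GLM with logit link of cg reads out of total
    homoeolog reads on the copy-number state (categorical) and returns
    the deviance-based coefficient of determination
    ``1 - residual deviance / null deviance``.  Returns 0 when all
    observations share one state.
    """
    cg = np.asarray(cg, dtype=float)
    total = np.asarray(total, dtype=float)
    states = np.asarray(states)
    ok = total > 0
    cg, total, states = cg[ok], total[ok], states[ok]
    if len(np.unique(states)) < 2:
        return 0.0
    y = cg / total
    exog = pd.get_dummies(pd.Categorical(states), drop_first=True, dtype=float)
    exog = sm.add_constant(exog.to_numpy())
    fam = sm.families.Binomial()
    fit = sm.GLM(y, exog, family=fam, var_weights=total).fit()
    null = sm.GLM(y, np.ones((len(y), 1)), family=fam, var_weights=total).fit()
    if null.deviance <= 0:
        return 0.0
    return float(1.0 - fit.deviance / null.deviance)
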