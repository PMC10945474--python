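"""Count-matrix containers, normalization, filtering and downsampling.

Bulk RNA-seq expression in this package lives in two containers:

* :class:`CountMatrix` — an unphased gene × sample matrix of mapped-read
  counts with per-sample metadata (group, line, tissue).
* :class:`PhasedCounts` — for allotetraploid individuals only, the reads
  that could be assigned to the *C. grandiflora*-derived homoeolog (``cg``),
  the *C. orientalis*-derived homoeolog (``co``), or neither
  (``unassigned``) at every gene.

The module also implements the standard preprocessing steps: counts per
million (CPM), expression filtering, trimmed-mean-of-M-values (TMM)
normalization factors, exact without-replacement downsampling, and the
rescaling of diploid expression by the phasing proportion observed in
allotetraploids (needed whenever phased homoeolog expression is compared
with diploid gene expression on the same scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "PhasedCounts",
    "GeneAnnotation",
    "cpm",
    "filter_expressed",
    "tmm_factors",
    "downsample",
    "rescale_diploid_by_phasing",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_phased_tsv",
    "write_phased_tsv",
    "read_annotation",
    "write_annotation_tsv",
]


@dataclass
class CountMatrix:
    """Gene × sample matrix of non-negative read counts.

    Parameters
    ----------
    counts
        DataFrame with gene ids as index and sample ids as columns.
        Values must be non-negative; they may be real-valued (rescaled
        diploid expression is non-integer by construction).
    sample_meta
        DataFrame indexed by sample id with at least a ``group`` column;
        ``line`` and ``tissue`` are carried through when present.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (np.asarray(self.counts.values) < 0).any():
            raise ValueError("count matrix contains negative entries")
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids are not unique")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.counts.columns)
        missing = self.counts.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")
        self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.sample_meta)

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.sample_meta.loc[list(samples)])

    def samples_in_group(self, group: str) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["group"] == group])


@dataclass
class PhasedCounts:
    """Homoeolog-assigned read counts for allotetraploid individuals.

    ``cg``, ``co`` and ``unassigned`` are aligned gene × individual
    DataFrames.  For simulated data ``cg + co + unassigned`` reconstructs
    the unphased count of the same individual exactly.
    """

    cg: pd.DataFrame
    co: pd.DataFrame
    unassigned: pd.DataFrame
    individual_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("co", "unassigned"):
            other = getattr(self, name)
            if not (other.index.equals(self.cg.index) and other.columns.equals(self.cg.columns)):
                raise ValueError(f"'{name}' table is not aligned with 'cg'")
        for name in ("cg", "co", "unassigned"):
            if (np.asarray(getattr(self, name).values) < 0).any():
                raise ValueError(f"negative entries in '{name}' counts")
        if self.individual_meta is None:
            self.individual_meta = pd.DataFrame(index=self.cg.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.cg.index

    @property
    def individuals(self) -> pd.Index:
        return self.cg.columns

    def totals(self) -> pd.DataFrame:
        """Phased total per gene and individual (cg + co)."""
        return self.cg + self.co

    def unphased(self) -> pd.DataFrame:
        return self.cg + self.co + self.unassigned

    def phasing_proportion(self) -> pd.Series:
        """Per-gene proportion of reads assigned to either homoeolog,
        pooled over individuals; NaN where no reads were observed."""
        assigned = (self.cg + self.co).sum(axis=1)
        total = assigned + self.unassigned.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return assigned / total

    def subset_individuals(self, individuals) -> "PhasedCounts":
        idx = list(individuals)
        return PhasedCounts(
            self.cg[idx], self.co[idx], self.unassigned[idx], self.individual_meta.loc[idx]
        )

    def subset_genes(self, genes) -> "PhasedCounts":
        return PhasedCounts(
            self.cg.loc[genes], self.co.loc[genes], self.unassigned.loc[genes],
            self.individual_meta,
        )

    def individuals_in_group(self, group: str) -> list[str]:
        meta = self.individual_meta
        return list(meta.index[meta["group"] == group])


class GeneAnnotation:
    """Gene coordinates used to order genes along chromosomes.

    Stores, per gene: chromosome id, 1-based start coordinate and the
    within-chromosome order index (rank of the start position, ties broken
    by gene id).
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"chromosome", "start"}
        if not required.issubset(table.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        table = table.copy()
        table = table.sort_values(["chromosome", "start"], kind="mergesort")
        # mergesort on a frame pre-sorted by index breaks start ties by gene id
        table = (
            table.reset_index()
            .rename(columns={table.index.name or "index": "gene"})
            .sort_values(["chromosome", "start", "gene"], kind="mergesort")
            .set_index("gene")
        )
        table["order"] = table.groupby("chromosome").cumcount()
        self.table = table

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.table["chromosome"].unique())

    def genes_on(self, chromosome: str) -> pd.Index:
        sub = self.table[self.table["chromosome"] == chromosome]
        return sub.sort_values("order").index


def cpm(counts: pd.DataFrame | CountMatrix, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million mapped reads.

    ``library_sizes`` defaults to the column sums; pass effective library
    sizes (library × TMM factor) for normalized CPM.  A zero library size
    is an error naming the offending sample.
    """
    frame = counts.counts if isinstance(counts, CountMatrix) else counts
    if library_sizes is None:
        library_sizes = frame.sum(axis=0)
    library_sizes = library_sizes.reindex(frame.columns)
    bad = library_sizes.index[(library_sizes <= 0) | library_sizes.isna()]
    if len(bad):
        raise ValueError(f"zero or undefined library size for sample(s): {list(bad)}")
    return frame / library_sizes * 1e6


def filter_expressed(
    counts: CountMatrix | pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    library_sizes: pd.Series | None = None,
) -> pd.Index:
    """Genes with CPM strictly above ``min_cpm`` in at least ``min_samples`` samples."""
    if min_cpm < 0 or min_samples < 0:
        raise ValueError("thresholds must be non-negative")
    values = cpm(counts, library_sizes)
    keep = (values > min_cpm).sum(axis=1) >= min_samples
    return values.index[keep]


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference column."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    p_o, p_r = obs / n_obs, ref / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # delta-method variance of M; precision (1/v) weights the trimmed mean
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank(method="average").to_numpy()
    rank_a = pd.Series(a).rank(method="average").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or (1.0 / v[keep]).sum() == 0:
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample, M-values (log2 expression ratios against a reference
    sample) are trimmed symmetrically (30 % on M, 5 % on A by default),
    averaged with precision weights and exponentiated.  The reference is
    the sample whose upper-quartile expression is closest to the mean
    upper quartile, unless given.  Factors are rescaled so their geometric
    mean is 1.  Genes with a zero count in either member of a pair are
    excluded from that pair's trimmed mean.
    """
    frame = counts.counts if isinstance(counts, CountMatrix) else counts
    if frame.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = frame.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = frame.columns[lib <= 0]
        raise ValueError(f"all-zero sample(s): {list(bad)}")
    values = frame.to_numpy(dtype=float)
    if reference_sample is None:
        q75 = np.array([np.quantile(values[:, j] / lib[j], 0.75) for j in range(values.shape[1])])
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = frame.columns.get_loc(reference_sample)
    ref = values[:, ref_idx]
    factors = np.array([
        1.0 if j == ref_idx else _tmm_pair(values[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(values.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=frame.columns, name="tmm_factor")


def downsample(
    counts: CountMatrix,
    target_depth: int,
    seed: int | np.random.Generator,
) -> CountMatrix:
    """Downsample every sample to exactly ``target_depth`` reads without replacement.

    Each column is thinned by a multivariate hypergeometric draw, so the
    column sum equals the target exactly and every mapped read is equally
    likely to be kept.  Samples already at or below the target are left
    unchanged (with a warning when below).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = counts.counts.copy()
    for sample in out.columns:
        col = out[sample].to_numpy()
        depth = int(col.sum())
        if depth < target_depth:
            logger.warning(
                "sample %s has depth %d < target %d; left unchanged", sample, depth, target_depth
            )
            continue
        if depth == target_depth:
            continue
        out[sample] = rng.multivariate_hypergeometric(col.astype(np.int64), target_depth)
    return CountMatrix(out, counts.sample_meta)


def rescale_diploid_by_phasing(
    diploid: CountMatrix,
    phased: PhasedCounts,
) -> CountMatrix:
    """Rescale diploid expression by the allotetraploid phasing proportion.

    Phased homoeolog counts only contain the reads carrying a diagnostic
    variant, so before comparing them with diploid gene expression each
    diploid count is multiplied by the per-gene proportion of reads that
    could be phased, pooled across the supplied allotetraploid
    individuals.  Genes never covered in the allotetraploids fall back to
    the mean phasing proportion.  The result is real-valued.
    """
    shared = diploid.gene_ids.intersection(phased.gene_ids)
    prop = phased.subset_genes(shared).phasing_proportion()
    prop = prop.fillna(prop.mean())
    scaled = diploid.counts.loc[shared].mul(prop, axis=0)
    return CountMatrix(scaled, diploid.sample_meta)


# --------------------------------------------------------------------------
# plain-text IO (TSV / GFF3)

def write_counts_tsv(counts: CountMatrix, path, meta_path=None) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="gene")
    if meta_path is not None:
        counts.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_counts_tsv(path, meta_path=None) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path is not None else None
    return CountMatrix(frame, meta)


def write_phased_tsv(phased: PhasedCounts, path) -> None:
    """Long-format TSV: gene, individual, cg, co, unassigned."""
    long = pd.concat(
        {
            "cg": phased.cg.stack(),
            "co": phased.co.stack(),
            "unassigned": phased.unassigned.stack(),
        },
        axis=1,
    )
    long.index.names = ["gene", "individual"]
    long.reset_index().to_csv(path, sep="\t", index=False)


def read_phased_tsv(path, individual_meta: pd.DataFrame | None = None) -> PhasedCounts:
    long = pd.read_csv(path, sep="\t")
    tables = {
        key: long.pivot(index="gene", columns="individual", values=key)
        for key in ("cg", "co", "unassigned")
    }
    return PhasedCounts(
        tables["cg"], tables["co"], tables["unassigned"], individual_meta
    )


def write_annotation_tsv(annotation: GeneAnnotation, path) -> None:
    annotation.table[["chromosome", "start"]].to_csv(path, sep="\t", index_label="gene")


def _read_annotation_gff3(path) -> pd.DataFrame:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    raw = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    genes = raw[raw["type"] == "gene"].copy()
    genes["gene"] = genes["attributes"].str.extract(r"ID=([^;]+)")
    if genes["gene"].isna().any():
        raise ValueError("GFF3 gene features without an ID attribute")
    return genes.rename(columns={"seqid": "chromosome"})[["gene", "chromosome", "start"]]


def read_annotation(path) -> GeneAnnotation:
    """Read gene coordinates from GFF3 (``gene`` features, ID attribute)
    or a 3-column TSV (gene, chromosome, start)."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        table = _read_annotation_gff3(path)
    else:
        table = pd.read_csv(path, sep="\t")
        table.columns = ["gene", "chromosome", "start"] + list(table.columns[3:])
    return GeneAnnotation(table.set_index("gene")[["chromosome", "start"]])
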