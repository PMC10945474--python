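"""Containers, CPM/TMM normalization, filtering, downsampling, rescaling, IO."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from homeobias import (
    CountMatrix,
    GeneAnnotation,
    PhasedCounts,
    cpm,
    downsample,
    filter_expressed,
    rescale_diploid_by_phasing,
    tmm_factors,
)
from homeobias.counts_io import (
    read_annotation,
    read_counts_tsv,
    read_phased_tsv,
    write_counts_tsv,
    write_phased_tsv,
)

from conftest import toy_count_matrix


class TestCpm:
    def test_closed_form(self):
        cm = toy_count_matrix([[5], [5]])
        assert cpm(cm).iloc[0, 0] == pytest.approx(5 / 10 * 1e6)

    def test_zero_count_and_unit_cpm(self):
        frame = pd.DataFrame({"s": [0, 1, 10**6 - 1]})
        values = cpm(frame)
        assert values.loc[0, "s"] == 0.0
        assert values.loc[1, "s"] == pytest.approx(1.0)

    def test_zero_library_names_sample(self):
        frame = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            cpm(frame)

    def test_round_trip_recovers_counts(self, rng):
        frame = pd.DataFrame(rng.poisson(50.0, size=(30, 4)))
        lib = frame.sum(axis=0)
        back = cpm(frame) * lib / 1e6
        np.testing.assert_allclose(back.to_numpy(), frame.to_numpy(), atol=1e-9)


class TestFilterExpressed:
    def test_single_high_sample_dropped(self):
        # CPM (1.5, 0, 0) with min_samples=2 -> dropped
        frame = pd.DataFrame(
            [[15, 0, 0], [15, 20, 0], [10**5] * 3],
            index=["lonely", "kept", "filler"],
        )
        keep = filter_expressed(frame, min_cpm=1.0, min_samples=2)
        values = cpm(frame)
        assert "kept" in keep and "lonely" not in keep
        assert (values.loc["kept"] > 1).sum() >= 2

    def test_zero_thresholds_keep_everything(self, rng):
        frame = pd.DataFrame(rng.poisson(5.0, size=(20, 3)) + 1)
        keep = filter_expressed(frame, min_cpm=0.0, min_samples=0)
        assert len(keep) == 20

    def test_threshold_is_strict(self):
        # a gene at exactly min_cpm in every sample is not "above" it
        frame = pd.DataFrame({"a": [1, 10**6 - 1], "b": [1, 10**6 - 1]})
        keep = filter_expressed(frame, min_cpm=1.0, min_samples=1)
        assert 0 not in keep


class TestTmm:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.poisson(40.0, size=100)
        frame = pd.DataFrame({"a": col, "b": col, "c": col})
        f = tmm_factors(frame)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-8)

    def test_geometric_mean_is_one(self, rng):
        frame = pd.DataFrame(rng.poisson(30.0, size=(200, 5)) + 1)
        frame.iloc[:40, 2] *= 4
        f = tmm_factors(frame)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-8)

    def test_pure_depth_difference_gives_unit_factors(self, rng):
        # doubling every count is a depth change, not composition: factors stay 1
        col = rng.poisson(60.0, size=150) + 1
        frame = pd.DataFrame({"a": col, "b": 2 * col})
        f = tmm_factors(frame)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-6)

    def test_gene_order_invariance(self, rng):
        frame = pd.DataFrame(rng.poisson(30.0, size=(300, 4)) + 1)
        frame.iloc[:60, 1] *= 3
        perm = rng.permutation(300)
        f1 = tmm_factors(frame)
        f2 = tmm_factors(frame.iloc[perm])
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-12)

    def test_all_zero_sample_errors(self):
        frame = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(frame)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
    def test_matches_edger_reference(self, rng, tmp_path):
        """Independent cross-check against Bioconductor edgeR on a toy matrix."""
        y = rng.negative_binomial(5, 0.05, size=(200, 4)).astype(int)
        y[:50, 1] *= 3
        path = tmp_path / "m.tsv"
        pd.DataFrame(y).to_csv(path, sep="\t", index=False)
        script = (
            "suppressMessages(library(edgeR));"
            f"y<-as.matrix(read.delim('{path}'));"
            "cat(calcNormFactors(y, method='TMM'), sep='\\n')"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        reference = np.array([float(x) for x in proc.stdout.split()])
        ours = tmm_factors(pd.DataFrame(y)).to_numpy()
        np.testing.assert_allclose(ours, reference, rtol=1e-4)


class TestDownsample:
    def test_identity_at_current_depth(self, rng):
        counts = rng.poisson(20.0, size=(50, 1))
        cm = toy_count_matrix(counts)
        out = downsample(cm, int(counts.sum()), 0)
        pd.testing.assert_frame_equal(out.counts, cm.counts)

    def test_exact_target_and_expectation(self, rng):
        counts = rng.poisson(100.0, size=(200, 1))
        cm = toy_count_matrix(counts)
        depth = int(counts.sum())
        target = depth // 2
        out = downsample(cm, target, 1)
        assert int(out.counts.sum().iloc[0]) == target
        # hypergeometric expectation: roughly half of each gene
        ratio = out.counts.to_numpy().sum() / counts.sum()
        assert ratio == pytest.approx(0.5, abs=1e-9)

    def test_seeded_rerun_identical(self, rng):
        cm = toy_count_matrix(rng.poisson(50.0, size=(100, 3)))
        a = downsample(cm, 2000, 42)
        b = downsample(cm, 2000, 42)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_low_sample_left_unchanged_with_warning(self, caplog):
        cm = toy_count_matrix([[5], [5]])
        with caplog.at_level("WARNING"):
            out = downsample(cm, 100, 0)
        assert out.counts.equals(cm.counts)
        assert any("left unchanged" in r.message for r in caplog.records)


class TestRescaleDiploid:
    def _phased(self, cg, co, un):
        idx = pd.Index([f"g{i}" for i in range(len(cg))], name="gene")
        mk = lambda v: pd.DataFrame({"t1": v}, index=idx)
        return PhasedCounts(mk(cg), mk(co), mk(un))

    def test_half_phasing_halves_counts(self):
        phased = self._phased([25], [25], [50])
        dip = CountMatrix(pd.DataFrame({"d1": [100]}, index=pd.Index(["g0"], name="gene")))
        out = rescale_diploid_by_phasing(dip, phased)
        assert out.counts.loc["g0", "d1"] == pytest.approx(50.0)

    def test_full_phasing_is_identity(self):
        phased = self._phased([30, 10], [10, 30], [0, 0])
        dip = CountMatrix(
            pd.DataFrame({"d1": [7, 9]}, index=pd.Index(["g0", "g1"], name="gene"))
        )
        out = rescale_diploid_by_phasing(dip, phased)
        np.testing.assert_allclose(out.counts["d1"], [7.0, 9.0])

    def test_more_unassigned_never_increases(self):
        dip = CountMatrix(pd.DataFrame({"d1": [100]}, index=pd.Index(["g0"], name="gene")))
        values = []
        for un in (0, 10, 50, 500):
            out = rescale_diploid_by_phasing(dip, self._phased([20], [20], [un]))
            values.append(out.counts.loc["g0", "d1"])
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestIO:
    def test_counts_round_trip(self, small_dataset, tmp_path):
        write_counts_tsv(small_dataset.unphased, tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = read_counts_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(
            back.counts, small_dataset.unphased.counts, check_dtype=False
        )
        assert list(back.sample_meta["group"]) == list(
            small_dataset.unphased.sample_meta["group"]
        )

    def test_phased_round_trip(self, small_dataset, tmp_path):
        write_phased_tsv(small_dataset.phased, tmp_path / "p.tsv")
        back = read_phased_tsv(tmp_path / "p.tsv")
        for name in ("cg", "co", "unassigned"):
            ours = getattr(small_dataset.phased, name)
            theirs = getattr(back, name).loc[ours.index, ours.columns]
            np.testing.assert_array_equal(theirs.to_numpy(), ours.to_numpy())

    def test_gff3_and_tsv_annotation(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t500\t900\t.\t+\t.\tID=gB;Name=x\n"
            "chr1\tsrc\tmRNA\t500\t900\t.\t+\t.\tID=gB.1;Parent=gB\n"
            "chr1\tsrc\tgene\t100\t400\t.\t-\t.\tID=gA\n"
            "chr2\tsrc\tgene\t100\t300\t.\t+\t.\tID=gC\n"
        )
        ann = read_annotation(gff)
        assert list(ann.genes_on("chr1")) == ["gA", "gB"]
        assert ann.table.loc["gA", "order"] == 0
        tsv = tmp_path / "a.tsv"
        tsv.write_text("gene\tchromosome\tstart\ngA\tchr1\t100\ngB\tchr1\t500\n")
        ann2 = read_annotation(tsv)
        assert list(ann2.genes_on("chr1")) == ["gA", "gB"]

    def test_annotation_tie_broken_by_gene_id(self):
        table = pd.DataFrame(
            {"chromosome": ["c", "c"], "start": [100, 100]},
            index=pd.Index(["zzz", "aaa"], name="gene"),
        )
        ann = GeneAnnotation(table)
        assert list(ann.genes_on("c")) == ["aaa", "zzz"]


class TestContainers:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(pd.DataFrame({"s": [-1]}))

    def test_duplicate_gene_ids_rejected(self):
        frame = pd.DataFrame({"s": [1, 2]}, index=["g", "g"])
        with pytest.raises(ValueError):
            CountMatrix(frame)

    def test_phased_alignment_enforced(self):
        a = pd.DataFrame({"t": [1]}, index=["g0"])
        b = pd.DataFrame({"t": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            PhasedCounts(a, b, a)
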