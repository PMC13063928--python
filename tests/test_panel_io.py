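import numpy as np
import pandas as pd
import pytest

from gardscan.io import (read_cohort, read_covariates, read_enhancer_bed,
                         read_gene_bed, read_gmt, read_ontology_edges,
                         read_results, write_results)
from gardscan.panel import CohortPanel
from gardscan.simulate import SimConfig, simulate_cohort, write_cohort_files


@pytest.fixture(scope="module")
def cohort_dir(tmp_path_factory):
    cfg = SimConfig(n_cases=80, n_controls=80, n_snps=30, n_genes=6,
                    n_causal_genes=1, seed=13)
    out = simulate_cohort(cfg)
    d = tmp_path_factory.mktemp("cohort")
    write_cohort_files(*out, d)
    return d, out


def _write_vcf(path, samples, rows):
    header = ["##fileformat=VCFv4.2",
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
              '##FORMAT=<ID=DS,Number=1,Type=Float,Description="d">',
              '##INFO=<ID=R2,Number=1,Type=Float,Description="r">',
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(samples)]
    path.write_text("\n".join(header + rows) + "\n")


def _write_covars(path, ids):
    rows = ["id\tstatus\tsex\tage\tsmoking\tpc1\tpc2\tpc3\tpc4"]
    for i, s in enumerate(ids):
        status = "case" if i % 2 == 0 else "control"
        rows.append(f"{s}\t{status}\tmale\t60\tnever\t0\t0\t0\t0")
    path.write_text("\n".join(rows) + "\n")


class TestReadCohort:
    def test_gt_dosages_are_allele_counts(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        _write_vcf(vcf, ["s1", "s2", "s3"],
                   ["1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1"])
        cov = tmp_path / "c.tsv"
        _write_covars(cov, ["s1", "s2", "s3"])
        panel = read_cohort(vcf, cov)
        np.testing.assert_array_equal(panel.dosage[:, 0], [0, 1, 2])

    def test_ds_wins_over_gt(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        _write_vcf(vcf, ["s1"],
                   ["1\t100\trs1\tA\tG\t.\tPASS\t.\tGT:DS\t0/1:0.73"])
        cov = tmp_path / "c.tsv"
        _write_covars(cov, ["s1", "s2"])
        panel = read_cohort(vcf, cov)
        assert panel.dosage[0, 0] == pytest.approx(0.73)

    def test_sample_intersection(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        _write_vcf(vcf, ["s1", "s9"],
                   ["1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1"])
        cov = tmp_path / "c.tsv"
        _write_covars(cov, ["s1", "s2"])
        panel = read_cohort(vcf, cov)
        assert list(panel.samples["id"]) == ["s1"]

    def test_no_overlap_fatal(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        _write_vcf(vcf, ["sA"],
                   ["1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1"])
        cov = tmp_path / "c.tsv"
        _write_covars(cov, ["s1"])
        with pytest.raises(ValueError, match="overlap"):
            read_cohort(vcf, cov)

    def test_multiallelic_split(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        _write_vcf(vcf, ["s1", "s2"],
                   ["1\t100\trs1\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2"])
        cov = tmp_path / "c.tsv"
        _write_covars(cov, ["s1", "s2"])
        panel = read_cohort(vcf, cov)
        assert panel.n_variants == 2
        np.testing.assert_array_equal(panel.dosage[:, 0], [1, 1])  # alt G
        np.testing.assert_array_equal(panel.dosage[:, 1], [0, 1])  # alt T

    def test_r2_info_marks_imputed(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        _write_vcf(vcf, ["s1"],
                   ["1\t100\trs1\tA\tG\t.\tPASS\tR2=0.91\tGT:DS\t0/1:1.1"])
        cov = tmp_path / "c.tsv"
        _write_covars(cov, ["s1"])
        panel = read_cohort(vcf, cov)
        assert panel.variants["source"].iloc[0] == "imputed"
        assert panel.variants["impute_r2"].iloc[0] == pytest.approx(0.91)

    def test_gt_equals_exact_ds_encoding(self, tmp_path):
        """A VCF with only GT gives the same panel as the same variants
        re-encoded with exact DS values."""
        samples = ["s1", "s2", "s3", "s4"]
        gt_row = "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1"
        ds_row = ("1\t100\trs1\tA\tG\t.\tPASS\t.\tGT:DS\t"
                  "0/0:0\t0/1:1\t1/1:2\t0/1:1")
        cov = tmp_path / "c.tsv"
        _write_covars(cov, samples)
        va = tmp_path / "a.vcf"
        _write_vcf(va, samples, [gt_row])
        vb = tmp_path / "b.vcf"
        _write_vcf(vb, samples, [ds_row])
        pa = read_cohort(va, cov)
        pb = read_cohort(vb, cov)
        np.testing.assert_array_equal(pa.dosage, pb.dosage)


class TestRoundTrip:
    def test_simulated_files_reread_lossless(self, cohort_dir):
        d, (panel, genes, enhancers, catalog, truth) = cohort_dir
        panel2 = read_cohort(d / "cohort.vcf", d / "covariates.tsv")
        assert panel2.n_samples == panel.n_samples
        assert panel2.n_variants == panel.n_variants
        assert list(panel2.variants["id"]) == list(panel.variants["id"])
        # dosages round-trip at the VCF's printed precision (4 decimals)
        a = np.nan_to_num(panel.dosage, nan=-1)
        b = np.nan_to_num(panel2.dosage, nan=-1)
        np.testing.assert_allclose(b, a, atol=5e-5)
        genes2 = read_gene_bed(d / "genes.bed")
        assert [(g.symbol, g.start, g.end) for g in genes2] == \
            [(r.symbol, r.start, r.end) for r in genes.itertuples()]
        enh2 = read_enhancer_bed(d / "enhancers.bed")
        assert len(enh2) == len(enhancers)
        catalog2 = read_gmt(d / "terms.gmt")
        assert {t: set(m) for t, (_, m) in catalog2.items()} == \
            {t: set(m) for t, (_, m) in catalog.items()}

    def test_source_flags_round_trip(self, cohort_dir):
        d, (panel, *_ ) = cohort_dir
        panel2 = read_cohort(d / "cohort.vcf", d / "covariates.tsv")
        assert list(panel2.variants["source"]) == \
            list(panel.variants["source"])


class TestWriteResults:
    def test_scientific_notation_and_roundtrip(self, tmp_path):
        t = pd.DataFrame({"gene": ["g1"], "p": [1.2e-10]})
        out = tmp_path / "r.tsv"
        write_results(t, out)
        text = out.read_text()
        assert "1.20000e-10" in text
        back = read_results(out)
        assert back["p"].iloc[0] == pytest.approx(1.2e-10)

    def test_single_row_has_header(self, tmp_path):
        out = tmp_path / "r.tsv"
        write_results(pd.DataFrame({"a": [1]}), out)
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 2 and lines[0] == "a"

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_results(pd.DataFrame({"a": []}), tmp_path / "r.tsv")

    def test_value_roundtrip_at_printed_precision(self, tmp_path, rng):
        t = pd.DataFrame({"unit": list("abcde"),
                          "p_adjusted": rng.uniform(size=5) * 1e-3})
        out = tmp_path / "r.tsv"
        write_results(t, out)
        back = read_results(out)
        np.testing.assert_allclose(back["p_adjusted"], t["p_adjusted"],
                                   rtol=1e-5)


class TestPanelInvariants:
    def _samples(self, n):
        return pd.DataFrame({
            "id": [f"s{i}" for i in range(n)], "status": "case",
            "sex": "male", "age": 60.0, "smoking": "never",
            "pc1": 0.0, "pc2": 0.0, "pc3": 0.0, "pc4": 0.0})

    def _variants(self, ids):
        return pd.DataFrame({"id": ids, "chrom": "1",
                             "pos": range(1, len(ids) + 1),
                             "ref": "A", "alt": "G", "source": "genotyped"})

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CohortPanel(self._variants(["v1"]), self._samples(3),
                        np.zeros((3, 2)))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CohortPanel(self._variants(["v1", "v1"]), self._samples(2),
                        np.zeros((2, 2)))

    def test_dosage_range_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            CohortPanel(self._variants(["v1"]), self._samples(2),
                        np.array([[0.5], [2.5]]))

    def test_bad_covariates_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\tstatus\tsex\tage\tsmoking\tpc1\tpc2\tpc3\tpc4\n"
                     "s1\tWRONG\tmale\t60\tnever\t0\t0\t0\t0\n")
        with pytest.raises(ValueError, match="status"):
            read_covariates(p)


class TestSmallReaders:
    def test_ontology_edges(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("# child parent\nA\tB\nB\troot\n")
        assert read_ontology_edges(p) == [("A", "B"), ("B", "root")]

    def test_gmt_short_line_fatal(self, tmp_path):
        p = tmp_path / "t.gmt"
        p.write_text("T1\tname only\n")
        with pytest.raises(ValueError):
            read_gmt(p)
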