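import logging

import numpy as np
import pandas as pd
import pytest

import pathburden.variant_model as vm

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""


def _vcf(tmp_path, body, header=VCF_HEADER, name="x.vcf"):
    p = tmp_path / name
    p.write_text(header + body)
    return p


class TestReadVcf:
    def test_biallelic_site_yields_one_record_per_sample_genotypes(self, tmp_path):
        path = _vcf(tmp_path,
                    "1\t100\t.\tA\tC\t99\tPASS\tMQ=60\tGT:DP\t0/1:20\t0/0:15\t1/1:30\n")
        t = vm.read_vcf(path)
        assert len(t) == 1 and t.samples == ["s1", "s2", "s3"]
        assert list(t.genotypes[0]) == [vm.GT_HET, vm.GT_HOMREF, vm.GT_HOMALT]
        assert list(t.depths[0]) == [20, 15, 30]
        assert t.records.loc[0, "site_qual"] == 99
        assert t.records.loc[0, "mapping_quality"] == 60

    def test_triallelic_site_splits_into_two_records(self, tmp_path):
        path = _vcf(tmp_path,
                    "1\t200\t.\tG\tA,T\t50\tPASS\tMQ=45\tGT:DP\t0/1:10\t0/2:12\t0/0:8\n")
        t = vm.read_vcf(path)
        assert len(t) == 2
        assert set(t.records["alt"]) == {"A", "T"}
        assert (t.records["chrom"] == "1").all()
        assert (t.records["pos"] == 200).all()
        assert (t.records["ref"] == "G").all()
        # per-alt genotypes: s1 carries A only, s2 carries T only
        by_alt = {t.records.loc[i, "alt"]: t.genotypes[i] for i in range(2)}
        assert list(by_alt["A"]) == [vm.GT_HET, vm.GT_HOMREF, vm.GT_HOMREF]
        assert list(by_alt["T"]) == [vm.GT_HOMREF, vm.GT_HET, vm.GT_HOMREF]

    def test_multiallelic_split_conserves_alt_carrier_count(self, tmp_path):
        path = _vcf(tmp_path,
                    "1\t200\t.\tG\tA,T\t50\tPASS\tMQ=45\tGT:DP\t0/1:10\t0/2:12\t0/0:8\n")
        t = vm.read_vcf(path)
        per_record = (t.genotypes >= vm.GT_HET).sum()
        carries_any = (t.genotypes >= vm.GT_HET).any(axis=0).sum()
        assert per_record == carries_any == 2

    def test_missing_dp_recorded_as_missing_with_warning(self, tmp_path, caplog):
        header = VCF_HEADER.replace(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n', "")
        path = _vcf(tmp_path, "1\t100\t.\tA\tC\t99\tPASS\tMQ=60\tGT\t0/1\t0/0\t./.\n",
                    header=header)
        with caplog.at_level(logging.WARNING, logger="pathburden"):
            t = vm.read_vcf(path)
        assert (t.depths == vm.DP_MISSING).all()
        assert t.genotypes[0, 2] == vm.GT_MISSING
        assert any("DP" in rec.message for rec in caplog.records)

    def test_vcf_without_gt_is_a_format_error(self, tmp_path):
        header = VCF_HEADER.replace(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n', "")
        path = _vcf(tmp_path, "1\t100\t.\tA\tC\t99\tPASS\tMQ=60\tDP\t20\t15\t30\n",
                    header=header)
        with pytest.raises(vm.VcfFormatError, match="GT"):
            vm.read_vcf(path)

    def test_write_read_round_trip(self, tmp_path):
        path = _vcf(
            tmp_path,
            "1\t100\t.\tA\tC\t99\tPASS\tMQ=60\tGT:DP\t0/1:20\t0/0:15\t1/1:30\n"
            "1\t300\t.\tT\tG\t42.5\tPASS\tMQ=33.5\tGT:DP\t./.:.\t0/1:7\t0/0:9\n",
        )
        t1 = vm.read_vcf(path)
        out = tmp_path / "rt.vcf"
        vm.write_vcf(t1, out)
        t2 = vm.read_vcf(out)
        assert np.array_equal(t1.genotypes, t2.genotypes)
        assert np.array_equal(t1.depths, t2.depths)
        assert np.allclose(t1.records["site_qual"], t2.records["site_qual"])
        assert np.allclose(t1.records["mapping_quality"],
                           t2.records["mapping_quality"], atol=1e-5)


ANN_HEADER = ("chrom\tpos\tref\talt\tgene\tregion\tconsequence\t"
              "maf_1000g_all\tmaf_esp6500\tmaf_gnomad_all\tmaf_gnomad_eas\t"
              "sift_call\tpolyphen_call\tmutationtaster_call\tcadd_phred\t"
              "dbscsnv_splice_relevant\tin_repeat_region\tsplice_distance_bp\n")


def _ann(tmp_path, rows, header=ANN_HEADER):
    p = tmp_path / "ann.tsv"
    p.write_text(header + "".join(r + "\n" for r in rows))
    return p


class TestReadAnnotations:
    def test_dot_means_missing_maf(self, tmp_path):
        path = _ann(tmp_path, [
            "1\t100\tA\tC\tLCT\texonic\tnonsynonymous SNV\t.\t0.002\t.\t.\t"
            "deleterious\ttolerated\t.\t25.1\t.\tfalse\t."])
        df = vm.read_annotations(path)
        assert np.isnan(df.loc[0, "maf_1000g_all"])
        assert df.loc[0, "maf_esp6500"] == 0.002
        assert df.loc[0, "mutationtaster_call"] is pd.NA
        assert df.loc[0, "gene"] == "LCT"
        assert df.loc[0, "indel_length"] == 0

    def test_combined_region_class_parses(self, tmp_path):
        path = _ann(tmp_path, [
            "1\t1\tA\tC\tG1\texonic;splicing\tnonsynonymous SNV\t.\t.\t.\t.\t"
            ".\t.\t.\t.\t.\tfalse\t2"])
        df = vm.read_annotations(path)
        assert df.loc[0, "region"] == "exonic;splicing"
        assert df.loc[0, "splice_distance_bp"] == 2

    def test_missing_gene_column_is_a_format_error(self, tmp_path):
        header = ANN_HEADER.replace("\tgene", "\tsymbol")
        path = _ann(tmp_path, [], header=header)
        with pytest.raises(vm.AnnotationFormatError, match="gene"):
            vm.read_annotations(path)

    def test_unparseable_maf_becomes_missing_with_warning(self, tmp_path, caplog):
        path = _ann(tmp_path, [
            "1\t1\tA\tC\tG1\texonic\tnonsynonymous SNV\toops\t.\t.\t.\t"
            ".\t.\t.\t.\t.\tfalse\t."])
        with caplog.at_level(logging.WARNING, logger="pathburden"):
            df = vm.read_annotations(path)
        assert np.isnan(df.loc[0, "maf_1000g_all"])
        assert any("unparseable" in r.message for r in caplog.records)

    def test_maf_outside_unit_interval_rejected(self, tmp_path):
        path = _ann(tmp_path, [
            "1\t1\tA\tC\tG1\texonic\tnonsynonymous SNV\t1.5\t.\t.\t.\t"
            ".\t.\t.\t.\t.\tfalse\t."])
        with pytest.raises(vm.AnnotationFormatError, match=r"\[0,1\]"):
            vm.read_annotations(path)

    def test_indel_length_follows_vcf_allele_convention(self, tmp_path):
        path = _ann(tmp_path, [
            "1\t1\tATTTT\tA\tG1\texonic\tnonframeshift indel\t.\t.\t.\t.\t"
            ".\t.\t.\t.\t.\ttrue\t."])
        df = vm.read_annotations(path)
        assert df.loc[0, "indel_length"] == 4
        assert df.loc[0, "in_repeat_region"] is np.True_ or df.loc[0, "in_repeat_region"] == True  # noqa: E712


class TestJoinCohort:
    def _variants(self, tmp_path, n=5):
        body = "".join(
            f"1\t{100 + i}\t.\tA\tC\t99\tPASS\tMQ=60\tGT:DP\t0/1:20\t0/0:15\t0/0:9\n"
            for i in range(n)
        )
        return vm.read_vcf(_vcf(tmp_path, body))

    def _annotations(self, tmp_path, n=5):
        rows = [
            f"1\t{100 + i}\tA\tC\tG{i}\texonic\tnonsynonymous SNV\t.\t.\t.\t.\t"
            "deleterious\tdeleterious\tdeleterious\t30\t.\tfalse\t."
            for i in range(n)
        ]
        return vm.read_annotations(_ann(tmp_path, rows))

    def _groups(self):
        return pd.DataFrame({"sample_id": ["s1", "s2", "s3"],
                             "group": ["case", "case", "control"]})

    def test_full_match_joins_everything(self, tmp_path):
        table, unmatched = vm.join_cohort(
            self._variants(tmp_path), self._annotations(tmp_path), self._groups())
        assert len(table) == 5 and unmatched == 0
        assert table.n_in_group("case") == 2

    def test_drop_policy_reports_unmatched_count(self, tmp_path):
        table, unmatched = vm.join_cohort(
            self._variants(tmp_path, n=5), self._annotations(tmp_path, n=4),
            self._groups(), unmatched="drop")
        assert len(table) == 4 and unmatched == 1

    def test_error_policy_raises_on_unmatched(self, tmp_path):
        with pytest.raises(vm.CohortJoinError, match="without annotation"):
            vm.join_cohort(self._variants(tmp_path, n=5),
                           self._annotations(tmp_path, n=4),
                           self._groups(), unmatched="error")

    def test_sample_missing_from_group_file_names_the_sample(self, tmp_path):
        groups = self._groups().iloc[:2]
        with pytest.raises(vm.CohortJoinError, match="s3"):
            vm.join_cohort(self._variants(tmp_path),
                           self._annotations(tmp_path), groups)


class TestGroupsAndInvariants:
    def test_read_groups_rejects_unknown_label(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("s1\tcase\ns2\tpatient\n")
        with pytest.raises(vm.CohortJoinError, match="patient"):
            vm.read_groups(p)

    def test_zero_based_position_rejected(self):
        rec = pd.DataFrame({"chrom": ["1"], "pos": [0], "ref": ["A"],
                            "alt": ["C"], "site_qual": [1.0],
                            "mapping_quality": [1.0]})
        with pytest.raises(ValueError, match="1-based"):
            vm.VariantTable(records=rec,
                            genotypes=np.zeros((1, 1), dtype=np.int8),
                            depths=np.zeros((1, 1), dtype=np.int32),
                            samples=["s1"])

    def test_carrier_matrix_applies_depth_mask_with_missing_fallback(self):
        rec = pd.DataFrame({"chrom": ["1"], "pos": [5], "ref": ["A"],
                            "alt": ["C"], "site_qual": [50.0],
                            "mapping_quality": [60.0]})
        t = vm.VariantTable(
            records=rec,
            genotypes=np.array([[1, 1, 1]], dtype=np.int8),
            depths=np.array([[3, 10, vm.DP_MISSING]], dtype=np.int32),
            samples=["a", "b", "c"],
        )
        ct = vm.CohortTable(
            samples=pd.DataFrame({"sample_id": ["a", "b", "c"],
                                  "group": ["case"] * 3}),
            records=rec, genotypes=t.genotypes, depths=t.depths)
        assert list(ct.carrier_matrix()[0]) == [True, True, True]
        assert list(ct.carrier_matrix(min_depth_exclusive=4)[0]) == [
            False, True, True]
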