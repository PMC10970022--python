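"""VCF ingestion, genotype decoding and presence-matrix round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpfinder import (ManifestError, MatrixFormatError, PresenceMatrix,
                      SampleManifest, VariantSite, VcfFormatError, build_matrix,
                      genotype_to_presence, read_vcf)

from conftest import make_vcf, random_matrix, split_manifest


class TestReadVcf:
    def test_qual_filter_keeps_only_records_at_or_above_cutoff(self, toy_vcf):
        rec = read_vcf(toy_vcf, min_qual=30)
        assert rec.n_sites == 2
        assert list(rec.sites["pos"]) == [300, 400]
        assert rec.dropped["low_qual"] == 2
        assert rec.dropped["no_qual"] == 1

    def test_raising_min_qual_never_increases_retained(self, toy_vcf):
        counts = [read_vcf(toy_vcf, min_qual=q).n_sites for q in (0, 10, 29, 30, 31, 40)]
        assert counts == sorted(counts, reverse=True)

    def test_multiallelic_and_indel_records_dropped_and_counted(self, tmp_path):
        path = make_vcf(tmp_path / "mixed.vcf", [
            ("A01", 10, "A", "G", 50, ["0/1", "0/0", "0/0"]),
            ("A01", 20, "A", "G,T", 50, ["0/1", "0/2", "0/0"]),
            ("A01", 30, "AT", "A", 50, ["0/1", "0/0", "0/0"]),
        ])
        rec = read_vcf(path)
        assert rec.n_sites == 1
        assert rec.dropped == {"low_qual": 0, "no_qual": 0, "multiallelic": 1, "non_snp": 1}

    def test_sites_sorted_by_chrom_then_pos(self, tmp_path):
        path = make_vcf(tmp_path / "unsorted.vcf", [
            ("A02", 10, "A", "G", 50, ["0/1", "0/0", "0/0"]),
            ("A01", 100, "C", "T", 50, ["0/1", "0/0", "0/0"]),
            ("A01", 50, "G", "A", 50, ["0/0", "0/1", "0/0"]),
        ])
        rec = read_vcf(path)
        assert list(zip(rec.sites["chrom"], rec.sites["pos"])) == [
            ("A01", 50), ("A01", 100), ("A02", 10)]

    def test_empty_result_warns_not_fails(self, toy_vcf):
        with pytest.warns(UserWarning, match="no records"):
            rec = read_vcf(toy_vcf, min_qual=1000)
        assert rec.n_sites == 0

    def test_unreadable_path_raises_naming_it(self, tmp_path):
        with pytest.raises(VcfFormatError, match="nope.vcf"):
            read_vcf(tmp_path / "nope.vcf")


@pytest.mark.parametrize("gt,present,missing", [
    ("0/1", True, False),
    ("1/0", True, False),
    ("1/1", True, False),
    ("0/0", False, False),
    ("0|0", False, False),
    ("1|0", True, False),
    ("./.", False, True),
    ("2/0", True, False),
])
def test_genotype_to_presence(gt, present, missing):
    assert genotype_to_presence(gt) == (present, missing)


def test_malformed_gt_raises():
    with pytest.raises(VcfFormatError):
        genotype_to_presence("x/y")


class TestBuildMatrix:
    def test_presence_values_follow_alt_allele_rule(self, tmp_path):
        path = make_vcf(tmp_path / "t.vcf", [
            ("A01", 10, "A", "G", 50, ["0/1", "0/0", "1/1"]),
            ("A01", 20, "C", "T", 50, ["0/0", "0/0", "0/0"]),
        ])
        manifest = split_manifest(["S1", "S2", "S3"], 1)
        m = build_matrix(read_vcf(path), manifest)
        assert m.values.tolist() == [[True, False, True], [False, False, False]]
        assert m.monomorphic_report() == {"all_absent": 1, "all_present": 0}

    def test_manifest_sample_missing_from_vcf_is_hard_error(self, toy_vcf):
        manifest = split_manifest(["S1", "S9"], 1)
        with pytest.raises(ManifestError, match="S9"):
            build_matrix(read_vcf(toy_vcf), manifest)

    def test_manifest_subsetting_and_column_order(self, toy_vcf):
        manifest = split_manifest(["S3", "S1"], 1)
        m = build_matrix(read_vcf(toy_vcf), manifest)
        assert m.samples == ["S3", "S1"]
        # rows 300 and 400; S3 is 1/1 then 0/0, S1 is 0/1 then 0/0
        assert m.values.tolist() == [[True, True], [False, False]]

    def test_presence_counts_match_brute_force_gt_recount(self, tmp_path):
        rng = np.random.default_rng(42)
        gt_pool = ["0/0", "0/1", "1/1", "./.", "1|0", "0|0"]
        for trial in range(10):
            n_sites, n_samples = int(rng.integers(1, 15)), int(rng.integers(2, 8))
            samples = tuple(f"S{i}" for i in range(n_samples))
            records = []
            for i in range(n_sites):
                gts = [gt_pool[j] for j in rng.integers(0, len(gt_pool), n_samples)]
                records.append(("A01", 10 * (i + 1), "A", "G", 50, gts))
            path = make_vcf(tmp_path / f"r{trial}.vcf", records, samples)
            m = build_matrix(read_vcf(path), split_manifest(samples, 1))
            expected = [sum("1" in gt.replace("|", "/").split("/") for gt in gts)
                        for (_, _, _, _, _, gts) in records]
            assert m.presence_counts().tolist() == expected


class TestMatrixIO:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_write_read_round_trip_is_identity(self, seed, tmp_path_factory):
        m = random_matrix(np.random.default_rng(seed))
        path = tmp_path_factory.mktemp("io") / "m.tsv"
        m.write(path)
        back = PresenceMatrix.read(path)
        assert back.samples == m.samples
        assert (back.values == m.values).all()
        pd.testing.assert_frame_equal(back.sites, m.sites.reset_index(drop=True))

    def test_empty_matrix_round_trip(self, tmp_path):
        m = PresenceMatrix(
            sites=pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
            samples=["S1"], values=np.zeros((0, 1), dtype=bool))
        path = tmp_path / "empty.tsv"
        m.write(path)
        assert PresenceMatrix.read(path).n_sites == 0

    def test_hand_written_single_cell_table(self, tmp_path):
        path = tmp_path / "one.tsv"
        path.write_text("chrom\tpos\tref\talt\tS1\nA01\t5\tA\tG\t1\n")
        m = PresenceMatrix.read(path)
        assert m.values.tolist() == [[True]]

    def test_bad_cell_value_rejected_with_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\tref\talt\tS1\nA01\t5\tA\tG\t7\n")
        with pytest.raises(MatrixFormatError, match="S1"):
            PresenceMatrix.read(path)

    def test_wrong_leading_columns_rejected(self, tmp_path):
        path = tmp_path / "hdr.tsv"
        path.write_text("chrom\tposition\tref\talt\tS1\nA01\t5\tA\tG\t1\n")
        with pytest.raises(MatrixFormatError):
            PresenceMatrix.read(path)


class TestTypes:
    @pytest.mark.parametrize("kwargs", [
        dict(chrom="A01", pos=0, ref="A", alt="G"),
        dict(chrom="A01", pos=5, ref="A", alt="A"),
        dict(chrom="A01", pos=5, ref="AT", alt="G"),
    ])
    def test_variant_site_invariants(self, kwargs):
        with pytest.raises(ValueError):
            VariantSite(**kwargs)

    def test_manifest_rejects_duplicates_and_bad_roles(self):
        with pytest.raises(ManifestError, match="duplicate"):
            SampleManifest(samples=["a", "a"], roles={"a": "target"})
        with pytest.raises(ManifestError, match="role"):
            SampleManifest(samples=["a"], roles={"a": "tgt"})

    def test_manifest_tsv_round_trip(self, tmp_path):
        m = SampleManifest(samples=["a", "b", "c"],
                           roles={"a": "target", "b": "background", "c": "background"},
                           regions={"b": "YZ", "c": "N"})
        path = tmp_path / "m.tsv"
        m.write(path)
        back = SampleManifest.read(path)
        assert back.samples == m.samples
        assert back.roles == m.roles
        assert back.regions == m.regions
        assert back.region_labels == ["N", "YZ"]
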