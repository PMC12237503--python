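import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import sparse

from dapcy import genotype_io, popsim
from dapcy.errors import (
    FormatError,
    InputError,
    ParameterError,
    StratificationError,
)
from dapcy.genotype_io import (
    GenotypeMatrix,
    SampleLabels,
    encode_genotype,
    filter_maf,
    impute_missing,
    load_labels,
    load_matrix,
    read_bed,
    read_vcf,
    save_matrix,
)

from conftest import write_minimal_vcf


def matrices_equal(a, b):
    return (
        (a.dosages != b.dosages).nnz == 0
        and (a.missing_mask != b.missing_mask).nnz == 0
        and a.sample_ids == b.sample_ids
        and a.variant_ids == b.variant_ids
    )


class TestEncodeGenotype:
    @pytest.mark.parametrize(
        "gt,expected",
        [("0/0", 0), ("0|1", 1), ("1/1", 2), ("1|0", 1)],
    )
    def test_diploid_definitions(self, gt, expected):
        assert encode_genotype(gt) == expected

    def test_missing(self):
        assert encode_genotype("./.") is None

    def test_half_call_is_missing(self):
        assert encode_genotype("./1") is None
        assert encode_genotype("0/.") is None

    def test_haploid(self):
        assert encode_genotype("1", ploidy=1) == 1
        assert encode_genotype("0", ploidy=1) == 0
        assert encode_genotype(".", ploidy=1) is None

    def test_multiallelic_rejected(self):
        with pytest.raises(ParameterError):
            encode_genotype("1/2")

    def test_ploidy_mismatch(self):
        with pytest.raises(ParameterError):
            encode_genotype("0/1", ploidy=1)

    @given(st.integers(0, 1), st.integers(0, 1), st.sampled_from(["/", "|"]))
    def test_dosage_is_alt_count(self, a, b, sep):
        assert encode_genotype(f"{a}{sep}{b}") == a + b


class TestReadVcf:
    def test_hand_written_encoding(self, tmp_path):
        path = write_minimal_vcf(
            tmp_path / "t.vcf",
            [
                "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
                "1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t0/1\t./.\t1/1",
            ],
        )
        G, samples = read_vcf(path)
        assert samples == ["S1", "S2", "S3"]
        np.testing.assert_array_equal(G.to_dense()[:, 0], [0, 1, 2])
        np.testing.assert_array_equal(G.to_dense()[:, 1], [1, 0, 2])
        assert G.missing_mask.toarray()[1, 1]
        assert G.variant_ids == ["1:100:A:T", "1:200:C:G"]

    def test_roundtrip_identity(self, small_cohort, tmp_path):
        path = tmp_path / "fix.vcf"
        popsim.write_vcf(small_cohort, path)
        G, samples = read_vcf(path)
        assert matrices_equal(G, small_cohort.genotypes)
        assert samples == small_cohort.genotypes.sample_ids

    def test_roundtrip_with_missing(self, missing_cohort, tmp_path):
        path = tmp_path / "fix.vcf.gz"
        popsim.write_vcf(missing_cohort, path)
        G, _ = read_vcf(path)
        assert matrices_equal(G, missing_cohort.genotypes)

    @pytest.mark.parametrize("chunk_size", [1, 7, 10_000])
    def test_chunk_invariance(self, small_cohort, tmp_path, chunk_size):
        path = tmp_path / "fix.vcf"
        popsim.write_vcf(small_cohort, path)
        G, _ = read_vcf(path, chunk_size=chunk_size)
        assert matrices_equal(G, small_cohort.genotypes)

    def test_alt_frequency_matches_source(self, small_cohort, tmp_path):
        path = tmp_path / "fix.vcf"
        popsim.write_vcf(small_cohort, path)
        G, _ = read_vcf(path)
        # recount ALT alleles directly from the text GT fields
        counts = None
        with open(path) as fh:
            rows = [l for l in fh if not l.startswith("#")]
        freqs = []
        for row in rows:
            gts = row.rstrip("\n").split("\t")[9:]
            alt = sum(g.count("1") for g in gts)
            obs = sum(1 for g in gts if "." not in g)
            freqs.append(alt / (2 * obs))
        np.testing.assert_allclose(G.alt_frequencies(), freqs, atol=1e-12)

    def test_multiallelic_dropped_by_default(self, tmp_path, caplog):
        path = write_minimal_vcf(
            tmp_path / "m.vcf",
            [
                "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
                "1\t200\t.\tC\tG,A\t.\tPASS\t.\tGT\t0/1\t1/2\t2/2",
            ],
        )
        G, _ = read_vcf(path)
        assert G.n_variants == 1
        assert G.variant_ids == ["1:100:A:T"]

    def test_multiallelic_split(self, tmp_path):
        path = write_minimal_vcf(
            tmp_path / "m.vcf",
            ["1\t200\t.\tC\tG,A\t.\tPASS\t.\tGT\t0/1\t1/2\t2/2"],
        )
        G, _ = read_vcf(path, multiallelic="split")
        assert G.variant_ids == ["1:200:C:G", "1:200:C:A"]
        np.testing.assert_array_equal(G.to_dense()[:, 0], [1, 1, 0])
        np.testing.assert_array_equal(G.to_dense()[:, 1], [0, 1, 2])

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(InputError):
            read_vcf(tmp_path / "nope.vcf")

    def test_no_variants(self, tmp_path):
        path = write_minimal_vcf(tmp_path / "e.vcf", [])
        with pytest.raises(InputError):
            read_vcf(path)

    def test_bad_chunk_size(self, tmp_path):
        path = write_minimal_vcf(
            tmp_path / "t.vcf", ["1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1"]
        )
        with pytest.raises(ParameterError):
            read_vcf(path, chunk_size=0)


class TestReadBed:
    def test_cross_format_oracle(self, small_cohort, tmp_path):
        popsim.write_vcf(small_cohort, tmp_path / "fix.vcf")
        popsim.write_bed(small_cohort, tmp_path / "fix")
        G_vcf, _ = read_vcf(tmp_path / "fix.vcf")
        G_bed, _ = read_bed(tmp_path / "fix")
        assert (G_vcf.dosages != G_bed.dosages).nnz == 0
        assert G_vcf.sample_ids == G_bed.sample_ids

    def test_cross_format_with_missing(self, missing_cohort, tmp_path):
        popsim.write_bed(missing_cohort, tmp_path / "fix")
        G, _ = read_bed(tmp_path / "fix")
        assert matrices_equal(
            G, missing_cohort.genotypes
        ) or (
            (G.dosages != missing_cohort.genotypes.dosages).nnz == 0
            and (G.missing_mask != missing_cohort.genotypes.missing_mask).nnz == 0
        )

    def _write_trio(self, tmp_path, bed_payload, n_samples=1, n_variants=1):
        with open(tmp_path / "t.fam", "w") as fh:
            for i in range(n_samples):
                fh.write(f"F{i} I{i} 0 0 0 -9\n")
        with open(tmp_path / "t.bim", "w") as fh:
            for j in range(n_variants):
                fh.write(f"1 snp{j} 0 {100 + j} T A\n")
        with open(tmp_path / "t.bed", "wb") as fh:
            fh.write(b"\x6c\x1b\x01" + bed_payload)
        return tmp_path / "t"

    def test_frozen_heterozygote_byte(self, tmp_path):
        # 2-bit code 10 (het) in the low bits -> dosage 1
        prefix = self._write_trio(tmp_path, bytes([0b00000010]))
        G, samples = read_bed(prefix)
        assert samples == ["I0"]
        assert G.to_dense()[0, 0] == 1
        assert G.n_missing == 0

    def test_frozen_missing_byte(self, tmp_path):
        # code 01 is the PLINK missing genotype
        prefix = self._write_trio(tmp_path, bytes([0b00000001]))
        G, _ = read_bed(prefix)
        assert G.missing_mask.toarray()[0, 0]
        assert G.to_dense()[0, 0] == 0

    def test_frozen_hom_codes(self, tmp_path):
        # four samples in one byte: codes 00,10,11,00 -> dosages 2,1,0,2
        prefix = self._write_trio(
            tmp_path, bytes([0b00111000]), n_samples=4
        )
        G, _ = read_bed(prefix)
        np.testing.assert_array_equal(G.to_dense().ravel(), [2, 1, 0, 2])

    def test_payload_dimension_mismatch(self, tmp_path):
        prefix = self._write_trio(tmp_path, bytes([0, 0]))
        with pytest.raises(FormatError):
            read_bed(prefix)

    def test_bad_magic(self, tmp_path):
        prefix = self._write_trio(tmp_path, b"")
        with open(str(prefix) + ".bed", "wb") as fh:
            fh.write(b"xx\x01\x00")
        with pytest.raises(FormatError):
            read_bed(prefix)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            read_bed(tmp_path / "absent")


class TestImputeMissing:
    def _matrix_with_missing(self):
        dos = np.array([[0.0, 2, 1], [2.0, 0, 1], [0.0, 1, 0]])
        mask = np.zeros_like(dos, dtype=bool)
        mask[2, 0] = True  # column 0 observed: (0, 2) -> mean 1.0
        return GenotypeMatrix(
            dosages=sparse.csr_matrix(dos * ~mask),
            missing_mask=sparse.csr_matrix(mask),
            sample_ids=["a", "b", "c"],
            variant_ids=["1:1:A:T", "1:2:A:T", "1:3:A:T"],
        )

    def test_mean_fill(self):
        G = impute_missing(self._matrix_with_missing(), "mean")
        assert G.n_missing == 0
        assert G.to_dense()[2, 0] == pytest.approx(1.0)

    def test_observed_entries_untouched(self):
        orig = self._matrix_with_missing()
        G = impute_missing(orig, "mean")
        obs = ~orig.missing_mask.toarray()
        np.testing.assert_array_equal(
            G.to_dense()[obs], orig.to_dense()[obs]
        )

    def test_identity_when_complete(self, small_cohort):
        G = small_cohort.genotypes
        assert impute_missing(G, "mean") is G

    def test_zero_strategy(self):
        G = impute_missing(self._matrix_with_missing(), "zero")
        assert G.n_missing == 0
        assert G.to_dense()[2, 0] == 0

    def test_all_missing_variant_dropped(self, caplog):
        dos = np.array([[0.0, 1], [0.0, 2]])
        mask = np.array([[True, False], [True, False]])
        G = GenotypeMatrix(
            dosages=sparse.csr_matrix(dos * ~mask),
            missing_mask=sparse.csr_matrix(mask),
            sample_ids=["a", "b"],
            variant_ids=["1:1:A:T", "1:2:A:T"],
        )
        out = impute_missing(G, "mean")
        assert out.variant_ids == ["1:2:A:T"]

    def test_bad_strategy(self, small_cohort):
        with pytest.raises(ParameterError):
            impute_missing(small_cohort.genotypes, "median")


class TestFilterMaf:
    def test_rare_variant_removed(self):
        # 10 diploid samples, one heterozygote -> p = 0.05 < 0.10
        dense = np.zeros((10, 2))
        dense[0, 0] = 1  # variant 0: p=0.05
        dense[:5, 1] = 2  # variant 1: p=0.5
        G = GenotypeMatrix(
            dosages=sparse.csr_matrix(dense),
            missing_mask=sparse.csr_matrix((10, 2), dtype=bool),
            sample_ids=[f"s{i}" for i in range(10)],
            variant_ids=["1:1:A:T", "1:2:A:T"],
        )
        out = filter_maf(G, 0.10)
        assert out.variant_ids == ["1:2:A:T"]

    def test_zero_threshold_identity(self, small_cohort):
        G = small_cohort.genotypes
        out = filter_maf(G, 0.0)
        assert out is G

    def test_p_half_always_survives(self):
        dense = np.array([[2.0], [0.0]])
        G = GenotypeMatrix(
            dosages=sparse.csr_matrix(dense),
            missing_mask=sparse.csr_matrix((2, 1), dtype=bool),
            sample_ids=["a", "b"],
            variant_ids=["1:1:A:T"],
        )
        for thr in (0.1, 0.3, 0.5):
            assert filter_maf(G, thr).n_variants == 1

    def test_idempotent(self, small_cohort):
        once = filter_maf(small_cohort.genotypes, 0.2)
        twice = filter_maf(once, 0.2)
        assert once.variant_ids == twice.variant_ids
        assert (once.dosages != twice.dosages).nnz == 0

    def test_threshold_range(self, small_cohort):
        with pytest.raises(ParameterError):
            filter_maf(small_cohort.genotypes, 0.6)

    def test_frequency_over_observed_calls_only(self):
        # variant has dosage 2 in one of two observed samples, third missing:
        # p = 2/4 = 0.5, survives; counting the missing sample would give 1/3
        dense = np.array([[2.0], [0.0], [0.0]])
        mask = np.array([[False], [False], [True]])
        G = GenotypeMatrix(
            dosages=sparse.csr_matrix(dense),
            missing_mask=sparse.csr_matrix(mask),
            sample_ids=["a", "b", "c"],
            variant_ids=["1:1:A:T"],
        )
        assert filter_maf(G, 0.45).n_variants == 1


class TestGenotypeMatrixContract:
    def test_dosage_bounds_enforced(self):
        with pytest.raises(ParameterError):
            GenotypeMatrix(
                dosages=sparse.csr_matrix(np.array([[3.0]])),
                missing_mask=sparse.csr_matrix((1, 1), dtype=bool),
                sample_ids=["a"],
                variant_ids=["1:1:A:T"],
            )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(FormatError):
            GenotypeMatrix(
                dosages=sparse.csr_matrix(np.zeros((2, 1))),
                missing_mask=sparse.csr_matrix((2, 1), dtype=bool),
                sample_ids=["a", "a"],
                variant_ids=["1:1:A:T"],
            )

    def test_sparse_storage(self, small_cohort):
        G = small_cohort.genotypes
        assert sparse.issparse(G.dosages)
        assert G.dosages.format == "csr"
        assert G.dosages.nnz == np.count_nonzero(G.to_dense())


class TestArchiveAndLabels:
    def test_matrix_archive_roundtrip(self, missing_cohort, tmp_path):
        G = missing_cohort.genotypes
        path = tmp_path / "m.npz"
        save_matrix(G, path)
        G2 = load_matrix(path)
        assert matrices_equal(G2, G)
        assert G2.ploidy == G.ploidy

    @pytest.mark.parametrize("delim", ["\t", ","])
    def test_load_labels(self, tmp_path, delim):
        path = tmp_path / "labels.txt"
        path.write_text(
            f"sample_id{delim}population\n"
            f"s1{delim}popA\ns2{delim}popB\ns3{delim}popA\n"
        )
        labels = load_labels(path)
        assert labels.mapping == {"s1": "popA", "s2": "popB", "s3": "popA"}
        assert labels.k == 2

    def test_load_labels_no_header(self, tmp_path):
        path = tmp_path / "labels.txt"
        path.write_text("s1 popA\ns2 popB\n")
        assert load_labels(path).k == 2

    def test_labels_validate_against_matrix(self, small_cohort):
        labels = SampleLabels(mapping={"ghost": "popX"})
        with pytest.raises(FormatError):
            labels.validate_against(small_cohort.genotypes)
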