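import numpy as np
import pandas as pd
import pytest

from trianet.genotype_io import (MISSING, GenotypeError, GenotypeMatrix,
                                 RegionSet, exclude_regions, ld_prune,
                                 maf_filter, read_bed, read_matrix, read_vcf,
                                 write_matrix)


def make_matrix(dosages, positions=None, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    positions = positions if positions is not None else np.arange(m) * 10
    variants = pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "id": [f"v{j}" for j in range(m)], "ref": "A", "alt": "G",
    })
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosages)


class TestReadVcf:
    def test_dosages_and_missing(self, tiny_vcf):
        g = read_vcf(tiny_vcf, biallelic_only=True)
        assert g.samples == ["A", "B", "C"]
        # multiallelic rs3 and indel rs4 are skipped
        assert [v for v in g.variants["id"]] == ["rs1", "rs2"]
        expected = np.array([[0, 1], [1, MISSING], [2, 0]], dtype=np.int8)
        assert np.array_equal(g.dosages, expected)
        # VCF 1-based positions become 0-based internally
        assert list(g.variants["pos"]) == [99, 199]

    def test_multiallelic_kept_out_even_without_flag(self, tiny_vcf):
        g = read_vcf(tiny_vcf, biallelic_only=False)
        assert "rs3" not in list(g.variants["id"])
        assert "rs4" in list(g.variants["id"])  # indel allowed when not SNP-only

    def test_empty_input_errors(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text("##fileformat=VCFv4.2\n##contig=<ID=1>\n"
                     "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tX\n")
        with pytest.raises(GenotypeError):
            read_vcf(str(p))


class TestMafFilter:
    def test_threshold_is_strict(self):
        # 50 samples -> 100 alleles; alt counts 4, 5, 6 -> MAF .04, .05, .06
        d = np.zeros((50, 3), dtype=np.int8)
        for j, alt in enumerate([4, 5, 6]):
            d[:alt, j] = 1
        g = maf_filter(make_matrix(d), 0.05)
        assert list(g.variants["id"]) == ["v2"]

    def test_monomorphic_removed(self):
        d = np.column_stack([np.zeros(20), np.ones(20)]).astype(np.int8)
        g = maf_filter(make_matrix(d), 0.01)
        assert g.n_variants == 1 and list(g.variants["id"]) == ["v1"]

    def test_maf_uses_nonmissing_calls(self):
        # v0: 1 het among 5 called -> MAF 0.1 (missing rows ignored); kept
        # v1: 1 het among 10 called -> MAF exactly 0.05; removed (strict)
        v0 = np.array([1, 0, 0, 0, 0] + [MISSING] * 5, dtype=np.int8)
        v1 = np.array([1] + [0] * 9, dtype=np.int8)
        g = make_matrix(np.column_stack([v0, v1]))
        out = maf_filter(g, 0.05)
        assert list(out.variants["id"]) == ["v0"]

    def test_all_removed_errors(self):
        d = np.zeros((10, 2), dtype=np.int8)
        with pytest.raises(GenotypeError, match="lower"):
            maf_filter(make_matrix(d), 0.05)

    def test_idempotent(self, rng):
        d = rng.integers(0, 3, size=(40, 30)).astype(np.int8)
        once = maf_filter(make_matrix(d), 0.1)
        twice = maf_filter(once, 0.1)
        assert np.array_equal(once.dosages, twice.dosages)
        assert list(once.variants["id"]) == list(twice.variants["id"])

    def test_commutes_with_exclude_regions(self, rng):
        d = rng.integers(0, 3, size=(30, 25)).astype(np.int8)
        g = make_matrix(d)
        regions = RegionSet([("chr1", 35, 120)])
        a = maf_filter(exclude_regions(g, regions), 0.1)
        b = exclude_regions(maf_filter(g, 0.1), regions)
        assert list(a.variants["id"]) == list(b.variants["id"])
        assert np.array_equal(a.dosages, b.dosages)


class TestLdPrune:
    def test_perfect_correlation_drops_later(self, rng):
        col = rng.integers(0, 3, size=50).astype(np.int8)
        other = rng.integers(0, 3, size=50).astype(np.int8)
        g = make_matrix(np.column_stack([col, col, other]))
        out = ld_prune(g, window=3, step=1, r2_max=0.2)
        assert list(out.variants["id"]) == ["v0", "v2"]

    def test_independent_snps_mostly_retained(self, rng):
        d = (rng.random((500, 40)) < 0.4).astype(np.int8) + \
            (rng.random((500, 40)) < 0.4)
        out = ld_prune(make_matrix(d.astype(np.int8)), window=40, step=5, r2_max=0.2)
        assert out.n_variants >= 38  # E[r^2] ~ 1/n << 0.2

    def test_matches_exhaustive_oracle(self, rng):
        for trial in range(20):
            n, m = 30, int(rng.integers(5, 21))
            base = (rng.random((n, m)) < 0.5).astype(float)
            # plant correlated pairs
            for _ in range(3):
                a, b = rng.integers(0, m, size=2)
                base[:, b] = base[:, a]
            d = base.astype(np.int8) + (rng.random((n, m)) < 0.3).astype(np.int8)
            d = np.clip(d, 0, 2).astype(np.int8)
            g = make_matrix(d)
            out = ld_prune(g, window=m, step=m, r2_max=0.5)
            # oracle: single pass over all pairs in order, independent r^2
            keep = [True] * m
            x = d.astype(float)
            for i in range(m):
                for j in range(i + 1, m):
                    if keep[i] and keep[j]:
                        c = np.corrcoef(x[:, i], x[:, j])[0, 1]
                        if np.isnan(c):
                            c = 0.0
                        if c * c > 0.5:
                            keep[j] = False
            expect = [f"v{j}" for j in range(m) if keep[j]]
            assert list(out.variants["id"]) == expect


class TestExcludeRegions:
    def test_interval_conventions(self):
        g = make_matrix(np.ones((5, 3), dtype=np.int8), positions=[50, 100, 200])
        out = exclude_regions(g, RegionSet([("chr1", 100, 200)]))
        # start inclusive (100 removed), end exclusive (200 kept)
        assert list(out.variants["pos"]) == [50, 200]

    def test_empty_regionset_is_identity(self, rng):
        d = rng.integers(0, 3, size=(10, 8)).astype(np.int8)
        g = make_matrix(d)
        out = exclude_regions(g, RegionSet([]))
        assert np.array_equal(out.dosages, g.dosages)

    def test_other_chromosome_untouched(self):
        g = make_matrix(np.ones((4, 2), dtype=np.int8), positions=[10, 20], chrom="chr2")
        out = exclude_regions(g, RegionSet([("chr1", 0, 100)]))
        assert out.n_variants == 2

    def test_read_bed(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t100\t200\nchr2\t0\t50\n")
        rs = read_bed(str(p))
        assert rs.intervals == [("chr1", 100, 200), ("chr2", 0, 50)]


def test_matrix_round_trip(tmp_path, rng):
    d = rng.integers(0, 3, size=(6, 9)).astype(np.int8)
    d[0, 0] = MISSING
    d[3, 4] = MISSING
    g = make_matrix(d)
    path = tmp_path / "geno.tsv"
    write_matrix(g, str(path))
    back = read_matrix(str(path))
    assert back.samples == g.samples
    assert back.variant_ids == g.variant_ids
    assert np.array_equal(back.dosages, g.dosages)


def test_invalid_dosage_rejected():
    with pytest.raises(GenotypeError):
        make_matrix(np.full((2, 2), 5, dtype=np.int8))


class TestFilterProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 0.45))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_maf_filter_idempotent_and_strict(self, seed, threshold):
        rng2 = np.random.default_rng(seed)
        d = rng2.integers(0, 3, size=(25, 15)).astype(np.int8)
        g = make_matrix(d)
        try:
            once = maf_filter(g, threshold)
        except GenotypeError:
            return  # everything filtered: nothing to check
        twice = maf_filter(once, threshold)
        assert list(once.variants["id"]) == list(twice.variants["id"])
        af = once.allele_frequencies()
        assert (np.fmin(af, 1 - af) > threshold).all()
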