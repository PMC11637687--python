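import numpy as np
import pandas as pd
import pytest


from barrierscan.core_io import (
    MISSING,
    FilterParams,
    GenotypeMatrix,
    VcfFormatError,
    apply_filters,
    make_windows,
    map_features,
    read_vcf,
    write_vcf,
)
from conftest import make_matrix


class TestReadVcf:
    def test_dosage_transcription(self, tiny_vcf):
        gm = read_vcf(tiny_vcf)
        assert gm.samples == ["a", "b"]
        expected = np.array([[0, 1], [2, MISSING], [1, 2]], dtype=np.int8)
        np.testing.assert_array_equal(gm.dosage, expected)
        assert gm.depth[0, 0] == 30 and gm.depth[1, 1] == MISSING
        assert gm.qual_gt[2, 1] == 95
        # unphased input: no haplotype matrix
        assert gm.haplotypes is None

    def test_phase_preserved_when_fully_phased(self, tmp_path, tiny_vcf):
        text = tiny_vcf.read_text().replace("0/", "0|").replace("1/", "1|")
        p = tmp_path / "phased.vcf"
        p.write_text(text)
        gm = read_vcf(p)
        assert gm.haplotypes is not None
        np.testing.assert_array_equal(gm.haplotypes[2], [0, 1, 1, 1])

    def test_multiallelic_and_indels_skipped(self, tmp_path, tiny_vcf):
        lines = tiny_vcf.read_text().splitlines()
        lines.insert(
            -1, "chr1\t250\t.\tA\tT,G\t50\t.\t.\tGT:DP:GQ\t0/1:10:30\t0/0:10:30"
        )
        lines.append("chr1\t400\t.\tA\tATT\t50\t.\t.\tGT:DP:GQ\t0/1:10:30\t0/0:10:30")
        p = tmp_path / "multi.vcf"
        p.write_text("\n".join(lines) + "\n")
        gm = read_vcf(p)
        assert gm.n_sites == 3
        assert gm.n_skipped_records == 2

    def test_empty_body_gives_empty_matrix(self, tmp_path, tiny_vcf):
        header = "\n".join(tiny_vcf.read_text().splitlines()[:6]) + "\n"
        p = tmp_path / "empty.vcf"
        p.write_text(header)
        gm = read_vcf(p)
        assert gm.n_sites == 0 and gm.n_samples == 2

    def test_bad_header_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("not a vcf at all\n")
        with pytest.raises(VcfFormatError):
            read_vcf(p)

    def test_round_trip_preserves_dosage_phase_order(self, tmp_path, tiny_vcf):
        text = tiny_vcf.read_text().replace("0/", "0|").replace("1/", "1|")
        src = tmp_path / "src.vcf"
        src.write_text(text)
        gm = read_vcf(src)
        out = tmp_path / "out.vcf"
        write_vcf(gm, out)
        gm2 = read_vcf(out)
        np.testing.assert_array_equal(gm.dosage, gm2.dosage)
        np.testing.assert_array_equal(gm.haplotypes, gm2.haplotypes)
        pd.testing.assert_frame_equal(
            gm.sites[["chrom", "pos", "ref", "alt"]],
            gm2.sites[["chrom", "pos", "ref", "alt"]],
        )


class TestApplyFilters:
    def test_qual_threshold_edge(self):
        gm = make_matrix(np.tile([0, 1, 2, 1], (3, 5)), qual=100.0)
        gm.sites.loc[1, "qual"] = 29.0
        out, rep = apply_filters(gm)
        assert out.n_sites == 2
        assert rep.n_sites_qual == 1

    def test_site_missingness(self):
        row = [MISSING] * 6 + [1, 1, 2, 0]  # 0.6 missing > 0.5
        clean = [0, 1, 2, 1, 0, 1, 2, 1, 0, 1]
        gm = make_matrix([row, clean, clean])
        out, rep = apply_filters(gm, FilterParams(min_mac=1))
        assert out.n_sites == 2
        assert rep.n_sites_missing == 1

    def test_depth_masks_calls_first(self):
        dosage = np.tile([0, 1, 2, 1, 0, 1, 2, 1, 0, 1], (2, 1))
        depth = np.full((2, 10), 30, dtype=np.int32)
        depth[0, :6] = 5  # below min_depth -> missing -> site missingness 0.6
        gm = make_matrix(dosage, depth=depth)
        out, rep = apply_filters(gm, FilterParams(min_mac=1))
        assert rep.n_calls_depth_masked == 6
        assert out.n_sites == 1

    def test_all_sites_removed_flag_not_exception(self):
        gm = make_matrix([[0, 0, 0, 0]])  # MAC 0 < 3
        out, rep = apply_filters(gm)
        assert out.n_sites == 0
        assert rep.all_sites_removed

    def test_idempotent(self, rng):
        dosage = rng.integers(-1, 3, size=(60, 20)).astype(np.int8)
        gm = make_matrix(dosage, qual=rng.uniform(20, 200, 60)[0])
        once, _ = apply_filters(gm)
        twice, rep2 = apply_filters(once)
        np.testing.assert_array_equal(once.dosage, twice.dosage)
        assert once.samples == twice.samples

    def test_matches_rule_transcription_oracle(self, rng):
        """Randomized fixture equals an independent re-application of the
        filter rules in the stated order."""
        S, N = 50, 12
        dosage = rng.integers(0, 3, size=(S, N)).astype(np.int8)
        dosage[rng.random((S, N)) < 0.15] = MISSING
        depth = rng.integers(2, 40, size=(S, N)).astype(np.int32)
        qual = rng.uniform(10, 120, S)
        gm = make_matrix(dosage, depth=depth)
        gm.sites["qual"] = qual
        p = FilterParams()
        out, _ = apply_filters(gm, p)

        # oracle: independent transcription with plain loops
        d = dosage.copy()
        d[(depth < p.min_depth)] = MISSING
        keep_sites = []
        for i in range(S):
            calls = d[i]
            n_miss = int((calls == MISSING).sum())
            alt = int(calls[calls != MISSING].sum())
            tot = 2 * int((calls != MISSING).sum())
            mac = min(alt, tot - alt)
            if qual[i] >= p.min_qual and n_miss / N <= p.max_site_missing and mac >= p.min_mac:
                keep_sites.append(i)
        d2 = d[keep_sites]
        keep_samp = []
        for j in range(N):
            if len(keep_sites) == 0:
                break
            if (d2[:, j] == MISSING).mean() < p.max_indiv_missing:
                keep_samp.append(j)
        d3 = d2[:, keep_samp]
        final_sites = []
        for i in range(d3.shape[0]):
            calls = d3[i]
            alt = int(calls[calls != MISSING].sum())
            tot = 2 * int((calls != MISSING).sum())
            if min(alt, tot - alt) >= p.min_mac:
                final_sites.append(i)
        np.testing.assert_array_equal(out.dosage, d3[final_sites])
        assert out.samples == [f"s{j}" for j in keep_samp]


class TestWindows:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (25_000, [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]),
            (10_000, [(0, 10_000)]),
            (1, [(0, 1)]),
        ],
    )
    def test_tiling(self, length, expected):
        w = make_windows({"chr1": length}, size=10_000, step=10_000)
        assert list(zip(w["start"], w["end"])) == expected

    def test_step_greater_than_size_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": 100}, size=10, step=20)

    def test_full_coverage_no_overlap(self):
        w = make_windows({"chr1": 95_001}, size=10_000, step=10_000)
        assert w["start"].iloc[0] == 0
        assert (w["start"].values[1:] == w["end"].values[:-1]).all()
        assert w["end"].iloc[-1] == 95_001


class TestMapFeatures:
    GENES = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [20_000, 50_000],
            "end": [25_000, 51_000],
            "gene_id": ["g1", "g2"],
            "strand": ["+", "-"],
        }
    )

    def test_snp_within_flank_mapped(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [30_001]})  # 5 kb past g1
        hits = map_features(snps, self.GENES, flank=10_000)
        assert set(hits["gene_id"]) == {"g1"}

    def test_snp_beyond_flank_unmapped(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [35_002]})  # 10,001 bp past
        hits = map_features(snps, self.GENES, flank=10_000)
        assert hits.empty

    def test_zero_flank_equals_strict_intersection(self, rng):
        snps = pd.DataFrame(
            {"chrom": ["chr1"] * 50, "pos": rng.integers(1, 60_000, 50)}
        )
        hits = map_features(snps, self.GENES, flank=0)
        for row in hits.itertuples(index=False):
            g = self.GENES[self.GENES["gene_id"] == row.gene_id].iloc[0]
            p0 = snps["pos"].iloc[row.feature_index] - 1
            assert g.start <= p0 < g.end

    def test_matches_quadratic_oracle(self, rng):
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 20),
                "start": (s := rng.integers(0, 200_000, 20)),
                "end": s + rng.integers(500, 5_000, 20),
                "gene_id": [f"g{i}" for i in range(20)],
                "strand": ["."] * 20,
            }
        )
        snps = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 100),
                "pos": rng.integers(1, 210_000, 100),
            }
        )
        flank = 10_000
        got = {
            (r.feature_index, r.gene_id)
            for r in map_features(snps, genes, flank).itertuples(index=False)
        }
        expected = set()
        for i, s_ in snps.iterrows():
            for _, g in genes.iterrows():
                if s_["chrom"] == g["chrom"] and (
                    g["start"] - flank <= s_["pos"] - 1 < g["end"] + flank
                ):
                    expected.add((i, g["gene_id"]))
        assert got == expected
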