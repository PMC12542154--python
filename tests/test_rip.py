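"""RIP threshold estimation, window classification, blocks and centromeres."""

import numpy as np
import pytest

from holosplit.model import Contig, ContigSet, FeatureRecord
from holosplit.rip import (
    RipClassification,
    classify_windows,
    find_rip_threshold,
    flank_gc,
    metaprofile,
    retro_density_centromeres,
    rip_blocks,
    te_family_gc_ranking,
)


def two_mode_windows(n=4000, seed=0, mu=(16.0, 48.0), w=(0.5, 0.5), sd=1.8):
    rng = np.random.default_rng(seed)
    comp = rng.choice([0, 1], size=n, p=w)
    return np.where(comp == 0, rng.normal(mu[0], sd, n), rng.normal(mu[1], sd, n))


class TestFindThreshold:
    def test_two_gaussian_mixture_valley(self):
        """Estimated threshold sits at the density minimum between the two
        modes, verified against a dense-grid minimum of the true mixture."""
        from scipy.stats import norm

        vals = two_mode_windows()
        res = find_rip_threshold(vals)
        assert not res.fallback_used
        grid = np.arange(20, 45, 0.01)
        true_dens = 0.5 * norm.pdf(grid, 16, 1.8) + 0.5 * norm.pdf(grid, 48, 1.8)
        true_valley = grid[np.argmin(true_dens)]
        assert 28 <= res.value <= 36
        assert abs(res.value - true_valley) <= 4.0

    def test_unimodal_falls_back(self):
        rng = np.random.default_rng(1)
        res = find_rip_threshold(rng.normal(50, 2, 5000))
        assert res.fallback_used and res.value == 35.0

    def test_too_few_windows_falls_back(self):
        res = find_rip_threshold(np.array([10.0, 50.0] * 100))
        assert res.fallback_used

    def test_synthetic_fungal_genome(self, holobiont):
        fungal = ContigSet([holobiont.contigs[f"F_chr{i}"] for i in range(1, 5)])
        res = find_rip_threshold(fungal)
        assert not res.fallback_used
        assert 30 <= res.value <= 36


class TestClassifyWindows:
    def test_all_gc_genome_unripped(self):
        cls = classify_windows(Contig("c", "GC" * 2000), 35.0)
        assert cls.fraction_ripped == 0.0

    def test_zero_threshold_boundary(self):
        cls = classify_windows(Contig("c", "AT" * 2000), 0.0)
        assert cls.fraction_ripped == 0.0

    def test_fraction_matches_generator_truth(self, holobiont):
        fungal = ContigSet([holobiont.contigs[f"F_chr{i}"] for i in range(1, 5)])
        truth_frac = holobiont.truth.ripped_fraction(
            {c.id: c.length for c in holobiont.contigs}
        )
        cls = classify_windows(fungal, 35.0)
        assert abs(cls.fraction_ripped - truth_frac) <= 0.02
        assert cls.fraction_ripped + cls.fraction_unripped == pytest.approx(1.0)

    def test_matches_brute_force_on_random_genomes(self):
        rng = np.random.default_rng(2)
        for rep in range(100):
            gc = rng.uniform(0.1, 0.9)
            n = int(rng.integers(1500, 4000))
            seq = "".join(rng.choice(list("ACGT"), n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]))
            thr = rng.uniform(20, 60)
            cls = classify_windows(Contig("c", seq), thr)
            # independent oracle: slice-and-count every window
            exp = []
            for s in range(0, n - 499, 500):
                w = seq[s : s + 500]
                wgc = 100.0 * (w.count("G") + w.count("C")) / 500
                exp.append("ripped" if wgc < thr else "unripped")
            assert cls.labels["c"].tolist() == exp

    def test_fraction_recovery_across_seeds(self):
        """Across 10 generator seeds the estimated ripped fraction stays
        within 0.02 of the designed truth in at least 9 runs."""
        from holosplit.synth import (
            AlgalConfig,
            BacteriumConfig,
            ChimeraConfig,
            FungalConfig,
            HolobiontConfig,
            generate_holobiont,
        )

        ok = 0
        for seed in range(10):
            cfg = HolobiontConfig(
                seed=seed,
                fungal=FungalConfig(n_chrom=2),
                algal=AlgalConfig(n_chrom=1, chrom_len=250_000),
                bacteria=[BacteriumConfig("BacA", genome_len=40_000, n_contigs=4),
                          BacteriumConfig("BacB", genome_len=40_000, n_contigs=4, gc=63.0)],
                chimeras=ChimeraConfig(n=0),
            )
            holo = generate_holobiont(cfg)
            fungal = ContigSet([c for c in holo.contigs if c.id.startswith("F_chr")])
            thr = find_rip_threshold(fungal)
            frac = classify_windows(fungal, thr.value).fraction_ripped
            truth = holo.truth.ripped_fraction({c.id: c.length for c in holo.contigs})
            ok += abs(frac - truth) <= 0.02
        assert ok >= 9

    def test_fraction_monotone_in_threshold(self, holobiont):
        fungal = ContigSet([holobiont.contigs["F_chr1"]])
        fracs = [classify_windows(fungal, t).fraction_ripped for t in (0, 20, 35, 50, 100)]
        assert fracs == sorted(fracs)


class TestFlankGc:
    def test_feature_at_contig_start_has_missing_5prime(self):
        c = ContigSet([Contig("c", "ACGT" * 2000)])
        (rec,) = flank_gc([FeatureRecord("c", 0, 500, "+", "gene")], c)
        assert rec.gc_5prime is None and rec.gc_3prime is not None

    def test_minus_strand_swaps_flanks(self):
        seq = "A" * 1000 + "G" * 500 + "C" * 500 + "G" * 500 + "T" * 1000
        c = ContigSet([Contig("c", seq)])
        plus = flank_gc([FeatureRecord("c", 1500, 2000, "+", "gene")], c)[0]
        minus = flank_gc([FeatureRecord("c", 1500, 2000, "-", "gene")], c)[0]
        assert plus.gc_5prime == minus.gc_3prime
        assert plus.gc_3prime == minus.gc_5prime

    def test_gene_flanks_track_genic_gc(self, holobiont):
        genes = [f for f in holobiont.features
                 if f.kind == "gene" and f.contig_id.startswith("F_")]
        recs = flank_gc(genes, holobiont.contigs)
        med5 = np.median([r.gc_5prime for r in recs if r.gc_5prime is not None])
        med3 = np.median([r.gc_3prime for r in recs if r.gc_3prime is not None])
        genic = holobiont.config.fungal.genic_gc
        assert abs(med5 - genic) <= 3 and abs(med3 - genic) <= 3

    def test_ripped_retro_flanks_track_ripped_gc(self, holobiont):
        cen = holobiont.truth.centromeres_rip["F_chr1"]
        retros = [f for f in holobiont.features
                  if f.kind == "retrotransposon" and f.contig_id == "F_chr1"
                  and cen[0] + 5000 <= f.start and f.end <= cen[1] - 5000]
        recs = flank_gc(retros, holobiont.contigs)
        med = np.median([r.gc_5prime for r in recs if r.gc_5prime is not None])
        assert abs(med - holobiont.config.fungal.ripped_gc) <= 3


class TestMetaprofile:
    def test_uniform_contig_flat_profile(self):
        seq = ("ATGC" * 5000)  # exactly 50% GC in any window of length 4k
        cs = ContigSet([Contig("c", seq)])
        # body of 3000 bp -> 60 bp bins, each a whole number of ATGC periods
        mp = metaprofile([FeatureRecord("c", 9_000, 12_000, "+", "gene")], cs)
        means = mp.column_means
        assert mp.matrix.shape[1] == 50 + 50 + 50
        finite = means[~np.isnan(means)]
        np.testing.assert_allclose(finite, 50.0, atol=1e-9)

    def test_strand_reversal_flips_row(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 40_000))
        cs = ContigSet([Contig("c", seq)])
        plus = metaprofile([FeatureRecord("c", 18_000, 21_000, "+", "gene")], cs)
        minus = metaprofile([FeatureRecord("c", 18_000, 21_000, "-", "gene")], cs)
        np.testing.assert_allclose(minus.matrix[0], plus.matrix[0][::-1], atol=1e-9)

    def test_gene_vs_retro_body_contrast(self, holobiont):
        genes = [f for f in holobiont.features
                 if f.kind == "gene" and f.contig_id == "F_chr1"][:30]
        cen = holobiont.truth.centromeres_rip["F_chr1"]
        retros = [f for f in holobiont.features
                  if f.kind == "retrotransposon" and f.contig_id == "F_chr1"
                  and f.start >= cen[0] and f.end <= cen[1]][:15]
        g_body = np.nanmean(metaprofile(genes, holobiont.contigs).column_means[50:100])
        r_body = np.nanmean(metaprofile(retros, holobiont.contigs).column_means[50:100])
        assert abs(g_body - holobiont.config.fungal.genic_gc) <= 3
        assert abs(r_body - holobiont.config.fungal.ripped_gc) <= 3


class TestRipBlocks:
    def _classification(self, labels_by_contig):
        labels = {c: np.array(v) for c, v in labels_by_contig.items()}
        return RipClassification(500, 35.0, labels, 0.0, 1.0)

    def test_no_ripped_windows_no_blocks(self):
        assert rip_blocks(self._classification({"c": ["unripped"] * 300})) == []

    def test_one_centromere_call_per_fungal_chromosome(self, holobiont):
        fungal = ContigSet([holobiont.contigs[f"F_chr{i}"] for i in range(1, 5)])
        blocks = rip_blocks(classify_windows(fungal, 35.0))
        for cid, truth_iv in holobiont.truth.centromeres_rip.items():
            calls = [b for b in blocks if b.contig_id == cid and b.centromere_call]
            assert len(calls) == 1
            b = calls[0]
            inter = max(0, min(b.end, truth_iv[1]) - max(b.start, truth_iv[0]))
            assert inter / max(b.length, truth_iv[1] - truth_iv[0]) >= 0.95

    def test_two_blocks_larger_flagged(self):
        lab = (["unripped"] * 20 + ["ripped"] * 600 + ["unripped"] * 40
               + ["ripped"] * 160 + ["unripped"] * 20)
        blocks = rip_blocks(self._classification({"c": lab}))
        assert len(blocks) == 2
        assert [b.centromere_call for b in sorted(blocks, key=lambda b: -b.length)] == [True, False]

    def test_merge_gap_bridges_small_interruptions(self):
        lab = ["ripped"] * 60 + ["unripped"] * 2 + ["ripped"] * 60
        (block,) = rip_blocks(self._classification({"c": lab}))
        assert (block.start, block.end) == (0, 61_000)


class TestTeFamilyRanking:
    def test_descending_sort(self):
        cs = ContigSet([Contig("c", "G" * 1000 + "GCAT" * 250 + ("GCTATATATA" * 100))])
        feats = [
            FeatureRecord("c", 0, 1000, "+", "retrotransposon", "fam"),
            FeatureRecord("c", 1000, 2000, "+", "retrotransposon", "fam"),
            FeatureRecord("c", 2000, 3000, "+", "retrotransposon", "fam"),
        ]
        ranked = te_family_gc_ranking(feats, cs)
        assert ranked["fam"] == sorted(ranked["fam"], reverse=True)
        assert ranked["fam"][0] == 100.0

    def test_ripped_family_drops_after_few_unripped_copies(self, holobiont):
        tes = [f for f in holobiont.features
               if f.kind in {"retrotransposon", "dna_transposon"}
               and f.contig_id.startswith("F_")]
        ranked = te_family_gc_ranking(tes, holobiont.contigs)
        retro = ranked["RT_hopper"]
        assert retro[1] - retro[2] >= 15  # sharp drop after the 2 unripped copies
        dta = ranked["DTA_mazu"]
        assert dta[-3] - dta[-2] >= 15  # inverse shape: drop near the tail


class TestRetroDensityCentromeres:
    def test_no_retro_features_flagged(self):
        cs = ContigSet([Contig("c", "ACGT" * 50_000)])
        res = retro_density_centromeres([], cs)
        assert res.loci["c"] == [] and "c" in res.flagged

    def test_one_locus_per_algal_chromosome(self, holobiont):
        algal = ContigSet([holobiont.contigs[f"A_chr{i}"] for i in range(1, 4)])
        retros = [f for f in holobiont.features
                  if f.kind == "retrotransposon" and f.contig_id.startswith("A_")]
        res = retro_density_centromeres(retros, algal)
        assert not res.flagged
        for cid, truth_iv in holobiont.truth.centromeres_retro.items():
            (locus,) = res.loci[cid]
            inter = max(0, min(locus[1], truth_iv[1]) - max(locus[0], truth_iv[0]))
            assert inter / max(locus[1] - locus[0], truth_iv[1] - truth_iv[0]) >= 0.9

    def test_scattered_low_density_copies_yield_no_locus(self):
        cs = ContigSet([Contig("c", "ACGT" * 100_000)])  # 400 kb
        feats = [FeatureRecord("c", p, p + 2_500, "+", "retrotransposon", "fam")
                 for p in range(0, 400_000 - 2_500, 50_000)]  # 5% coverage
        res = retro_density_centromeres(feats, cs)
        assert res.loci["c"] == []
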