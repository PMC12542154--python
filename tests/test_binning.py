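"""Coverage-correlation binning, composition binning and the consensus rule."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from holosplit.binning import (
    BinAssignment,
    bin_stats,
    composition_coverage_bins,
    consensus_bins,
    correlation_matrix,
    hierarchical_bins,
)
from holosplit.kingdom import tetramer_freqs
from holosplit.model import Contig, ContigSet, CoverageTable


def brute_force_pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def _bact_coverage(holobiont, table="mq0"):
    cov = holobiont.coverage_mq0 if table == "mq0" else holobiont.coverage_mq60
    bact = [c for c in cov.contig_ids
            if holobiont.truth.contigs[c]["kingdom"] == "bacteria"
            and holobiont.contigs[c].length >= 10_000]
    return cov.subset(bact), [holobiont.truth.contigs[c]["species"] for c in bact]


class TestCorrelationMatrix:
    def test_identical_rows_perfectly_correlated(self):
        cov = CoverageTable(["a", "b"], ["s1", "s2", "s3"],
                            [[1.0, 5.0, 2.0], [1.0, 5.0, 2.0]])
        cm = correlation_matrix(cov, transform=False)
        assert cm.r[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_rows(self):
        cov = CoverageTable(["a", "b"], ["s1", "s2", "s3"],
                            [[1.0, 5.0, 2.0], [5.0, 1.0, 4.0]])
        cm = correlation_matrix(cov, transform=False)
        assert cm.r[0, 1] == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(0)
        depth = rng.uniform(0, 100, size=(20, 12))
        cov = CoverageTable([f"c{i}" for i in range(20)],
                            [f"s{j}" for j in range(12)], depth)
        cm = correlation_matrix(cov, transform=False)
        for i in range(20):
            for j in range(20):
                exp = brute_force_pearson(depth[i], depth[j])
                assert abs(cm.r[i, j] - exp) < 1e-9

    def test_too_few_samples_rejected(self):
        cov = CoverageTable(["a"], ["s1", "s2"], [[1.0, 2.0]])
        with pytest.raises(ValueError):
            correlation_matrix(cov)

    def test_zero_variance_contig_flagged(self):
        cov = CoverageTable(["a", "b"], ["s1", "s2", "s3"],
                            [[2.0, 2.0, 2.0], [1.0, 5.0, 2.0]])
        cm = correlation_matrix(cov, transform=False)
        assert cm.zero_variance == ["a"]
        assert cm.r[0, 1] == 0.0 and cm.r[0, 0] == 1.0


class TestHierarchicalBins:
    def test_block_diagonal_two_bins(self):
        r = np.array([
            [1.0, 0.95, 0.1, 0.1],
            [0.95, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.97],
            [0.1, 0.1, 0.97, 1.0],
        ])
        from holosplit.binning import CorrelationMatrix

        cm = CorrelationMatrix(["a", "b", "c", "d"], r)
        bins = hierarchical_bins(cm).mapping
        assert bins["a"] == bins["b"] != bins["c"] == bins["d"]

    def test_holobiont_coverage_recovers_species(self, holobiont):
        cov, species = _bact_coverage(holobiont)
        ba = hierarchical_bins(correlation_matrix(cov))
        pred = [ba.mapping.get(c, f"un{i}") for i, c in enumerate(cov.contig_ids)]
        assert adjusted_rand_score(species, pred) >= 0.8

    def test_input_permutation_invariant(self, holobiont):
        cov, _ = _bact_coverage(holobiont)
        base = hierarchical_bins(correlation_matrix(cov)).mapping
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(cov.contig_ids))
        cov_p = CoverageTable([cov.contig_ids[i] for i in perm],
                              cov.sample_ids, cov.depth[perm])
        assert hierarchical_bins(correlation_matrix(cov_p)).mapping == base


class TestCompositionBins:
    def test_two_separated_species_perfect(self, holobiont):
        cov, species = _bact_coverage(holobiont)
        keep = [i for i, s in enumerate(species) if s in ("BacA", "BacB")]
        ids = [cov.contig_ids[i] for i in keep]
        sub = cov.subset(ids)
        profiles = [tetramer_freqs(holobiont.contigs[c]) for c in ids]
        ba = composition_coverage_bins(profiles, sub, k_range=range(1, 5))
        labels = [ba.mapping[c] for c in ids]
        assert adjusted_rand_score([species[i] for i in keep], labels) == 1.0

    def test_single_species_selects_k1(self, holobiont):
        cov, species = _bact_coverage(holobiont)
        ids = [c for c, s in zip(cov.contig_ids, species) if s == "BacA"]
        profiles = [tetramer_freqs(holobiont.contigs[c]) for c in ids]
        ba = composition_coverage_bins(profiles, cov.subset(ids), k_range=range(1, 4))
        assert len(set(ba.mapping.values())) == 1

    def test_six_species_high_agreement(self, holobiont):
        cov, species = _bact_coverage(holobiont)
        profiles = [tetramer_freqs(holobiont.contigs[c]) for c in cov.contig_ids]
        ba = composition_coverage_bins(profiles, cov)
        labels = [ba.mapping[c] for c in cov.contig_ids]
        assert adjusted_rand_score(species, labels) >= 0.8

    def test_empty_k_range_rejected(self, holobiont):
        cov, _ = _bact_coverage(holobiont)
        profiles = [tetramer_freqs(holobiont.contigs[c]) for c in cov.contig_ids]
        with pytest.raises(ValueError):
            composition_coverage_bins(profiles, cov, k_range=[])


def _truth_assignment(species_by_contig, approach_id, corrupt_frac=0.0, seed=0):
    mapping = dict(species_by_contig)
    if corrupt_frac:
        rng = np.random.default_rng(seed)
        cids = sorted(mapping)
        labels = sorted(set(mapping.values()))
        for c in rng.choice(cids, int(corrupt_frac * len(cids)), replace=False):
            mapping[c] = labels[int(rng.integers(len(labels)))]
    return BinAssignment(approach_id, mapping)


class TestConsensus:
    def _species(self, holobiont):
        return {
            c.id: holobiont.truth.contigs[c.id]["species"]
            for c in holobiont.contigs
            if holobiont.truth.contigs[c.id]["kingdom"] == "bacteria"
            and c.length >= 10_000
        }

    def test_identical_assignments_reproduce_input(self, holobiont):
        sp = self._species(holobiont)
        assigns = [_truth_assignment(sp, f"a{i}") for i in range(4)]
        cons = consensus_bins(assigns)
        got = {frozenset(v) for v in cons.bins.values()}
        exp = {frozenset(c for c, s in sp.items() if s == lab) for lab in set(sp.values())}
        assert got == exp and cons.unassigned == []

    def test_single_approach_support_insufficient(self):
        a1 = BinAssignment("a1", {"x": "b1", "y": "b1", "z": "b2"})
        a2 = BinAssignment("a2", {"x": "b1", "y": "b2", "z": "b2"})
        a3 = BinAssignment("a3", {"x": "b9", "y": "b2", "z": "b2"})
        a4 = BinAssignment("a4", {"x": "b3", "y": "b4", "z": "b2"})
        cons = consensus_bins([a1, a2, a3, a4])
        # x/y co-binned only once -> no edge; y/z twice, z alone with y
        assert "x" in cons.unassigned
        assert any({"y", "z"} == set(v) for v in cons.bins.values())

    def test_corrupted_approach_tolerated(self, holobiont):
        """Three faithful approaches out-vote one deliberately corrupted one,
        and every rDNA contig stays in its own species' bin."""
        sp = self._species(holobiont)
        assigns = [_truth_assignment(sp, f"a{i}") for i in range(3)]
        assigns.append(_truth_assignment(sp, "bad", corrupt_frac=0.5, seed=3))
        rdna = set(holobiont.truth.rdna_contigs)
        cons = consensus_bins(assigns, rdna_contigs=rdna, rdna_min_support=3)
        mapping = cons.mapping()
        pred = [mapping.get(c, f"un{i}") for i, c in enumerate(sorted(sp))]
        true = [sp[c] for c in sorted(sp)]
        assert adjusted_rand_score(true, pred) >= 0.9
        for cid, species in holobiont.truth.rdna_contigs.items():
            assert cid in mapping
            peers = {c for c, b in mapping.items() if b == mapping[cid]}
            assert {sp[c] for c in peers if c in sp} == {species}

    def test_idempotent(self, holobiont):
        sp = self._species(holobiont)
        assigns = [_truth_assignment(sp, f"a{i}") for i in range(3)]
        assigns.append(_truth_assignment(sp, "bad", corrupt_frac=0.4, seed=1))
        first = consensus_bins(assigns)
        again = consensus_bins(
            [BinAssignment(f"r{i}", first.mapping()) for i in range(4)]
        )
        assert {frozenset(v) for v in first.bins.values()} == {
            frozenset(v) for v in again.bins.values()
        }

    def test_min_support_monotone_refinement(self, holobiont):
        sp = self._species(holobiont)
        assigns = [_truth_assignment(sp, f"a{i}", corrupt_frac=0.2 * i, seed=i)
                   for i in range(4)]
        loose = consensus_bins(assigns, min_support=2)
        strict = consensus_bins(assigns, min_support=3)
        mapping_loose = loose.mapping()
        for members in strict.bins.values():
            parents = {mapping_loose.get(c) for c in members}
            assert len(parents) == 1 and parents != {None}

    def test_consensus_beats_average_single_approach_across_seeds(self, holobiont):
        """Over 10 perturbation seeds, the consensus partition agrees with
        truth at least as well as the average individual approach in >= 8
        runs: the reason for combining approaches at all.  Each approach
        independently mis-bins 25% of contigs into approach-specific junk
        bins (the fragmentation failure mode of real binners)."""
        sp = self._species(holobiont)
        wins = 0
        cids = sorted(sp)
        true = [sp[c] for c in cids]
        for seed in range(10):
            assigns = []
            for i in range(4):
                rng = np.random.default_rng(100 * seed + i)
                mapping = dict(sp)
                for c in rng.choice(cids, len(cids) // 4, replace=False):
                    mapping[c] = f"junk_a{i}_{c}"
                assigns.append(BinAssignment(f"a{i}", mapping))
            single = np.mean([
                adjusted_rand_score(true, [a.mapping[c] for c in cids])
                for a in assigns
            ])
            cons = consensus_bins(assigns).mapping()
            pred = [cons.get(c, f"un{i}") for i, c in enumerate(cids)]
            wins += adjusted_rand_score(true, pred) >= single
        assert wins >= 8

    def test_min_support_above_n_rejected(self):
        a = BinAssignment("a", {"x": "b1", "y": "b1"})
        with pytest.raises(ValueError):
            consensus_bins([a, a], min_support=3)

    def test_components_match_networkx_oracle(self, holobiont):
        import networkx as nx

        sp = self._species(holobiont)
        assigns = [_truth_assignment(sp, f"a{i}", corrupt_frac=0.3, seed=10 + i)
                   for i in range(4)]
        cons = consensus_bins(assigns)
        g = nx.Graph()
        g.add_nodes_from(sp)
        for (a, b), s in cons.support.items():
            if s >= 2:
                g.add_edge(a, b)
        exp = {frozenset(c) for c in nx.connected_components(g) if len(c) >= 2}
        assert {frozenset(v) for v in cons.bins.values()} == exp


class TestBinStats:
    def test_totals_exact_and_sorted(self):
        contigs = ContigSet([
            Contig("a", "A" * 1_000_000),
            Contig("b", "G" * 500_000),
            Contig("c", "C" * 100),
        ])
        cov = CoverageTable(["a", "b", "c"], ["s1", "s2", "s3"], np.ones((3, 3)))
        from holosplit.binning import ConsensusBins

        cons = ConsensusBins({"bin01": ["a", "b"], "bin02": ["c"]}, [])
        df = bin_stats(cons, contigs, cov)
        assert df.iloc[0]["total_bp"] == 1_500_000
        assert list(df["bin"]) == ["bin01", "bin02"]

    def test_empty_consensus_empty_table(self):
        from holosplit.binning import ConsensusBins

        cov = CoverageTable(["a"], ["s1"], [[1.0]])
        df = bin_stats(ConsensusBins({}, ["a"]), ContigSet([Contig("a", "A")]), cov)
        assert len(df) == 0
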