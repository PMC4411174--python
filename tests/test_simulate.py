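"""Generator behaviour: seeded determinism, distributional properties,
resolution-map bookkeeping and read/ARISA construction guarantees."""

import numpy as np
import pytest

from regiondiv.simulate import (ResolutionSpec, TruthConfig, apply_resolution,
                                default_region_specs, generate_dataset,
                                otu_representative_sequences, region_abundances,
                                sample_otu_table, simulate_arisa,
                                simulate_background_reads,
                                simulate_metacommunity, simulate_reads,
                                simulate_tree, species_master_sequences)
from regiondiv.io import tree_to_newick


def _uniform_config(**kw):
    base = dict(n_species=100, n_lakes=5, sdlog=0.0, lake_sdlog=0.0,
                occupancy=1.0, niche_breadth=None, depth_per_lake=100, seed=1)
    base.update(kw)
    return TruthConfig(**base)


class TestMetacommunity:
    def test_rows_sum_to_one(self):
        meta = simulate_metacommunity(TruthConfig(n_species=80, seed=3))
        assert np.allclose(meta.abundances.sum(axis=1), 1.0)

    def test_seeded_rerun_identical(self):
        a = simulate_metacommunity(TruthConfig(n_species=50, seed=9))
        b = simulate_metacommunity(TruthConfig(n_species=50, seed=9))
        assert np.array_equal(a.abundances, b.abundances)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_degenerate_sdlog_zero_gives_equal_abundances(self):
        meta = simulate_metacommunity(_uniform_config())
        assert np.allclose(meta.abundances, 1.0 / 100)

    def test_lognormal_shape_of_generator(self):
        # sd of log relative abundance is invariant to the per-lake
        # normalisation, so it should match sdlog within sampling error
        cfg = TruthConfig(n_species=10000, n_lakes=2, sdlog=1.0,
                          lake_sdlog=0.0, occupancy=1.0,
                          niche_breadth=None, seed=11)
        meta = simulate_metacommunity(cfg)
        logs = np.log(meta.abundances[0])
        se = 1.0 / np.sqrt(2 * (10000 - 1))  # SE of the SD estimate
        assert abs(logs.std(ddof=1) - 1.0) < 3 * se

    def test_lakes_overlap_but_differ(self):
        meta = simulate_metacommunity(TruthConfig(n_species=200, seed=5))
        occ = meta.occupancy
        shared = (occ[0] & occ[1]).sum()
        assert 0 < shared < occ[0].sum()
        assert not np.array_equal(occ[0], occ[1])

    def test_rejects_tiny_pool(self):
        with pytest.raises(ValueError):
            TruthConfig(n_species=1)


class TestYuleTree:
    def test_two_tips_is_a_cherry(self):
        tree = simulate_tree(2, seed=4)
        tips = list(tree.tips())
        assert len(tips) == 2
        assert all(t.length > 0 for t in tips)

    def test_seeded_rerun_identical_newick(self):
        assert tree_to_newick(simulate_tree(20, seed=7)) == \
            tree_to_newick(simulate_tree(20, seed=7))

    def test_binary_rooted_node_count(self):
        tree = simulate_tree(64, seed=2)
        internal = [n for n in tree.traverse(include_self=True)
                    if not n.is_tip()]
        assert len(internal) == 63

    def test_all_branch_lengths_positive(self):
        tree = simulate_tree(30, seed=8)
        assert all(n.length > 0 for n in tree.traverse(include_self=False))

    def test_rejects_n_below_two(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)


class TestResolution:
    def test_identity_map_when_no_split_no_lump(self):
        tree = simulate_tree(40, seed=1)
        spec = ResolutionSpec("R", split_fraction=0.0, lump_fraction=0.0)
        res = apply_resolution(tree, spec, seed=1)
        assert sorted(res.otu_ids) == sorted(t.name for t in tree.tips())
        assert all(v == [(k, 1.0)] for k, v in res.species_to_otus.items())

    def test_split_half_expected_otu_count(self):
        tree = simulate_tree(100, seed=3)
        spec = ResolutionSpec("R", split_fraction=0.5, lump_fraction=0.0)
        res = apply_resolution(tree, spec, seed=3)
        # binomial expectation 150 +- 3*sqrt(100*0.25) = +-15
        assert abs(len(res.otu_ids) - 150) <= 15

    def test_lump_all_pairs_to_about_half(self):
        tree = simulate_tree(100, seed=5)
        spec = ResolutionSpec("R", split_fraction=0.0, lump_fraction=1.0)
        res = apply_resolution(tree, spec, seed=5)
        # neighbour-pair merging: ~n/2 OTUs, a few leftovers possible
        assert 50 <= len(res.otu_ids) <= 60

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError):
            ResolutionSpec("R", split_fraction=0.7, lump_fraction=0.5)

    def test_map_determinism(self):
        tree = simulate_tree(60, seed=6)
        spec = ResolutionSpec("R", split_fraction=0.3, lump_fraction=0.2)
        a = apply_resolution(tree, spec, seed=6)
        b = apply_resolution(tree, spec, seed=6)
        assert a.otu_ids == b.otu_ids
        assert a.species_to_otus == b.species_to_otus

    def test_allocation_matrix_rows_sum_to_one(self):
        tree = simulate_tree(50, seed=7)
        spec = ResolutionSpec("R", split_fraction=0.4, lump_fraction=0.3)
        res = apply_resolution(tree, spec, seed=7)
        species = [t.name for t in tree.tips()]
        A = res.allocation_matrix(species)
        assert np.allclose(A.sum(axis=1), 1.0)

    def test_region_tree_tips_match_otus(self):
        tree = simulate_tree(50, seed=9)
        spec = ResolutionSpec("R", split_fraction=0.4, lump_fraction=0.2)
        res = apply_resolution(tree, spec, seed=9)
        assert sorted(t.name for t in res.tree.tips()) == sorted(res.otu_ids)

    def test_split_monotonically_increases_expected_richness(self):
        # over many seeds, more splitting means more observed OTUs
        no_split, with_split = [], []
        for seed in range(50):
            tree = simulate_tree(40, seed=seed)
            meta = simulate_metacommunity(TruthConfig(
                n_species=40, n_lakes=3, seed=seed))
            for frac, store in ((0.0, no_split), (0.5, with_split)):
                spec = ResolutionSpec("R", split_fraction=frac)
                res = apply_resolution(tree, spec, seed=seed)
                ab = region_abundances(meta, res, seed=seed)
                table = sample_otu_table(ab, res.otu_ids, meta.lake_ids,
                                         200, seed, region_label="R")
                store.append((table.counts > 0).sum(axis=1).mean())
        assert np.mean(with_split) > np.mean(no_split)


class TestSampling:
    def test_rows_sum_to_depth(self):
        meta = simulate_metacommunity(TruthConfig(n_species=30, seed=2))
        ab = meta.abundances
        t = sample_otu_table(ab, meta.species_ids, meta.lake_ids, 650, 1)
        assert (t.sample_sums() == 650).all()

    def test_single_species_gets_everything(self):
        ab = np.array([[1.0, 0.0, 0.0]])
        t = sample_otu_table(ab, ["a", "b", "c"], ["lake"], 99, 0)
        assert t.counts.tolist() == [[99, 0, 0]]

    def test_large_depth_recovers_proportions(self):
        rng_ab = np.array([[0.5, 0.3, 0.15, 0.05]])
        depth = 100000
        t = sample_otu_table(rng_ab, list("abcd"), ["lake"], depth, 3)
        props = t.counts[0] / depth
        for p_hat, p in zip(props, rng_ab[0]):
            assert abs(p_hat - p) <= 3 * np.sqrt(p * (1 - p) / depth)

    def test_depth_validated(self):
        with pytest.raises(ValueError):
            sample_otu_table(np.array([[1.0]]), ["a"], ["l"], 0, 1)


@pytest.fixture(scope="module")
def read_bundle():
    cfg = TruthConfig(n_species=20, n_lakes=3, depth_per_lake=60, seed=4)
    ds = generate_dataset(cfg)
    spec = cfg.region_specs[0]
    masters = species_master_sequences(
        ds.metacommunity.species_ids, 4,
        forbidden=tuple(s.anchor_11mer for s in cfg.region_specs))
    seqs = otu_representative_sequences(
        ds.resolutions[spec.region_name], masters, spec, 4)
    reads, prov = simulate_reads(ds.tables[spec.region_name], seqs, spec, 4)
    return spec, reads, prov


class TestReads:
    def test_anchor_occurs_exactly_once_per_read(self, read_bundle):
        spec, reads, _ = read_bundle
        anchor = spec.anchor_11mer
        rc = anchor.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        for read in reads:
            fwd, rev = read.sequence.count(anchor), read.sequence.count(rc)
            assert (fwd, rev) in ((1, 0), (0, 1))

    def test_planted_segment_has_trim_length(self, read_bundle):
        spec, _, prov = read_bundle
        assert all(len(seg) == spec.trim_length
                   for _, _, seg in prov.values())

    def test_read_count_matches_table_total(self, read_bundle):
        _, reads, prov = read_bundle
        assert len(reads) == len(prov) == 3 * 60

    def test_seeded_rerun_identical(self):
        cfg = TruthConfig(n_species=10, n_lakes=2, depth_per_lake=20, seed=6)
        ds = generate_dataset(cfg)
        spec = cfg.region_specs[0]
        masters = species_master_sequences(ds.metacommunity.species_ids, 6)
        seqs = otu_representative_sequences(ds.resolutions["V3"], masters,
                                            spec, 6)
        r1, _ = simulate_reads(ds.tables["V3"], seqs, spec, 6)
        r2, _ = simulate_reads(ds.tables["V3"], seqs, spec, 6)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]

    def test_background_reads_are_anchor_free(self):
        anchors = [s.anchor_11mer for s in default_region_specs()]
        bg = simulate_background_reads(200, anchors, seed=5)
        rc = [a.translate(str.maketrans("ACGT", "TGCA"))[::-1]
              for a in anchors]
        for read in bg:
            assert not any(a in read.sequence for a in anchors + rc)


class TestArisaSimulation:
    def test_zero_jitter_richness_equals_true_counts(self):
        cfg = TruthConfig(n_species=40, n_lakes=6, seed=2)
        meta = simulate_metacommunity(cfg)
        profiles, lengths = simulate_arisa(meta, seed=2, jitter=0.0)
        for l, prof in enumerate(profiles):
            assert prof.n_peaks == meta.occupancy[l].sum()
            assert len(set(prof.fragment_lengths)) == prof.n_peaks

    def test_seeded_rerun_identical(self):
        meta = simulate_metacommunity(TruthConfig(n_species=30, seed=3))
        p1, l1 = simulate_arisa(meta, seed=3)
        p2, l2 = simulate_arisa(meta, seed=3)
        assert l1 == l2
        for a, b in zip(p1, p2):
            assert np.array_equal(a.fragment_lengths, b.fragment_lengths)

    def test_species_lengths_on_separated_grid(self):
        meta = simulate_metacommunity(TruthConfig(n_species=50, seed=4))
        _, lengths = simulate_arisa(meta, seed=4)
        vals = np.sort(np.array(list(lengths.values())))
        assert (np.diff(vals) >= 3.0 - 1e-9).all()

    def test_pool_larger_than_grid_rejected(self):
        meta = simulate_metacommunity(TruthConfig(n_species=50, seed=4))
        with pytest.raises(ValueError, match="fragment"):
            simulate_arisa(meta, seed=4, length_range=(200.0, 260.0))


class TestDatasetProvenance:
    def test_every_count_traces_to_one_species(self):
        cfg = TruthConfig(n_species=40, n_lakes=4, depth_per_lake=200, seed=8)
        ds = generate_dataset(cfg)
        for region, res in ds.resolutions.items():
            otu_sources = {}
            for sp, dest in res.species_to_otus.items():
                for otu, frac in dest:
                    otu_sources.setdefault(otu, []).append(sp)
            # every OTU column in the table has at least one source species
            for otu in ds.tables[region].otu_ids:
                assert otu in otu_sources

    def test_tables_row_sums_equal_depth(self):
        cfg = TruthConfig(n_species=30, n_lakes=4, depth_per_lake=123, seed=9)
        ds = generate_dataset(cfg)
        for t in ds.tables.values():
            assert (t.sample_sums() == 123).all()

    def test_same_spec_same_truth_identical_tables(self):
        cfg = TruthConfig(n_species=25, n_lakes=3, depth_per_lake=50, seed=10)
        d1 = generate_dataset(cfg)
        d2 = generate_dataset(cfg)
        for region in d1.tables:
            assert np.array_equal(d1.tables[region].counts,
                                  d2.tables[region].counts)
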