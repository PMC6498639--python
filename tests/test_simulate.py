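import numpy as np
import pytest

from ssdfate.io import count_exons
from ssdfate.simulate import (
    DEFAULT_NEWICK,
    SimulationConfig,
    simulate_annotations_and_divergence,
    simulate_dataset,
    simulate_family_evolution,
    simulate_single_copy_orthologs,
    simulate_trios,
)
from ssdfate.tree import SpeciesTree


def _small(seed=0, **kw):
    kw.setdefault("n_single_copy", 60)
    kw.setdefault("n_trios_per_mechanism", 8)
    return SimulationConfig(seed=seed, **kw)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(rna_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(delta=-1)
        with pytest.raises(ValueError):
            SimulationConfig(gain_rate=-0.1)

    def test_delta_within_noise_warns(self):
        with pytest.warns(UserWarning, match="identifiable"):
            SimulationConfig(sigma_o=1.0, delta=0.5)


class TestOrthologs:
    def test_noiseless_limit_gives_zero_divergence(self):
        f, s, pairs = simulate_single_copy_orthologs(_small(sigma_o=1e-12))
        lf = np.log2(f.data.to_numpy() + 1)
        ls = np.log2(s.data.to_numpy() + 1)
        assert np.allclose(np.linalg.norm(lf - ls, axis=1), 0.0, atol=1e-9)

    def test_mean_divergence_increases_with_noise(self):
        means = []
        for sigma in (0.2, 0.5, 1.0):
            cfg = SimulationConfig(seed=9, n_single_copy=400, sigma_o=sigma)
            f, s, _ = simulate_single_copy_orthologs(cfg)
            lf = np.log2(f.data.to_numpy() + 1)
            ls = np.log2(s.data.to_numpy() + 1)
            means.append(np.linalg.norm(lf - ls, axis=1).mean())
        assert means[0] < means[1] < means[2]

    def test_distance_distribution_shape(self):
        f, s, _ = simulate_single_copy_orthologs(_small(n_single_copy=300))
        d = np.linalg.norm(
            np.log2(f.data.to_numpy() + 1) - np.log2(s.data.to_numpy() + 1), axis=1
        )
        assert np.all(d >= 0) and np.all(np.isfinite(d)) and d.var() > 0

    def test_same_seed_identical(self):
        a = simulate_single_copy_orthologs(_small(seed=4))[0]
        b = simulate_single_copy_orthologs(_small(seed=4))[0]
        assert np.array_equal(a.data.to_numpy(), b.data.to_numpy())


class TestTrios:
    def test_conservation_noiseless_profiles_identical(self):
        cfg = _small(sigma_o=1e-12)
        focal, sister, trios, truth = simulate_trios(cfg)
        for t in trios:
            if truth.mechanism[t.trio_id] != "conservation":
                continue
            a = sister.loc[t.ancestral_gene].to_numpy()
            assert np.allclose(focal.loc[t.copy1].to_numpy(), a, atol=1e-6)
            assert np.allclose(focal.loc[t.copy2].to_numpy(), a, atol=1e-6)

    def test_subfunctionalization_partition_sums_to_ancestor(self):
        cfg = _small(sigma_o=1e-12)
        focal, sister, trios, truth = simulate_trios(cfg)
        for t in trios:
            if truth.mechanism[t.trio_id] != "subfunctionalization":
                continue
            total = focal.loc[t.copy1].to_numpy() + focal.loc[t.copy2].to_numpy()
            assert np.allclose(total, sister.loc[t.ancestral_gene].to_numpy(), atol=1e-5)

    def test_truth_covers_every_trio(self):
        _, _, trios, truth = simulate_trios(_small())
        for t in trios:
            assert t.trio_id in truth.mechanism
            assert truth.parent[t.trio_id] in t.copies


class TestFamilyEvolution:
    def test_zero_rates_leave_all_single_copy(self):
        tree = SpeciesTree.from_newick(DEFAULT_NEWICK, is_path=False)
        cfg = SimulationConfig(seed=1, gain_rate=0.0, loss_rate=0.0)
        table, truth = simulate_family_evolution(tree, cfg, n_families=50)
        assert (table.counts.to_numpy() == 1).all()
        assert not truth.family_event_branch

    def test_duplication_yield_scales_with_gain_rate(self):
        # at low rates the single-gain yield follows n * B * r * (1-r)^(B-1)
        # over the B branches, i.e. is linear in the rate to first order
        tree = SpeciesTree.from_newick(DEFAULT_NEWICK, is_path=False)
        n_branches = len(tree.branches)
        n_fam = 3000
        yields = []
        for rate in (0.002, 0.004):
            cfg = SimulationConfig(seed=2, gain_rate=rate, loss_rate=0.0)
            _, truth = simulate_family_evolution(tree, cfg, n_families=n_fam)
            expected = n_fam * n_branches * rate * (1 - rate) ** (n_branches - 1)
            yields.append(len(truth.family_event_branch))
            assert len(truth.family_event_branch) == pytest.approx(expected, rel=0.2)
        assert yields[1] > yields[0]

    def test_same_seed_identical_table(self):
        tree = SpeciesTree.from_newick(DEFAULT_NEWICK, is_path=False)
        cfg = SimulationConfig(seed=3)
        a, _ = simulate_family_evolution(tree, cfg, n_families=40)
        b, _ = simulate_family_evolution(tree, cfg, n_families=40)
        assert a.counts.equals(b.counts)


class TestAnnotationsAndDivergence:
    def _dataset(self, **kw):
        return simulate_dataset(_small(**kw))

    def test_rna_free_annotation_when_fraction_zero(self):
        ds = self._dataset(rna_fraction=0.0)
        assert "RNA" not in set(ds.truth.duplication_mechanism.values())

    def test_gff3_exon_counts_match_truth(self, tmp_path):
        ds = self._dataset()
        path = tmp_path / "ann.gff3"
        path.write_text(ds.gff3_text)
        genes = [g for t in ds.trios for g in t.copies]
        exons = count_exons(path, genes)
        assert all(exons[g] is not None and exons[g] >= 1 for g in genes)
        for t in ds.trios:
            parent = ds.truth.parent[t.trio_id]
            child = t.copy2 if parent == t.copy1 else t.copy1
            mech = ds.truth.duplication_mechanism[t.trio_id]
            if mech == "RNA":
                assert exons[parent] > 1 and exons[child] == 1
            elif mech == "DNA":
                assert exons[parent] > 1 and exons[child] > 1
            else:
                assert exons[parent] == 1

    def test_uncorrupted_evidence_links_true_parent_everywhere(self):
        ds = self._dataset(evidence_error=0.0)
        for t in ds.trios:
            parent = ds.truth.parent[t.trio_id]
            for ev in ds.evidence:
                assert ev.links(parent, t.ancestral_gene)

    def test_ka_correlation_close_to_target(self):
        cfg = SimulationConfig(seed=5, n_single_copy=60, n_trios_per_mechanism=125)
        ds = simulate_dataset(cfg)
        usable = ds.divergence[ds.divergence.ks < 3]
        assert len(usable) >= 900
        r = np.corrcoef(usable.expression_divergence, usable.ka)[0, 1]
        assert r == pytest.approx(cfg.ka_target_r, abs=0.06)

    def test_saturated_fraction_present(self):
        ds = self._dataset(seed=6)
        assert (ds.divergence.ks >= 3).sum() > 0


class TestDatasetDeterminism:
    def test_full_dataset_reproducible(self):
        a = simulate_dataset(_small(seed=7))
        b = simulate_dataset(_small(seed=7))
        assert np.array_equal(a.focal.data.to_numpy(), b.focal.data.to_numpy())
        assert np.array_equal(a.sister.data.to_numpy(), b.sister.data.to_numpy())
        assert a.gff3_text == b.gff3_text
        assert a.truth.mechanism == b.truth.mechanism
        assert a.divergence.equals(b.divergence)
        assert a.family_table.counts.equals(b.family_table.counts)

    def test_write_is_byte_stable(self, tmp_path):
        a = simulate_dataset(_small(seed=8))
        b = simulate_dataset(_small(seed=8))
        da, db = tmp_path / "a", tmp_path / "b"
        a.write(da)
        b.write(db)
        for f in sorted(da.iterdir()):
            assert (db / f.name).read_bytes() == f.read_bytes()
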