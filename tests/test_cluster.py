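"""Frequency-profile clustering and the gene-annotated shortlist."""

import itertools

import numpy as np
import pandas as pd
import pytest

import pygmyscan as pg
from pygmyscan.errors import ConfigurationError, ValidationError


def _profiles(rows, ids=None, pops=("popA", "popB")):
    rows = np.asarray(rows, dtype=float)
    ids = ids if ids is not None else [f"v{i}" for i in range(len(rows))]
    return pg.FrequencyProfileMatrix(
        pd.DataFrame(rows, index=pd.Index(ids, name="variant_id"),
                     columns=list(pops))
    )


def _annotation(ids, genes=None):
    genes = genes if genes is not None else [f"G{i}" for i in range(len(ids))]
    return pd.DataFrame({"gene": genes, "localization": "CDS"},
                        index=pd.Index(ids, name="variant_id"))


class TestBuildProfiles:
    def test_fully_defined_matrix(self):
        table = pd.DataFrame({"popA": [0.1, 0.9], "popB": [0.2, 0.8]},
                             index=["v0", "v1"])
        prof = pg.build_profiles(table, ["v0", "v1"])
        assert prof.profiles.shape == (2, 2)

    def test_undefined_variant_dropped(self):
        table = pd.DataFrame({"popA": [0.1, np.nan], "popB": [0.2, 0.8]},
                             index=["v0", "v1"])
        prof = pg.build_profiles(table, ["v0", "v1"])
        assert prof.variant_ids == ["v0"]

    def test_empty_intersection_raises(self):
        table = pd.DataFrame({"popA": [np.nan], "popB": [0.8]}, index=["v0"])
        with pytest.raises(ValidationError):
            pg.build_profiles(table, ["v0"])

    def test_planted_variants_show_large_contrast(self, small_cohort):
        freqs = pg.allele_frequencies(small_cohort.genotypes,
                                      small_cohort.manifest)
        prof = pg.build_profiles(freqs, small_cohort.planted_ids)
        # planted at (0.9, 0.1): between-column contrast near 0.8
        assert (prof.contrast() > 0.5).all()


class TestClusterVariants:
    def test_identical_rows_merge_at_zero(self):
        prof = _profiles([[0.5, 0.1], [0.5, 0.1], [0.9, 0.9]])
        dendro = pg.cluster_variants(prof)
        assert dendro.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(dendro.linkage_matrix[0, :2]) == {0.0, 1.0}

    def test_outlier_joins_last_under_complete_linkage(self):
        """Brute-force over 3-leaf topologies: the outlier merges last."""
        rows = np.array([[0.10, 0.10], [0.12, 0.12], [0.90, 0.95]])
        # verify by enumeration that leaf 2 is the farthest from both others
        dists = {
            (i, j): np.linalg.norm(rows[i] - rows[j])
            for i, j in itertools.combinations(range(3), 2)
        }
        closest_pair = min(dists, key=dists.get)
        assert closest_pair == (0, 1)
        dendro = pg.cluster_variants(_profiles(rows))
        assert set(dendro.linkage_matrix[0, :2]) == {0.0, 1.0}

    def test_constant_rows_rejected_under_correlation(self):
        prof = _profiles([[0.5, 0.5], [0.1, 0.9]])
        with pytest.raises(ValidationError):
            pg.cluster_variants(prof, metric="correlation")

    def test_cut_produces_exactly_k_clusters(self):
        rng = np.random.default_rng(8)
        prof = _profiles(rng.uniform(0, 1, size=(40, 3)),
                         pops=("a", "b", "c"))
        dendro = pg.cluster_variants(prof)
        for k in (1, 2, 5, 17, 40):
            labels = dendro.cut(n_clusters=k)
            assert len(np.unique(labels)) == k

    def test_row_permutation_isomorphic(self):
        rng = np.random.default_rng(9)
        rows = rng.uniform(0, 1, size=(25, 2))
        ids = [f"v{i}" for i in range(25)]
        dendro = pg.cluster_variants(_profiles(rows, ids))
        perm = rng.permutation(25)
        dendro_p = pg.cluster_variants(
            _profiles(rows[perm], [ids[i] for i in perm])
        )
        # same multiset of merge heights and identical flat partitions
        assert np.allclose(np.sort(dendro.linkage_matrix[:, 2]),
                           np.sort(dendro_p.linkage_matrix[:, 2]))
        labels = dendro.cut(n_clusters=5)
        labels_p = dendro_p.cut(n_clusters=5)
        part = {frozenset(np.array(ids)[labels == c]) for c in set(labels)}
        part_p = {
            frozenset(np.array([ids[i] for i in perm])[labels_p == c])
            for c in set(labels_p)
        }
        assert part == part_p

    def test_single_variant_rejected(self):
        with pytest.raises(ValidationError):
            pg.cluster_variants(_profiles([[0.1, 0.9]]))

    def test_newick_round_trip_leaf_count(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(10)
        prof = _profiles(rng.uniform(0, 1, size=(12, 2)))
        dendro = pg.cluster_variants(prof)
        tree = Phylo.read(StringIO(dendro.to_newick()), "newick")
        leaves = sorted(t.name for t in tree.get_terminals())
        assert leaves == sorted(prof.variant_ids)


class TestShortlist:
    def test_trivial_cut_returns_all_annotated(self):
        prof = _profiles([[0.1, 0.9], [0.2, 0.3], [0.5, 0.6]])
        dendro = pg.cluster_variants(prof)
        ann = _annotation(["v0", "v1"])  # v2 unannotated
        out = pg.shortlist(dendro, prof, ann, n_clusters=3)
        assert sorted(out["variant_id"]) == ["v0", "v1"]

    def test_no_annotation_warns_and_returns_empty(self):
        prof = _profiles([[0.1, 0.9], [0.2, 0.3]])
        dendro = pg.cluster_variants(prof)
        ann = _annotation([], [])
        with pytest.warns(UserWarning):
            out = pg.shortlist(dendro, prof, ann, n_clusters=2)
        assert out.empty

    def test_cut_cardinality_bound(self):
        rng = np.random.default_rng(11)
        prof = _profiles(rng.uniform(0, 1, size=(60, 2)))
        dendro = pg.cluster_variants(prof)
        ann = _annotation(prof.variant_ids)
        out = pg.shortlist(dendro, prof, ann, n_clusters=29)
        assert len(out) <= 29
        assert (out["contrast"].diff().dropna() <= 1e-12).all()  # sorted desc

    def test_representative_is_max_contrast(self):
        prof = _profiles([[0.4, 0.6], [0.0, 1.0], [0.45, 0.55]])
        dendro = pg.cluster_variants(prof)
        ann = _annotation(["v0", "v1", "v2"])
        out = pg.shortlist(dendro, prof, ann, n_clusters=1)
        assert list(out["variant_id"]) == ["v1"]

    def test_cut_parameter_validation(self):
        prof = _profiles([[0.1, 0.9], [0.2, 0.3]])
        dendro = pg.cluster_variants(prof)
        ann = _annotation(["v0"])
        with pytest.raises(ConfigurationError):
            pg.shortlist(dendro, prof, ann, n_clusters=5)
        with pytest.raises(ConfigurationError):
            pg.shortlist(dendro, prof, ann)

    @staticmethod
    def _has_exact_cluster(Z, target: set, n: int) -> bool:
        """True if some merge in the tree yields exactly the target leaf set."""
        members = {i: {i} for i in range(n)}
        for m, row in enumerate(Z):
            merged = members[int(row[0])] | members[int(row[1])]
            members[n + m] = merged
            if merged == target:
                return True
        return len(target) == 1

    def test_planted_variants_form_a_connected_subtree(self):
        """Planted loci merge into their own subtree before any background
        variant joins, in nearly every seed."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = pg.SimulationConfig(
                n_pop1=40, n_pop2=40, n_variants=200, n_planted=8,
                planted_freqs=(0.95, 0.05), fst_background=0.02,
                missing_rate=0.0, seed=seed,
            )
            cohort = pg.simulate_cohort(cfg)
            freqs = pg.allele_frequencies(cohort.genotypes, cohort.manifest)
            all_ids = list(cohort.genotypes.variants["id"])
            background = [v for v in all_ids if v not in cohort.planted_ids]
            subset = cohort.planted_ids + background[:30]
            prof = pg.build_profiles(freqs, subset)
            dendro = pg.cluster_variants(prof)
            planted_rows = {
                i for i, v in enumerate(prof.variant_ids)
                if v in cohort.planted_ids
            }
            if self._has_exact_cluster(dendro.linkage_matrix, planted_rows,
                                       prof.profiles.shape[0]):
                hits += 1
        assert hits >= 0.9 * n_seeds
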