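"""Readers, dataset assembly, fold plans, negative sampling, external sets."""

import numpy as np
import pytest

from bimpadr.data import (
    BipartiteDataset,
    DrugRecord,
    assemble_dataset,
    build_external_pairset,
    external_drugs_from_matrix,
    load_association_table,
    load_feature_matrix,
    make_drug_folds,
    sample_negatives,
    write_feature_matrix,
)

from conftest import make_toy_dataset


class TestLoadAssociationTable:
    def test_deduplicates_and_resolves_named_columns(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("drug_id\tadr_id\nD1\tA1\nD1\tA1\nD2\tA2\n")
        assert load_association_table(f) == {("D1", "A1"), ("D2", "A2")}
        # swapped column order, same names -> same pair set
        g = tmp_path / "b.tsv"
        g.write_text("adr_id\tdrug_id\nA1\tD1\nA2\tD2\n")
        assert load_association_table(g) == {("D1", "A1"), ("D2", "A2")}

    def test_missing_column_error_names_it(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("drug\tadr_id\nD1\tA1\n")
        with pytest.raises(ValueError, match="drug_id"):
            load_association_table(f)

    def test_empty_file_errors(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("drug_id\tadr_id\n")
        with pytest.raises(ValueError, match="empty"):
            load_association_table(f)

    def test_fixture_pairs_match_hand_listing(self, fixture_tables):
        pairs = load_association_table(fixture_tables["associations"])
        assert pairs == fixture_tables["pairs"]
        assert len(pairs) == 9


class TestLoadFeatureMatrix:
    def test_identity_readback_and_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        mat = rng.standard_normal((3, 7))
        ids = ["D0", "D1", "D2"]
        path = tmp_path / "m.tsv"
        write_feature_matrix(path, ids, mat)
        got_ids, got = load_feature_matrix(path, expected_width=7)
        assert got_ids == ids
        assert np.allclose(got, mat, atol=1e-12)
        # re-serialize and re-read: numerically identical
        path2 = tmp_path / "m2.tsv"
        write_feature_matrix(path2, got_ids, got)
        _, got2 = load_feature_matrix(path2)
        assert np.array_equal(got, got2)

    def test_binary_flag_rejects_fractional_values(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\tb0\tb1\nD0\t0\t0.5\n")
        with pytest.raises(ValueError, match="binary"):
            load_feature_matrix(path, binary=True)

    def test_width_mismatch_errors(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\tb0\tb1\nD0\t0\t1\n")
        with pytest.raises(ValueError, match="expected 3"):
            load_feature_matrix(path, expected_width=3)


class TestAssembleDataset:
    def _inputs(self, fixture_tables):
        pairs = load_association_table(fixture_tables["associations"])
        expr = load_feature_matrix(fixture_tables["expression"])
        fps = load_feature_matrix(fixture_tables["fingerprints"], binary=True)
        adr_gene = load_feature_matrix(fixture_tables["adr_gene"], binary=True)
        return pairs, expr, fps, adr_gene

    def test_fixture_counts(self, fixture_tables):
        pairs, expr, fps, adr_gene = self._inputs(fixture_tables)
        ds, manifest = assemble_dataset(pairs, expr, fps, adr_gene)
        assert ds.n_drugs == 5
        assert ds.n_adrs == 4
        assert len(ds.edges) == 9
        assert manifest["zero_filled_adrs"] == ["A3"]

    def test_zero_fill_gives_zero_gene_vector(self, fixture_tables):
        pairs, expr, fps, adr_gene = self._inputs(fixture_tables)
        ds, _ = assemble_dataset(pairs, expr, fps, adr_gene,
                                 fill_missing_adr=True)
        a3 = next(a for a in ds.adrs if a.adr_id == "A3")
        assert np.array_equal(a3.gene_assoc, np.zeros(fixture_tables["p"]))

    def test_without_fill_missing_adr_is_dropped(self, fixture_tables):
        pairs, expr, fps, adr_gene = self._inputs(fixture_tables)
        ds, manifest = assemble_dataset(pairs, expr, fps, adr_gene,
                                        fill_missing_adr=False)
        assert ds.n_adrs == 3
        assert manifest["dropped_adrs"] == ["A3"]
        # edge conservation: only pairs whose ADR survived remain
        surviving = {(d, a) for d, a in pairs if a != "A3"}
        assert len(ds.edges) == len(surviving)

    def test_unobserved_adr_is_excluded(self, fixture_tables):
        pairs, expr, fps, adr_gene = self._inputs(fixture_tables)
        pairs = {(d, a) for d, a in pairs if a != "A2"}
        ds, _ = assemble_dataset(pairs, expr, fps, adr_gene)
        assert "A2" not in ds.adr_ids

    def test_missing_fingerprint_error_lists_drugs(self, fixture_tables):
        pairs, expr, fps, adr_gene = self._inputs(fixture_tables)
        fps = ([i for i in fps[0] if i != "D2"],
               fps[1][[0, 1, 3, 4]])
        with pytest.raises(ValueError, match="D2"):
            assemble_dataset(pairs, expr, fps, adr_gene)


class TestDrugFolds:
    def test_balanced_partition_sizes(self):
        ds = make_toy_dataset(m=10, n=3)
        plan = make_drug_folds(ds, n_folds=5, seed=0)
        sizes = [len(plan.fold_drugs(f)) for f in range(5)]
        assert sizes == [2] * 5
        ds7 = make_toy_dataset(m=7, n=3)
        plan7 = make_drug_folds(ds7, n_folds=5, seed=0)
        sizes7 = sorted(len(plan7.fold_drugs(f)) for f in range(5))
        assert sizes7 == [1, 1, 1, 2, 2]

    def test_deterministic_per_seed(self):
        ds = make_toy_dataset(m=10, n=3)
        a = make_drug_folds(ds, 5, seed=7).assignment
        b = make_drug_folds(ds, 5, seed=7).assignment
        assert np.array_equal(a, b)

    def test_every_drug_in_exactly_one_fold(self):
        ds = make_toy_dataset(m=13, n=3)
        plan = make_drug_folds(ds, 4, seed=1)
        all_drugs = np.concatenate([plan.fold_drugs(f) for f in range(4)])
        assert sorted(all_drugs.tolist()) == list(range(13))

    def test_invalid_fold_counts_error(self):
        ds = make_toy_dataset(m=4, n=3)
        with pytest.raises(ValueError):
            make_drug_folds(ds, 1)
        with pytest.raises(ValueError):
            make_drug_folds(ds, 5)


class TestSampleNegatives:
    def test_one_to_one_ratio_and_disjointness(self):
        ds = make_toy_dataset(m=8, n=6, seed=3)
        subset = [0, 1, 2, 3]
        ps = sample_negatives(ds, subset, ratio=1.0, seed=5)
        n_pos = sum(1 for i, _ in ds.edges if i in set(subset))
        assert ps.n_positive == n_pos
        assert len(ps) == 2 * n_pos
        neg = {(int(i), int(j)) for i, j, l in
               zip(ps.drug_idx, ps.adr_idx, ps.labels) if l == 0}
        assert neg.isdisjoint(ds.edges)
        assert all(i in set(subset) for i, _ in neg)

    def test_positive_set_is_exactly_subset_edges(self):
        ds = make_toy_dataset(m=8, n=6, seed=3)
        ps = sample_negatives(ds, [2, 5], seed=1)
        pos = {(int(i), int(j)) for i, j, l in
               zip(ps.drug_idx, ps.adr_idx, ps.labels) if l == 1}
        assert pos == {(i, j) for i, j in ds.edges if i in {2, 5}}

    def test_seed_controls_only_the_negatives(self):
        ds = make_toy_dataset(m=8, n=6, seed=3)
        a = sample_negatives(ds, [0, 1], seed=1)
        b = sample_negatives(ds, [0, 1], seed=2)
        pos_a = {(int(i), int(j)) for i, j, l in
                 zip(a.drug_idx, a.adr_idx, a.labels) if l == 1}
        pos_b = {(int(i), int(j)) for i, j, l in
                 zip(b.drug_idx, b.adr_idx, b.labels) if l == 1}
        assert pos_a == pos_b
        c = sample_negatives(ds, [0, 1], seed=1)
        assert np.array_equal(a.drug_idx, c.drug_idx)
        assert np.array_equal(a.adr_idx, c.adr_idx)

    def test_saturated_drug_has_no_negatives(self):
        # a drug linked to every ADR leaves nothing to sample
        ds = make_toy_dataset(m=3, n=4, edges={(0, j) for j in range(4)})
        with pytest.raises(ValueError, match="negatives"):
            sample_negatives(ds, [0], ratio=1.0, seed=0)


class TestExternalPairset:
    def test_cartesian_count_and_labels(self):
        ds = make_toy_dataset(m=5, n=4, seed=2)
        ext = [DrugRecord("X0", fingerprint=np.ones(8)),
               DrugRecord("X1", fingerprint=np.zeros(8))]
        known = {("X0", "A0"), ("X0", "A2"), ("X1", "A3")}
        ps = build_external_pairset(ds, ext, known)
        assert len(ps) == 8
        assert ps.n_positive == 3
        assert ps.provenance == "external"

    def test_empty_known_pairs_all_negative(self):
        ds = make_toy_dataset(m=5, n=4, seed=2)
        ext = [DrugRecord("X0", fingerprint=np.ones(8))]
        ps = build_external_pairset(ds, ext, set())
        assert ps.n_positive == 0
        assert len(ps) == 4

    def test_id_collision_with_modeling_drug_errors(self):
        ds = make_toy_dataset(m=3, n=4, seed=2)
        ext = [DrugRecord("D0", fingerprint=np.ones(8))]
        with pytest.raises(ValueError, match="D0"):
            build_external_pairset(ds, ext, set())

    def test_external_drugs_from_matrix(self):
        ids = ["X0", "X1"]
        mat = np.array([[1.0, 0.0], [0.0, 1.0]])
        ext = external_drugs_from_matrix((ids, mat))
        assert [d.drug_id for d in ext] == ids
        assert ext[0].gene_expression is None


class TestInvariants:
    def test_fold_exclusivity_over_derived_splits(self):
        ds = make_toy_dataset(m=12, n=8, seed=9, density=0.3)
        plan = make_drug_folds(ds, 4, seed=0)
        for fold in range(4):
            test = sample_negatives(ds, plan.fold_drugs(fold), seed=fold,
                                    provenance="test")
            train = sample_negatives(ds, plan.complement_drugs(fold),
                                     seed=100 + fold)
            assert set(test.drug_idx.tolist()).isdisjoint(
                set(train.drug_idx.tolist()))

    def test_duplicate_ids_rejected(self):
        d = DrugRecord("D0", fingerprint=np.ones(2), gene_expression=np.ones(2))
        with pytest.raises(ValueError, match="duplicate drug"):
            BipartiteDataset(drugs=[d, d], adrs=[], edges=set())
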