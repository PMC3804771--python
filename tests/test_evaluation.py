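import numpy as np
import pytest

from cortiparc.evaluation import (
    consolidate_labels,
    dice_by_region,
    vertex_accuracy,
)
from cortiparc.labels import LabelEntry, LabelTable
from cortiparc.mesh import vertex_areas

from conftest import icosphere_mesh


def table_for(ids):
    return LabelTable(
        [LabelEntry(i, f"R{i}", f"region {i}") for i in ids], unlabeled_id=ids[0]
    )


class TestDice:
    def test_identity_gives_ones(self):
        m = icosphere_mesh(2)
        lab = (m.vertices[:, 2] > 0).astype(np.int64)
        rep = dice_by_region(lab, lab, m, table_for([0, 1]))
        assert all(r.dice == pytest.approx(1.0) for r in rep.per_region)

    def test_disjoint_support_zero(self):
        m = icosphere_mesh(2)
        a = (m.vertices[:, 2] > 0).astype(np.int64)
        rep = dice_by_region(a, 1 - a, m, table_for([0, 1]))
        assert all(r.dice == pytest.approx(0.0) for r in rep.per_region)

    def test_worked_example_half(self):
        # region areas 2 and 2 with shared area 1 -> D = 0.5; build labels
        # on a mesh where vertex areas are equal (tetrahedron)
        from cortiparc.mesh import TriangleMesh

        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        tris = np.array([(0, 1, 2), (0, 3, 1), (0, 2, 3), (1, 3, 2)])
        m = TriangleMesh(verts, tris)
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        rep = dice_by_region(a, b, m, table_for([0, 1]))
        assert rep.dice_of(1) == pytest.approx(0.5)

    def test_symmetry_exact(self):
        m = icosphere_mesh(2)
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, m.n_vertices)
        b = rng.integers(0, 4, m.n_vertices)
        t = table_for([0, 1, 2, 3])
        ra = dice_by_region(a, b, m, t)
        rb = dice_by_region(b, a, m, t)
        for x, y in zip(ra.per_region, rb.per_region):
            assert x.dice == y.dice

    def test_label_permutation_invariance(self):
        m = icosphere_mesh(2)
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, m.n_vertices)
        b = rng.integers(0, 3, m.n_vertices)
        perm = {0: 2, 1: 0, 2: 1}
        t = table_for([0, 1, 2])
        r1 = dice_by_region(a, b, m, t)
        pa = np.vectorize(perm.get)(a)
        pb = np.vectorize(perm.get)(b)
        r2 = dice_by_region(pa, pb, m, t)
        for lab in [0, 1, 2]:
            assert r1.dice_of(lab) == r2.dice_of(perm[lab])

    def test_area_bookkeeping(self):
        m = icosphere_mesh(3)
        rng = np.random.default_rng(2)
        a = rng.integers(0, 5, m.n_vertices)
        rep = dice_by_region(a, a, m, table_for([0, 1, 2, 3, 4]))
        total = sum(r.area_a for r in rep.per_region)
        assert total == pytest.approx(vertex_areas(m).sum(), rel=1e-9)

    def test_absent_region_excluded_from_mean(self):
        m = icosphere_mesh(1)
        a = np.zeros(m.n_vertices, dtype=np.int64)
        rep = dice_by_region(a, a, m, table_for([0, 1]))
        assert rep.dice_of(1) is None
        assert rep.mean_dice() == pytest.approx(1.0)

    def test_unknown_label_warns_but_reports(self):
        m = icosphere_mesh(1)
        a = np.zeros(m.n_vertices, dtype=np.int64)
        a[0] = 77
        with pytest.warns(UserWarning):
            rep = dice_by_region(a, a, m, table_for([0]))
        assert rep.dice_of(77) == pytest.approx(1.0)


class TestVertexAccuracy:
    def test_full_agreement(self):
        gold = [np.array([1, 2, 3])] * 4
        acc = vertex_accuracy(gold, gold)
        assert (acc.accuracy == 100.0).all()
        assert acc.histogram[9] == 3 and acc.histogram.sum() == 3

    def test_no_agreement_and_half(self):
        gold = [np.array([1, 1])] * 14
        auto = [np.array([2, 1])] * 7 + [np.array([2, 2])] * 7
        acc = vertex_accuracy(gold, auto)
        assert acc.accuracy[0] == 0.0
        assert acc.accuracy[1] == 50.0
        assert acc.histogram.sum() == 2

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            vertex_accuracy([np.array([1, 2])], [np.array([1, 2, 3])])


class TestConsolidate:
    def test_identity(self):
        lab = np.array([1, 2, 3])
        np.testing.assert_array_equal(
            consolidate_labels(lab, {1: 1, 2: 2, 3: 3}), lab
        )

    def test_merge_adds_areas(self):
        m = icosphere_mesh(2)
        z = m.vertices[:, 2]
        lab = np.where(z > 0.3, 1, np.where(z > -0.3, 2, 3)).astype(np.int64)
        merged = consolidate_labels(lab, {1: 1, 2: 1, 3: 3})
        t = table_for([1, 3])
        rep = dice_by_region(merged, merged, m, t)
        va = vertex_areas(m)
        assert rep.per_region[0].area_a == pytest.approx(va[lab <= 2].sum())

    def test_unmapped_label_rejected(self):
        with pytest.raises(KeyError):
            consolidate_labels(np.array([1, 9]), {1: 1})

    def test_consolidation_cannot_reduce_dice_for_merged_region(self):
        # errors between sub-parts vanish after merging
        m = icosphere_mesh(2)
        z = m.vertices[:, 2]
        gold = np.where(z > 0, 1, 2).astype(np.int64)
        auto = np.where(z > 0.1, 1, 2).astype(np.int64)  # boundary shifted
        mapping = {1: 1, 2: 1}
        d_before = dice_by_region(gold, auto, m, table_for([1, 2])).dice_of(1)
        d_after = dice_by_region(
            consolidate_labels(gold, mapping),
            consolidate_labels(auto, mapping),
            m,
            table_for([1]),
        ).dice_of(1)
        assert d_after >= d_before
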