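"""Gaussian shape engine: analytic overlaps vs grid quadrature, superposition."""
import numpy as np
import pytest

from herbnet.chem import Atom, Molecule
from herbnet.errors import ValidationError
from herbnet.shape import (
    GaussianShape,
    RigidTransform,
    optimize_superposition,
    pair_overlap,
    self_overlap,
    shape_tanimoto,
    to_gaussian_shape,
)
from conftest import random_molecule


def grid_overlap(a: GaussianShape, b: GaussianShape, t: RigidTransform, spacing=0.1, pad=4.0):
    """Independent oracle: product-density quadrature on a regular grid."""
    ac = t.apply(a.centers)
    allc = np.vstack([ac, b.centers])
    lo, hi = allc.min(axis=0) - pad, allc.max(axis=0) + pad
    axes = [np.arange(l, h, spacing) for l, h in zip(lo, hi)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    def density(centers, shape):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
        return (shape.weights * shape.p * np.exp(-shape.alphas * d2)).sum(axis=1)

    return float((density(ac, a) * density(b.centers, b)).sum() * spacing**3)


def single_atom(radius=1.7):
    return Molecule("one", [Atom("C", np.zeros(3), radius)])


class TestShapeConstruction:
    def test_single_atom_gaussian_integral_matches_hard_sphere(self):
        """p (pi/alpha)^{3/2} must equal (4/3) pi R^3; checked by quadrature too."""
        shape = to_gaussian_shape(single_atom(1.7), p=2.7)
        hs = 4.0 / 3.0 * np.pi * 1.7**3
        assert shape.atom_volumes[0] == pytest.approx(hs, rel=1e-12)
        assert hs == pytest.approx(20.58, abs=0.01)
        # quadrature of the Gaussian itself
        xs = np.arange(-8, 8, 0.1)
        pts = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1).reshape(-1, 3)
        rho = shape.p * np.exp(-shape.alphas[0] * (pts**2).sum(axis=1))
        assert rho.sum() * 0.1**3 == pytest.approx(hs, rel=1e-3)

    def test_distant_atoms_keep_unit_weights(self):
        mol = Molecule("far", [Atom("C", np.array([0.0, 0, 0]), 1.7),
                               Atom("C", np.array([100.0, 0, 0]), 1.7)])
        shape = to_gaussian_shape(mol, weighted=True)
        np.testing.assert_allclose(shape.weights, 1.0, atol=1e-9)

    def test_coincident_atoms_shrink_weights(self):
        mol = Molecule("co", [Atom("C", np.zeros(3), 1.7), Atom("C", np.zeros(3), 1.7)])
        shape = to_gaussian_shape(mol, weighted=True)
        assert np.all(shape.weights < 1.0)

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValidationError):
            Atom("C", np.zeros(3), 0.0)


class TestPairOverlap:
    def test_identity_self_case(self):
        s = to_gaussian_shape(single_atom())
        assert pair_overlap(s, s, RigidTransform.identity()) == pytest.approx(self_overlap(s))

    def test_far_separation_vanishes(self):
        a = to_gaussian_shape(single_atom())
        t = RigidTransform(np.array([1.0, 0, 0, 0]), np.array([100.0, 0, 0]))
        assert pair_overlap(a, a, t) < 1e-12

    def test_symmetry_under_inverse_transform(self, rng):
        a = to_gaussian_shape(random_molecule(rng, 4, "a"))
        b = to_gaussian_shape(random_molecule(rng, 5, "b"))
        t = RigidTransform(rng.normal(size=4), rng.normal(size=3))
        fwd = pair_overlap(a, b, t)
        rev = pair_overlap(b, a, t.inverse())
        assert fwd == pytest.approx(rev, rel=1e-9)

    @pytest.mark.parametrize("na,nb,seed", [(1, 1, 0), (3, 3, 1), (3, 4, 2), (6, 5, 3), (2, 6, 4)])
    def test_grid_oracle_equivalence(self, na, nb, seed):
        """Closed form matches 0.1 A quadrature within 2% for small shapes."""
        rng = np.random.default_rng(seed)
        a = to_gaussian_shape(random_molecule(rng, na, "a"))
        b = to_gaussian_shape(random_molecule(rng, nb, "b"))
        t = RigidTransform(rng.normal(size=4), rng.uniform(-1, 1, 3))
        closed = pair_overlap(a, b, t)
        assert closed == pytest.approx(grid_overlap(a, b, t), rel=0.02)

    def test_separation_monotonicity(self):
        a = to_gaussian_shape(single_atom())
        overlaps = [
            pair_overlap(a, a, RigidTransform(np.array([1.0, 0, 0, 0]), np.array([d, 0, 0])))
            for d in np.linspace(0, 5, 12)
        ]
        assert all(x > y for x, y in zip(overlaps, overlaps[1:]))


class TestSuperposition:
    def test_recovers_rigidly_rotated_copy(self, rng):
        mol = random_molecule(rng, 7, "m")
        t = RigidTransform(rng.normal(size=4), np.array([3.0, -2.0, 5.0]))
        moved = mol.transformed(t.apply(mol.coords))
        score = shape_tanimoto(mol, moved)
        assert score.tanimoto >= 0.999

    def test_single_atoms_align_perfectly(self):
        a = Molecule("a", [Atom("C", np.array([5.0, 5, 5]), 1.7)])
        b = Molecule("b", [Atom("C", np.array([-3.0, 0, 9]), 1.7)])
        assert shape_tanimoto(a, b).tanimoto == pytest.approx(1.0, abs=1e-6)

    def test_self_similarity_is_one(self, rng):
        for n in (1, 3, 9):
            mol = random_molecule(rng, n, f"m{n}")
            assert shape_tanimoto(mol, mol).tanimoto == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_of_score(self, rng):
        a = random_molecule(rng, 6, "a")
        b = random_molecule(rng, 8, "b")
        assert shape_tanimoto(a, b).tanimoto == pytest.approx(
            shape_tanimoto(b, a).tanimoto, abs=1e-4
        )

    def test_rigid_motion_invariance(self, rng):
        a = random_molecule(rng, 6, "a")
        b = random_molecule(rng, 7, "b")
        base = shape_tanimoto(a, b).tanimoto
        t = RigidTransform(rng.normal(size=4), rng.uniform(-5, 5, 3))
        moved = shape_tanimoto(
            a.transformed(t.apply(a.coords)), b.transformed(t.apply(b.coords))
        ).tanimoto
        assert moved == pytest.approx(base, abs=1e-6)

    def test_jittered_copy_scores_high(self, rng):
        mol = random_molecule(rng, 10, "m")
        jit = mol.transformed(mol.coords + rng.normal(scale=0.05, size=(10, 3)))
        assert shape_tanimoto(mol, jit).tanimoto > 0.95

    def test_disjoint_decoy_scores_below_random_restart_bound(self, rng):
        """Deterministic starts must match an exhaustive random-restart oracle."""
        a = to_gaussian_shape(random_molecule(rng, 5, "a"))
        b = to_gaussian_shape(random_molecule(rng, 12, "b", scale=2.5))
        det = optimize_superposition(a, b)
        oracle = optimize_superposition(a, b, extra_starts=200, seed=7)
        assert det.tanimoto == pytest.approx(oracle.tanimoto, abs=5e-3)
        assert det.tanimoto < 0.8

    def test_score_bounds_and_consistency(self, rng):
        a = random_molecule(rng, 5, "a")
        b = random_molecule(rng, 6, "b")
        s = shape_tanimoto(a, b)
        assert 0.0 <= s.tanimoto <= 1.0
        assert s.overlap_ab <= min(s.self_a, s.self_b) + 1e-6
        assert s.tanimoto == pytest.approx(
            s.overlap_ab / (s.self_a + s.self_b - s.overlap_ab), abs=1e-9
        )

    def test_transform_reproduces_reported_overlap(self, rng):
        """The returned rigid transform must realize the returned overlap."""
        a = random_molecule(rng, 6, "a")
        b = random_molecule(rng, 6, "b")
        s = shape_tanimoto(a, b)
        sa = to_gaussian_shape(a)
        sb = to_gaussian_shape(b)
        assert pair_overlap(sa, sb, s.transform) == pytest.approx(s.overlap_ab, rel=1e-6)


def test_analytic_gradient_matches_finite_differences(rng):
    from herbnet.shape import _objective

    a = to_gaussian_shape(random_molecule(rng, 4, "a"))
    b = to_gaussian_shape(random_molecule(rng, 5, "b"))
    asum = a.alphas[:, None] + b.alphas[None, :]
    k = a.alphas[:, None] * b.alphas[None, :] / asum
    pref = (a.weights[:, None] * b.weights[None, :]) * (a.p * b.p) * (np.pi / asum) ** 1.5
    x = np.concatenate([rng.normal(size=4), rng.normal(size=3)])
    f0, g = _objective(x, a.centers, b.centers, pref, k, True)
    num = np.empty_like(x)
    eps = 1e-6
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        num[i] = (_objective(xp, a.centers, b.centers, pref, k, True)[0]
                  - _objective(xm, a.centers, b.centers, pref, k, True)[0]) / (2 * eps)
    np.testing.assert_allclose(g, num, rtol=1e-5, atol=1e-7)
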