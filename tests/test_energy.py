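import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from homodel.energy import (
    EnergyModel,
    SplinePotential,
    evaluate_objective,
    spline_pair_energy,
    toy_potential,
)
from homodel.io_formats import Atom, Residue, Structure
from homodel.restraints import DistanceRestraint, RestraintEntry, RestraintSet


def _two_atom_system(distance):
    res = [
        Residue(1, "GLY", (Atom("CA", "C", np.zeros(3)),)),
        Residue(2, "GLY", (Atom("CA", "C", np.array([distance, 0.0, 0.0])),)),
    ]
    return Structure("pair", res)


def _one_restraint(d_t=4.0, sigma=1.0):
    return RestraintSet([
        DistanceRestraint((1, "CA"), (2, "CA"), "CA-CA",
                          (RestraintEntry(1, d_t, sigma, 1.0),))
    ])


class TestEvaluateObjective:
    def test_single_one_sigma_term(self):
        model = _two_atom_system(5.0)
        bd = evaluate_objective(model, _one_restraint(4.0, 1.0), include_physical=False)
        assert bd.f_tot == pytest.approx(1.418939, abs=1e-6)
        assert bd.f_hom == bd.f_tot

    def test_wsp_zero_recovers_two_term_form(self, helix_pair, helix_restraints):
        native, _, _ = helix_pair
        bd = evaluate_objective(native, helix_restraints, toy_potential(), w_sp=0.0)
        assert bd.f_tot == pytest.approx(bd.f_phys + bd.f_hom, abs=1e-9)

    def test_wsp_linearity(self, helix_pair, helix_restraints):
        native, _, _ = helix_pair
        sp = toy_potential()
        bd1 = evaluate_objective(native, helix_restraints, sp, w_sp=1.0)
        bd2 = evaluate_objective(native, helix_restraints, sp, w_sp=2.0)
        assert bd1.f_phys == bd2.f_phys
        assert bd1.f_hom == bd2.f_hom
        assert bd2.f_tot - bd1.f_tot == pytest.approx(bd1.f_sp, rel=1e-9)

    def test_breakdown_identity(self, helix_pair, helix_restraints):
        native, _, _ = helix_pair
        bd = evaluate_objective(native, helix_restraints, toy_potential(), w_sp=0.7)
        assert bd.f_tot == pytest.approx(bd.f_phys + bd.f_hom + 0.7 * bd.f_sp, abs=1e-9)

    def test_missing_restrained_atom_errors(self):
        model = _two_atom_system(5.0)
        bad = RestraintSet([
            DistanceRestraint((1, "CA"), (9, "CA"), "CA-CA",
                              (RestraintEntry(1, 4.0, 1.0, 1.0),))
        ])
        with pytest.raises(ValueError, match="missing"):
            evaluate_objective(model, bad)

    def test_rigid_invariance(self, helix_pair, helix_restraints):
        native, _, _ = helix_pair
        sp = toy_potential()
        bd0 = evaluate_objective(native, helix_restraints, sp, w_sp=0.5)
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
        moved = native.with_coords(native.coords() @ rot.T + np.array([5.0, -3.0, 11.0]))
        bd1 = evaluate_objective(moved, helix_restraints, sp, w_sp=0.5)
        assert abs(bd1.f_tot - bd0.f_tot) <= 1e-8 * max(1.0, abs(bd0.f_tot))

    def test_hom_minimum_at_template_distance(self):
        sigma, d_t = 0.7, 4.0
        vals = {}
        for d in (3.6, 4.0, 4.4):
            bd = evaluate_objective(_two_atom_system(d), _one_restraint(d_t, sigma),
                                    include_physical=False)
            vals[d] = bd.f_hom
        assert vals[4.0] < vals[3.6] and vals[4.0] < vals[4.4]
        assert vals[4.0] == pytest.approx(math.log(sigma * math.sqrt(2 * math.pi)), abs=1e-9)


def _natural_cubic_oracle(xs, ys, x):
    """Independent natural cubic spline evaluation via the second-derivative
    linear system (tridiagonal solve, then piecewise cubic formula)."""
    n = len(xs)
    h = np.diff(xs)
    a = np.zeros((n, n))
    rhs = np.zeros(n)
    a[0, 0] = a[-1, -1] = 1.0
    for i in range(1, n - 1):
        a[i, i - 1] = h[i - 1]
        a[i, i] = 2 * (h[i - 1] + h[i])
        a[i, i + 1] = h[i]
        rhs[i] = 6 * ((ys[i + 1] - ys[i]) / h[i] - (ys[i] - ys[i - 1]) / h[i - 1])
    m = np.linalg.solve(a, rhs)
    k = np.searchsorted(xs, x) - 1
    k = min(max(k, 0), n - 2)
    t = x - xs[k]
    return (
        ys[k]
        + t * ((ys[k + 1] - ys[k]) / h[k] - h[k] * (2 * m[k] + m[k + 1]) / 6)
        + t**2 * m[k] / 2
        + t**3 * (m[k + 1] - m[k]) / (6 * h[k])
    )


class TestSplinePotential:
    def test_beyond_cutoff_is_zero(self):
        sp = toy_potential(cutoff=8.0)
        assert spline_pair_energy(sp, ("CA", "CA"), 9.0) == 0.0

    def test_knot_values_exact(self):
        sp = toy_potential()
        for r in (3.0, 5.25, 7.75):
            assert sp.energy("N", "O", r) == pytest.approx(
                sp._spline("N", "O")(r), abs=1e-12
            )
        # spline passes through its own knots exactly
        vals = sp._spline("N", "O")(sp.knots)
        for x, v in zip(sp.knots[::5], vals[::5]):
            assert sp.energy("N", "O", float(x)) == pytest.approx(float(v), abs=1e-12)

    def test_midpoint_against_independent_oracle(self):
        xs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ys = np.array([4.0, -1.0, -2.0, -0.5, 0.2, 0.0])
        sp = SplinePotential(xs, {("CA", "CA"): ys}, cutoff=6.0)
        x = 2.5  # midpoint of two knots
        assert sp.energy("CA", "CA", x) == pytest.approx(
            _natural_cubic_oracle(xs, ys, x), abs=1e-10
        )

    def test_continuous_at_cutoff(self):
        sp = toy_potential(cutoff=8.0)
        assert abs(sp.energy("SC", "SC", 8.0 - 1e-9)) < 1e-6

    def test_unknown_pair_errors(self):
        sp = toy_potential()
        with pytest.raises(KeyError, match="XX"):
            sp.energy("XX", "CA", 3.0)

    def test_tsv_round_trip(self, tmp_path):
        sp = toy_potential()
        p = tmp_path / "pot.tsv"
        sp.to_tsv(p)
        back = SplinePotential.from_tsv(p)
        for r in (2.0, 4.5, 7.9):
            assert back.energy("N", "SC", r) == pytest.approx(
                sp.energy("N", "SC", r), abs=1e-6
            )


@pytest.fixture(scope="module")
def model(helix_pair, helix_restraints):
    native, _, _ = helix_pair
    return EnergyModel(native, helix_restraints, toy_potential(), w_sp=0.5)


class TestGradients:
    @pytest.mark.parametrize("term", ["phys", "hom", "sp"])
    def test_term_gradients_match_central_differences(self, model, term, helix_pair):
        native, _, _ = helix_pair
        rng = np.random.default_rng(17)
        h = 1e-5
        evaluators = {
            "phys": lambda c: model._phys(c, False)[0],
            "hom": lambda c: model._hom(c, False)[0],
            "sp": lambda c: model._statpot(c, False)[0],
        }
        fn = evaluators[term]
        n_checked = 0
        for trial in range(50):
            x = native.coords() + rng.normal(scale=0.15, size=native.coords().shape)
            grad = model.term_gradients(x)[term]
            # directional derivative along a random unit direction
            v = rng.normal(size=x.shape)
            v /= np.linalg.norm(v)
            fd = (fn(x + h * v) - fn(x - h * v)) / (2 * h)
            an = float(np.sum(grad * v))
            assert an == pytest.approx(fd, rel=1e-4, abs=1e-6)
            # spot-check two individual coordinates
            for i, d in [(int(rng.integers(x.shape[0])), int(rng.integers(3)))
                         for _ in range(2)]:
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                fd1 = (fn(xp) - fn(xm)) / (2 * h)
                assert grad[i, d] == pytest.approx(fd1, rel=1e-4, abs=1e-6)
            n_checked += 1
        assert n_checked == 50

    def test_total_gradient_consistent_with_terms(self, model, helix_pair):
        native, _, _ = helix_pair
        x = native.coords() + 0.1
        terms = model.term_gradients(x)
        total = model.gradient(x)
        np.testing.assert_allclose(
            total, terms["phys"] + terms["hom"] + 0.5 * terms["sp"], atol=1e-10
        )
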