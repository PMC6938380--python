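import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from homodel.quality import (
    GDT_CUTOFFS,
    LDDT_THRESHOLDS,
    QualityReport,
    gdt_ha,
    lddt,
    score_decoys,
    superpose_rmsd,
)
from homodel.synthetic_data import ToySpec, build_native, generate_pair


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(seed)).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return rot, t


class TestSuperposeRmsd:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        rmsd, (rot, t) = superpose_rmsd(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)

    def test_translation_invariance(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        rmsd, _ = superpose_rmsd(pts, pts + np.array([10.0, 0.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_against_scipy_oracle(self):
        # Oracle: scipy's quaternion-based alignment on hand-built sets.
        a = np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5, 2.0, 0], [0.0, 2.0, 1.0]])
        b = np.array([[0.1, 0, 0], [1.4, 0.2, 0], [1.6, 2.1, 0.1], [0.0, 1.9, 0.9]])
        rot_o, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        expected = rssd / np.sqrt(len(a))
        rmsd, _ = superpose_rmsd(a, b)
        assert rmsd == pytest.approx(expected, abs=1e-9)

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            superpose_rmsd(line, line)


def _gdt_bruteforce(model_ca, native_ca, cutoffs=GDT_CUTOFFS):
    """Exhaustive oracle: every 3-residue subset seeds a superposition,
    followed by inlier refinement."""
    from homodel.quality import _kabsch

    n = len(model_ca)
    total = 0.0
    for c in cutoffs:
        best = 0
        for subset in itertools.combinations(range(n), 3):
            sel = np.array(subset)
            for _ in range(10):
                try:
                    rot, t = _kabsch(model_ca[sel], native_ca[sel])
                except np.linalg.LinAlgError:
                    break
                moved = model_ca @ rot.T + t
                inl = np.nonzero(np.linalg.norm(moved - native_ca, axis=1) <= c)[0]
                if inl.size < 3 or np.array_equal(inl, sel):
                    break
                sel = inl
            rot, t = _kabsch(model_ca[sel], native_ca[sel])
            moved = model_ca @ rot.T + t
            best = max(best, int(np.sum(np.linalg.norm(moved - native_ca, axis=1) <= c)))
        total += best / n
    return total / len(cutoffs)


class TestGdtHa:
    def test_identical_structures(self, tiny_native):
        assert gdt_ha(tiny_native, tiny_native) == pytest.approx(1.0)

    def test_all_displaced_scores_zero(self, tiny_native):
        rng = np.random.default_rng(3)
        # scramble: reflect and shuffle so no rigid fit gets within 4 A
        coords = tiny_native.coords()
        scrambled = coords * np.array([-1.0, 1.0, 1.0])
        scrambled = scrambled[::-1] * 3.0 + rng.normal(scale=8.0, size=coords.shape)
        moved = tiny_native.with_coords(scrambled)
        assert gdt_ha(moved, tiny_native) <= 0.45  # no meaningful fit survives

    def test_rigid_invariance(self, tiny_native):
        rot, t = _random_rigid(5)
        moved = tiny_native.with_coords(tiny_native.coords() @ rot.T + t)
        assert gdt_ha(moved, tiny_native) == pytest.approx(1.0, abs=1e-8)

    def test_half_displaced_matches_bruteforce_oracle(self):
        native = build_native(10, "helix", "LEKFDILETK", "n")
        coords = native.coords()
        moved = coords.copy()
        # displace the last 5 residues far away
        start = sum(len(r.atoms) for r in native.residues[:5])
        moved[start:] += np.array([25.0, 13.0, -9.0])
        model = native.with_coords(moved)
        heuristic = gdt_ha(model, native)
        oracle = _gdt_bruteforce(model.ca_coords(), native.ca_coords())
        assert heuristic == pytest.approx(oracle, abs=1e-9)
        assert oracle == pytest.approx(0.5, abs=1e-9)

    def test_noisy_toy_close_to_bruteforce(self):
        native = build_native(10, "hairpin", "LEKFDILETK", "n")
        rng = np.random.default_rng(11)
        model = native.with_coords(
            native.coords() + rng.normal(scale=1.2, size=native.coords().shape)
        )
        heuristic = gdt_ha(model, native)
        oracle = _gdt_bruteforce(model.ca_coords(), native.ca_coords())
        # the heuristic may only miss fits the oracle finds, never invent them
        assert heuristic <= oracle + 1e-9
        assert heuristic >= oracle - 0.06

    def test_at_least_plain_superposition_fraction(self, helix_pair):
        native, templates, _ = helix_pair
        model = templates[0]
        rmsd, (rot, t) = superpose_rmsd(model.ca_coords(), native.ca_coords())
        moved = model.ca_coords() @ rot.T + t
        dist = np.linalg.norm(moved - native.ca_coords(), axis=1)
        plain = np.mean([np.mean(dist <= c) for c in GDT_CUTOFFS])
        assert gdt_ha(model, native) >= plain - 1e-9


class TestLddt:
    def test_identical_structures(self, tiny_native):
        assert lddt(tiny_native, tiny_native) == pytest.approx(1.0)

    def test_rotation_gives_one_without_superposition(self, tiny_native):
        rot, t = _random_rigid(7)
        moved = tiny_native.with_coords(tiny_native.coords() @ rot.T + t)
        assert lddt(moved, tiny_native) == pytest.approx(1.0, abs=1e-8)

    def test_three_atom_toy_against_enumeration(self):
        from homodel.io_formats import Atom, Residue, Structure

        def make(d13):
            res = [
                Residue(1, "GLY", (Atom("CA", "C", np.array([0.0, 0, 0])),)),
                Residue(2, "GLY", (Atom("CA", "C", np.array([4.0, 0, 0])),)),
                Residue(3, "GLY", (Atom("CA", "C", np.array([d13, 3.0, 0])),)),
            ]
            return Structure("t", res)

        native = make(4.0)
        model = make(5.5)  # perturbs distances 1-3 and 2-3
        # Oracle: direct enumeration of the 3 pairs x 4 thresholds.
        pairs_native = {(1, 2): 4.0, (1, 3): 5.0, (2, 3): 3.0}
        pairs_model = {
            (1, 2): 4.0,
            (1, 3): np.hypot(5.5, 3.0),
            (2, 3): np.hypot(1.5, 3.0),
        }
        hits = 0
        for t in LDDT_THRESHOLDS:
            for k in pairs_native:
                if abs(pairs_model[k] - pairs_native[k]) < t:
                    hits += 1
        expected = hits / (len(pairs_native) * len(LDDT_THRESHOLDS))
        assert lddt(model, native) == pytest.approx(expected, abs=1e-9)

    def test_score_range(self, helix_pair):
        native, templates, _ = helix_pair
        val = lddt(templates[0], native)
        assert 0.0 <= val <= 1.0


class TestQualityReport:
    def test_decoy_average_is_arithmetic_mean(self, helix_pair):
        native, templates, _ = helix_pair
        report = score_decoys([templates[0], native], native)
        assert report.mean_gdt_ha == pytest.approx(np.mean(report.gdt_ha_scores))
        assert min(report.gdt_ha_scores) <= report.mean_gdt_ha <= max(report.gdt_ha_scores)
        assert all(0 <= g <= 1 for g in report.gdt_ha_scores)
        assert all(0 <= l <= 1 for l in report.lddt_scores)
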