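"""Composite modeling objective and its analytic gradient.

F_TOT = F_PHYS + F_HOM + w_SP * F_SP, where

* F_PHYS is a simplified stereochemical stand-in: harmonic bonds, harmonic
  bond angles, and a quadratic soft-sphere repulsion between non-bonded
  atoms (no attractive non-bonded physics);
* F_HOM sums -ln of each restraint's Gaussian-mixture density;
* F_SP is a knowledge-based pairwise term tabulated per coarse atom-type
  pair and evaluated with interpolating cubic splines inside an 8 A contact
  shell (0 beyond it).

The weights on F_PHYS and F_HOM are fixed at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from homodel.io_formats import Structure
from homodel.restraints import RestraintSet

__all__ = [
    "ObjectiveBreakdown", "SplinePotential", "EnergyModel",
    "evaluate_objective", "spline_pair_energy", "toy_potential",
    "IDEAL_BOND_LENGTHS", "IDEAL_ANGLES",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

# Idealized internal geometry shared with the synthetic generator, so a
# freshly generated native sits at the stereochemical minimum.
IDEAL_BOND_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("C", "N"): 1.329,   # peptide bond to the next residue
    ("CA", "CB"): 1.530,
    ("CB", "CG"): 1.520,
}

IDEAL_ANGLES = {  # degrees
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "O"): 120.8,
    ("CA", "C", "N"): 116.2,
    ("O", "C", "N"): 123.0,
    ("C", "N", "CA"): 121.7,
    ("N", "CA", "CB"): 110.5,
    ("C", "CA", "CB"): 110.1,
    ("CA", "CB", "CG"): 114.0,
}

K_BOND = 100.0   # 1/A^2
K_ANGLE = 20.0   # 1/rad^2
K_REPULSE = 10.0

_VDW_RADII = {"N": 1.55, "C": 1.70, "O": 1.52, "S": 1.80}
_SOFT_SCALE = 0.8  # repulsion engages below this fraction of the vdW sum

_COARSE_TYPES = ("N", "CA", "C", "O", "SC")


def atom_coarse_type(atom_name: str) -> str:
    return atom_name if atom_name in ("N", "CA", "C", "O") else "SC"


@dataclass(frozen=True)
class ObjectiveBreakdown:
    f_phys: float
    f_hom: float
    f_sp: float
    w_sp: float

    @property
    def f_tot(self) -> float:
        return self.f_phys + self.f_hom + self.w_sp * self.f_sp


class SplinePotential:
    """Pairwise statistical potential on a uniform knot grid, spline form.

    Terms are cubic interpolating splines (natural boundary conditions)
    through per-pair knot energies; evaluation beyond ``cutoff`` returns 0.
    """

    def __init__(
        self,
        knots: np.ndarray,
        energies: dict[tuple[str, str], np.ndarray],
        cutoff: float = 8.0,
    ):
        knots = np.asarray(knots, dtype=float)
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knot distances must be strictly increasing")
        self.knots = knots
        self.cutoff = float(cutoff)
        self._splines: dict[tuple[str, str], CubicSpline] = {}
        for pair, e in energies.items():
            key = tuple(sorted(pair))
            self._splines[key] = CubicSpline(knots, np.asarray(e, dtype=float), bc_type="natural")

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._splines)

    def _spline(self, type_a: str, type_b: str) -> CubicSpline:
        key = tuple(sorted((type_a, type_b)))
        if key not in self._splines:
            raise KeyError(f"no potential term for atom-type pair {key}")
        return self._splines[key]

    def energy(self, type_a: str, type_b: str, r: float | np.ndarray):
        sp = self._spline(type_a, type_b)
        r = np.asarray(r, dtype=float)
        val = np.where(r <= self.cutoff, sp(np.minimum(r, self.cutoff)), 0.0)
        return float(val) if val.ndim == 0 else val

    def denergy(self, type_a: str, type_b: str, r: float | np.ndarray):
        sp = self._spline(type_a, type_b).derivative()
        r = np.asarray(r, dtype=float)
        val = np.where(r <= self.cutoff, sp(np.minimum(r, self.cutoff)), 0.0)
        return float(val) if val.ndim == 0 else val

    def to_tsv(self, path: str | Path) -> None:
        lines = ["type_a\ttype_b\tknot_A\tenergy"]
        for (a, b), sp in sorted(self._splines.items()):
            for x, e in zip(self.knots, sp(self.knots)):
                lines.append(f"{a}\t{b}\t{x:.4f}\t{e:.8f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, cutoff: float = 8.0) -> "SplinePotential":
        lines = Path(path).read_text().splitlines()
        if lines[0].split("\t") != ["type_a", "type_b", "knot_A", "energy"]:
            raise ValueError(f"{path}: unexpected header")
        table: dict[tuple[str, str], list[tuple[float, float]]] = {}
        for line in lines[1:]:
            if not line.strip():
                continue
            a, b, x, e = line.split("\t")
            table.setdefault(tuple(sorted((a, b))), []).append((float(x), float(e)))
        knots = None
        energies = {}
        for pair, rows in table.items():
            rows.sort()
            xs = np.array([x for x, _ in rows])
            if knots is None:
                knots = xs
            elif not np.allclose(knots, xs):
                raise ValueError(f"{path}: pair {pair} has a different knot grid")
            energies[pair] = np.array([e for _, e in rows])
        return cls(knots, energies, cutoff=cutoff)


def spline_pair_energy(sp: SplinePotential, type_pair: tuple[str, str], r: float) -> float:
    """Spline energy for one atom-type pair at distance ``r`` (0 past cutoff)."""
    if r <= 0:
        raise ValueError(f"distance must be positive, got {r}")
    return sp.energy(type_pair[0], type_pair[1], r)


def toy_potential(cutoff: float = 8.0, knot_step: float = 0.25) -> SplinePotential:
    """Built-in smooth well per coarse-type pair: repulsive core, contact
    minimum, and a value and slope of exactly 0 at the cutoff."""
    contact_radius = {"N": 1.6, "CA": 1.9, "C": 1.8, "O": 1.5, "SC": 2.0}
    knots = np.arange(knot_step, cutoff + knot_step / 2, knot_step)
    energies = {}
    for i, a in enumerate(_COARSE_TYPES):
        for b in _COARSE_TYPES[i:]:
            r0 = contact_radius[a] + contact_radius[b]
            eps = 0.5

            def well(r):
                x = r0 / r
                return eps * (x**4 - 2.0 * x**2)

            def dwell(r):
                x = r0 / r
                return eps * (-4.0 * x**4 + 4.0 * x**2) / r

            e = well(knots) - well(cutoff) - dwell(cutoff) * (knots - cutoff)
            energies[(a, b)] = e
    return SplinePotential(knots, energies, cutoff=cutoff)


def _bond_list(structure: Structure) -> list[tuple[int, int, float]]:
    """(i, j, ideal length) over the reduced-topology covalent bonds."""
    index = {}
    k = 0
    for r in structure.residues:
        for a in r.atoms:
            index[(r.index, a.name)] = k
            k += 1
    bonds = []

    def add(ri, a, rj, b):
        key_i, key_j = (ri, a), (rj, b)
        if key_i in index and key_j in index:
            ideal = IDEAL_BOND_LENGTHS.get((a, b)) or IDEAL_BOND_LENGTHS.get((b, a))
            if ideal is not None:
                bonds.append((index[key_i], index[key_j], ideal))

    residues = structure.residues
    for n, r in enumerate(residues):
        add(r.index, "N", r.index, "CA")
        add(r.index, "CA", r.index, "C")
        add(r.index, "C", r.index, "O")
        add(r.index, "CA", r.index, "CB")
        add(r.index, "CB", r.index, "CG")
        if n + 1 < len(residues):
            add(r.index, "C", residues[n + 1].index, "N")
    return bonds


class EnergyModel:
    """Precompiled evaluator for F_TOT and its gradient on one topology."""

    def __init__(
        self,
        topology: Structure,
        restraints: RestraintSet | None = None,
        sp: SplinePotential | None = None,
        w_sp: float = 0.0,
        include_physical: bool = True,
    ):
        if w_sp < 0:
            raise ValueError("w_sp must be >= 0")
        self.topology = topology
        self.sp = sp
        self.w_sp = float(w_sp)
        self.include_physical = include_physical

        self._atom_index: dict[tuple[int, str], int] = {}
        names: list[str] = []
        elements: list[str] = []
        for r in topology.residues:
            for a in r.atoms:
                self._atom_index[(r.index, a.name)] = len(names)
                names.append(a.name)
                elements.append(a.element)
        self.n_atoms = len(names)

        bonds = _bond_list(topology)
        self._bond_i = np.array([b[0] for b in bonds], dtype=int)
        self._bond_j = np.array([b[1] for b in bonds], dtype=int)
        self._bond_r0 = np.array([b[2] for b in bonds], dtype=float)

        # Angles: every bonded path a-b-c with a known ideal value.
        adj: dict[int, list[int]] = {k: [] for k in range(self.n_atoms)}
        for i, j, _ in bonds:
            adj[i].append(j)
            adj[j].append(i)
        ang = []
        for j in range(self.n_atoms):
            nb = adj[j]
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    a, c = nb[x], nb[y]
                    key = (names[a], names[j], names[c])
                    ideal = IDEAL_ANGLES.get(key) or IDEAL_ANGLES.get(key[::-1])
                    if ideal is not None:
                        ang.append((a, j, c, math.radians(ideal)))
        self._ang = np.array([(a, j, c) for a, j, c, _ in ang], dtype=int).reshape(-1, 3)
        self._ang_theta0 = np.array([t for *_, t in ang], dtype=float)

        # Bond-separation <= 2 exclusions, then the non-bonded pair list.
        excluded: set[tuple[int, int]] = set()
        for i, j, _ in bonds:
            excluded.add((min(i, j), max(i, j)))
        for j in range(self.n_atoms):
            nb = adj[j]
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    a, c = nb[x], nb[y]
                    excluded.add((min(a, c), max(a, c)))
        nb_i, nb_j = [], []
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                if (i, j) not in excluded:
                    nb_i.append(i)
                    nb_j.append(j)
        self._nb_i = np.array(nb_i, dtype=int)
        self._nb_j = np.array(nb_j, dtype=int)
        rad = np.array([_VDW_RADII.get(e.upper(), 1.7) for e in elements])
        self._nb_r0 = _SOFT_SCALE * (rad[self._nb_i] + rad[self._nb_j])

        # Statistical-potential typing: group non-bonded pairs by type pair.
        self._sp_groups: list[tuple[tuple[str, str], np.ndarray]] = []
        if sp is not None:
            types = np.array([atom_coarse_type(n) for n in names])
            keys = [tuple(sorted((types[i], types[j]))) for i, j in zip(self._nb_i, self._nb_j)]
            uniq = sorted(set(keys))
            arr = np.array([uniq.index(k) for k in keys])
            for u, key in enumerate(uniq):
                self._sp_groups.append((key, np.nonzero(arr == u)[0]))

        # Restraint arrays: zero-weight entries drop out of the mixture.
        self._rest_i = np.zeros(0, dtype=int)
        self._rest_j = np.zeros(0, dtype=int)
        self._ent_rest = np.zeros(0, dtype=int)
        self._ent_logw = np.zeros(0)
        self._ent_dt = np.zeros(0)
        self._ent_sig = np.zeros(0)
        self.n_restraints = 0
        if restraints is not None and len(restraints):
            ri, rj, er, ew, edt, esg = [], [], [], [], [], []
            for k, r in enumerate(restraints):
                for ref in (r.atom_i, r.atom_j):
                    if ref not in self._atom_index:
                        raise ValueError(f"restrained atom {ref} missing from model topology")
                ri.append(self._atom_index[r.atom_i])
                rj.append(self._atom_index[r.atom_j])
                live = [e for e in r.entries if e.weight > 0]
                if not live:
                    raise ValueError("restraint has no non-zero-weight entries")
                for e in live:
                    er.append(k)
                    ew.append(math.log(e.weight))
                    edt.append(e.d_t)
                    esg.append(e.sigma)
            self._rest_i = np.array(ri, dtype=int)
            self._rest_j = np.array(rj, dtype=int)
            self._ent_rest = np.array(er, dtype=int)
            self._ent_logw = np.array(ew)
            self._ent_dt = np.array(edt)
            self._ent_sig = np.array(esg)
            self.n_restraints = len(restraints)
            self._seg_starts = np.flatnonzero(
                np.r_[True, np.diff(self._ent_rest) != 0]
            )

    # -- term evaluation ---------------------------------------------------

    def _hom(self, coords: np.ndarray, want_grad: bool):
        grad = np.zeros_like(coords) if want_grad else None
        if self.n_restraints == 0:
            return 0.0, grad
        diff = coords[self._rest_i] - coords[self._rest_j]
        d = np.linalg.norm(diff, axis=1)
        dev = d[self._ent_rest] - self._ent_dt
        loglik = (
            self._ent_logw - np.log(self._ent_sig) - _LOG_SQRT_2PI
            - dev**2 / (2.0 * self._ent_sig**2)
        )
        seg_max = np.maximum.reduceat(loglik, self._seg_starts)
        shifted = np.exp(loglik - seg_max[self._ent_rest])
        seg_sum = np.add.reduceat(shifted, self._seg_starts)
        f = -float(np.sum(seg_max + np.log(seg_sum)))
        if want_grad:
            # dF/dd_r = sum_e softmax_e * (d - d_t,e) / sigma_e^2
            contrib = shifted * dev / self._ent_sig**2
            dfdd = np.add.reduceat(contrib, self._seg_starts) / seg_sum
            unit = diff / np.maximum(d, 1e-12)[:, None]
            g = dfdd[:, None] * unit
            np.add.at(grad, self._rest_i, g)
            np.add.at(grad, self._rest_j, -g)
        return f, grad

    def _phys(self, coords: np.ndarray, want_grad: bool):
        grad = np.zeros_like(coords) if want_grad else None
        f = 0.0
        if not self.include_physical:
            return f, grad
        if self._bond_i.size:
            diff = coords[self._bond_i] - coords[self._bond_j]
            d = np.linalg.norm(diff, axis=1)
            dev = d - self._bond_r0
            f += float(K_BOND * np.sum(dev**2))
            if want_grad:
                g = (2.0 * K_BOND * dev / np.maximum(d, 1e-12))[:, None] * diff
                np.add.at(grad, self._bond_i, g)
                np.add.at(grad, self._bond_j, -g)
        if self._ang.size:
            a, j, c = self._ang[:, 0], self._ang[:, 1], self._ang[:, 2]
            u = coords[a] - coords[j]
            v = coords[c] - coords[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            cos = np.clip(np.sum(uh * vh, axis=1), -1.0 + 1e-10, 1.0 - 1e-10)
            theta = np.arccos(cos)
            dev = theta - self._ang_theta0
            f += float(K_ANGLE * np.sum(dev**2))
            if want_grad:
                sin = np.sqrt(1.0 - cos**2)
                coeff = 2.0 * K_ANGLE * dev
                ga = coeff[:, None] * (cos[:, None] * uh - vh) / (nu * sin)[:, None]
                gc = coeff[:, None] * (cos[:, None] * vh - uh) / (nv * sin)[:, None]
                np.add.at(grad, a, ga)
                np.add.at(grad, c, gc)
                np.add.at(grad, j, -(ga + gc))
        if self._nb_i.size:
            diff = coords[self._nb_i] - coords[self._nb_j]
            d = np.linalg.norm(diff, axis=1)
            pen = np.maximum(self._nb_r0 - d, 0.0)
            f += float(K_REPULSE * np.sum(pen**2))
            if want_grad:
                g = (-2.0 * K_REPULSE * pen / np.maximum(d, 1e-12))[:, None] * diff
                np.add.at(grad, self._nb_i, g)
                np.add.at(grad, self._nb_j, -g)
        return f, grad

    def _statpot(self, coords: np.ndarray, want_grad: bool):
        grad = np.zeros_like(coords) if want_grad else None
        if self.sp is None or not self._nb_i.size:
            return 0.0, grad
        diff = coords[self._nb_i] - coords[self._nb_j]
        d = np.linalg.norm(diff, axis=1)
        f = 0.0
        for key, idx in self._sp_groups:
            r = d[idx]
            inside = r <= self.sp.cutoff
            if not np.any(inside):
                continue
            sub = idx[inside]
            f += float(np.sum(self.sp.energy(key[0], key[1], d[sub])))
            if want_grad:
                de = self.sp.denergy(key[0], key[1], d[sub])
                g = (de / np.maximum(d[sub], 1e-12))[:, None] * diff[sub]
                np.add.at(grad, self._nb_i[sub], g)
                np.add.at(grad, self._nb_j[sub], -g)
        return f, grad

    # -- public API --------------------------------------------------------

    def evaluate(self, coords: np.ndarray) -> ObjectiveBreakdown:
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        f_phys, _ = self._phys(coords, False)
        f_hom, _ = self._hom(coords, False)
        f_sp, _ = self._statpot(coords, False)
        return ObjectiveBreakdown(f_phys, f_hom, f_sp, self.w_sp)

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        _, g1 = self._phys(coords, True)
        _, g2 = self._hom(coords, True)
        _, g3 = self._statpot(coords, True)
        return g1 + g2 + self.w_sp * g3

    def term_gradients(self, coords: np.ndarray) -> dict[str, np.ndarray]:
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return {
            "phys": self._phys(coords, True)[1],
            "hom": self._hom(coords, True)[1],
            "sp": self._statpot(coords, True)[1],
        }

    def value_and_grad(self, flat: np.ndarray) -> tuple[float, np.ndarray]:
        coords = flat.reshape(self.n_atoms, 3)
        f_phys, g1 = self._phys(coords, True)
        f_hom, g2 = self._hom(coords, True)
        f_sp, g3 = self._statpot(coords, True)
        f = f_phys + f_hom + self.w_sp * f_sp
        return f, (g1 + g2 + self.w_sp * g3).ravel()


def evaluate_objective(
    model: Structure,
    restraints: RestraintSet | None,
    sp: SplinePotential | None = None,
    w_sp: float = 0.0,
    include_physical: bool = True,
) -> ObjectiveBreakdown:
    """One-shot F_TOT breakdown for a model conformation."""
    em = EnergyModel(model, restraints, sp, w_sp, include_physical)
    return em.evaluate(model.coords())
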