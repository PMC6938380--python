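"""Model building: initialization, CG minimization and seeded annealing.

The refinement stage is a Metropolis annealing on Cartesian coordinates
(collective moves, temperature-scaled step sizes) between two conjugate-
gradient phases; the final stage is always a zero-temperature quench, so
the returned conformation never scores worse than the starting one. Builds
abort when the total objective exceeds a configurable ceiling, which is how
quasi-singular (unfloored) sigma values manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from homodel.energy import EnergyModel, ObjectiveBreakdown, SplinePotential
from homodel.io_formats import JoinedAlignment, Structure
from homodel.restraints import RestraintSet
from homodel.synthetic_data import _ANGLE, _BOND, _place

__all__ = [
    "OptimizationProtocol", "ObjectiveCeilingError", "DecoySet",
    "initialize_model", "optimize", "generate_decoys",
]


class ObjectiveCeilingError(RuntimeError):
    """The total objective surpassed the allowed ceiling; build stopped."""

    def __init__(self, value: float, ceiling: float):
        super().__init__(
            f"total objective {value:.6g} exceeds the allowed ceiling {ceiling:.6g}"
        )
        self.value = value
        self.ceiling = ceiling


@dataclass
class OptimizationProtocol:
    name: str = "very_fast"
    cg_iterations: int = 300
    schedule: tuple[tuple[float, int], ...] = ((5.0, 40), (1.5, 40), (0.0, 40))
    seed: int = 0
    objective_ceiling: float | None = None  # default: 1e4 per restraint

    def __post_init__(self):
        if any(t < 0 for t, _ in self.schedule):
            raise ValueError("temperatures must be non-negative")
        if self.schedule and self.schedule[-1][0] != 0.0:
            raise ValueError("the final annealing stage must be a zero-temperature quench")

    @classmethod
    def very_fast(cls, seed: int = 0, **kw) -> "OptimizationProtocol":
        return cls(name="very_fast", seed=seed, **kw)

    @classmethod
    def slow(cls, seed: int = 0) -> "OptimizationProtocol":
        # ~3.4x the very_fast annealing length, mirroring the duration ratio
        # of the two reference refinement protocols.
        sched = tuple((round(5.0 * (0.62**k), 3), 40) for k in range(9)) + ((0.0, 48),)
        return cls(name="slow", cg_iterations=400, schedule=sched, seed=seed)

    @property
    def total_steps(self) -> int:
        return sum(s for _, s in self.schedule)


@dataclass
class DecoySet:
    decoys: list[Structure]
    traces: list[list[tuple[str, ObjectiveBreakdown]]]
    n_failed: int = 0


def initialize_model(
    aln: JoinedAlignment,
    templates: Sequence[Structure],
    topology: Structure,
    seed: int = 0,
    jitter: float = 0.15,
) -> Structure:
    """Initial model coordinates from the highest-coverage template.

    Aligned residues copy the template's equivalent atoms (matched by name);
    unaligned residues and atoms missing from the template are placed by
    extending the backbone with ideal geometry plus seeded jitter, so decoys
    started from different seeds differ slightly everywhere.
    """
    from homodel.io_formats import residue_correspondence

    rng = np.random.default_rng(seed)
    coverages = [len(pw.match_columns) for pw in aln.pairwise]
    if max(coverages) == 0:
        raise ValueError("no aligned residues in any template")
    best = int(np.argmax(coverages))
    pw, tmpl = aln.pairwise[best], templates[best]
    res_map = dict(residue_correspondence(pw, topology, tmpl))
    tmpl_atoms = {(r.index, a.name): a.position for r in tmpl.residues for a in r.atoms}

    placed: dict[tuple[int, str], np.ndarray] = {}
    residues = topology.residues
    for r in residues:
        tr = res_map.get(r.index)
        if tr is None:
            continue
        for a in r.atoms:
            pos = tmpl_atoms.get((tr, a.name))
            if pos is not None:
                placed[(r.index, a.name)] = pos.copy()

    def backbone_complete(res) -> bool:
        return all((res.index, n) in placed for n in ("N", "CA", "C"))

    # Forward pass: extend missing residues/atoms from the previous backbone.
    for k, r in enumerate(residues):
        prev = residues[k - 1] if k > 0 else None
        have_prev = prev is not None and backbone_complete(prev)
        if not backbone_complete(r):
            if have_prev:
                pn = placed[(prev.index, "N")]
                pca = placed[(prev.index, "CA")]
                pc = placed[(prev.index, "C")]
                n = _place(pn, pca, pc, _BOND["C-N"], _ANGLE["CA-C-N"], -47.0)
                ca = _place(pca, pc, n, _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
                c = _place(pc, n, ca, _BOND["CA-C"], _ANGLE["N-CA-C"], -57.0)
                placed[(r.index, "N")], placed[(r.index, "CA")], placed[(r.index, "C")] = n, ca, c
            else:
                # Leading run with no anchor yet: copy topology-local geometry
                # around an arbitrary origin; the quench will settle it.
                base = r.atom("CA").position
                offset = rng.normal(scale=0.5, size=3)
                for a in r.atoms:
                    placed.setdefault((r.index, a.name), a.position - base + offset)
        # Fill remaining atoms from ideal geometry off the backbone.
        n = placed.get((r.index, "N"))
        ca = placed.get((r.index, "CA"))
        c = placed.get((r.index, "C"))
        for a in r.atoms:
            key = (r.index, a.name)
            if key in placed:
                continue
            if a.name == "O" and c is not None:
                placed[key] = _place(n, ca, c, _BOND["C-O"], _ANGLE["CA-C-O"], 133.0)
            elif a.name == "CB":
                placed[key] = _place(c, n, ca, _BOND["CA-CB"], _ANGLE["N-CA-CB"], -122.6)
            elif a.name == "CG" and (r.index, "CB") in placed:
                placed[key] = _place(n, ca, placed[(r.index, "CB")],
                                     _BOND["CB-CG"], _ANGLE["CA-CB-CG"], -60.0)
            else:
                placed[key] = ca + rng.normal(scale=0.5, size=3)
    coords = np.array([placed[(r.index, a.name)] for r in residues for a in r.atoms])
    coords += rng.uniform(-jitter, jitter, size=coords.shape)
    return topology.with_coords(coords)


def _default_ceiling(n_restraints: int) -> float:
    return 1e4 * max(1, n_restraints)


def optimize(
    model: Structure,
    restraints: RestraintSet | None,
    sp: SplinePotential | None = None,
    w_sp: float = 0.0,
    protocol: OptimizationProtocol | None = None,
    include_physical: bool = True,
) -> tuple[Structure, list[tuple[str, ObjectiveBreakdown]]]:
    """CG minimization, Metropolis annealing, final CG quench.

    Returns the optimized structure and a per-phase objective trace. Raises
    :class:`ObjectiveCeilingError` if F_TOT exceeds the protocol ceiling.
    """
    protocol = protocol or OptimizationProtocol()
    em = EnergyModel(model, restraints, sp, w_sp, include_physical)
    ceiling = protocol.objective_ceiling
    if ceiling is None:
        ceiling = _default_ceiling(em.n_restraints)
    rng = np.random.default_rng(protocol.seed)

    x = model.coords().ravel().copy()
    trace: list[tuple[str, ObjectiveBreakdown]] = []

    def check(label: str, flat: np.ndarray) -> ObjectiveBreakdown:
        bd = em.evaluate(flat)
        if not np.isfinite(bd.f_tot) or bd.f_tot > ceiling:
            raise ObjectiveCeilingError(bd.f_tot, ceiling)
        trace.append((label, bd))
        return bd

    initial = check("initial", x)

    def cg(flat: np.ndarray, label: str) -> np.ndarray:
        res = minimize(
            em.value_and_grad, flat, jac=True, method="CG",
            options={"maxiter": protocol.cg_iterations, "gtol": 1e-4},
        )
        out = res.x if res.fun <= em.value_and_grad(flat)[0] else flat
        check(label, out)
        return out

    x = cg(x, "cg1")
    best = x.copy()
    best_f = em.value_and_grad(x)[0]

    f_cur = best_f
    for temp, steps in protocol.schedule:
        move = 0.05 + 0.25 * temp / (1.0 + temp)
        for _ in range(steps):
            prop = x + rng.normal(scale=move, size=x.shape)
            f_prop, _ = em.value_and_grad(prop)
            d = f_prop - f_cur
            if d <= 0 or (temp > 0 and rng.random() < np.exp(-d / temp)):
                x, f_cur = prop, f_prop
                if f_cur < best_f:
                    best, best_f = x.copy(), f_cur
        check(f"anneal_T{temp:g}", x)

    x = cg(x, "quench")
    f_final = em.value_and_grad(x)[0]
    if best_f < f_final:
        x, f_final = best, best_f
    if f_final > initial.f_tot:  # contract: never return worse than start
        x = model.coords().ravel()
    final = check("final", x)
    if final.f_tot > ceiling:
        raise ObjectiveCeilingError(final.f_tot, ceiling)
    return model.with_coords(x.reshape(-1, 3)), trace


def generate_decoys(
    aln: JoinedAlignment,
    templates: Sequence[Structure],
    topology: Structure,
    restraints: RestraintSet | None,
    sp: SplinePotential | None = None,
    w_sp: float = 0.0,
    protocol: OptimizationProtocol | None = None,
    n_decoys: int = 16,
    base_seed: int = 0,
) -> DecoySet:
    """Build ``n_decoys`` independently initialized and optimized models.

    Decoy k uses seed ``base_seed + k`` for both initialization and
    optimization; failed builds (ceiling aborts) are recorded, and at least
    one decoy must succeed.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    protocol = protocol or OptimizationProtocol()
    out = DecoySet([], [])
    for k in range(n_decoys):
        seed = base_seed + k
        start = initialize_model(aln, templates, topology, seed=seed)
        proto_k = OptimizationProtocol(
            name=protocol.name, cg_iterations=protocol.cg_iterations,
            schedule=protocol.schedule, seed=seed,
            objective_ceiling=protocol.objective_ceiling,
        )
        try:
            structure, trace = optimize(start, restraints, sp, w_sp, proto_k)
        except ObjectiveCeilingError:
            out.n_failed += 1
            continue
        out.decoys.append(structure)
        out.traces.append(trace)
    if not out.decoys:
        raise ObjectiveCeilingError(float("inf"), protocol.objective_ceiling or float("inf"))
    return out
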