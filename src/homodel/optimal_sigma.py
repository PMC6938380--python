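"""Optimal restraint parameters from a known native structure.

The sigma that maximizes the likelihood of recovering the native distance is
|native distance - template distance|, floored at 0.05 A so near-identical
distances do not produce quasi-singular harmonic terms. For multi-template
restraints the optimal parameterization additionally puts all mixture weight
on the template with the smallest (floored) sigma ("only-lowest").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from homodel.io_formats import Structure
from homodel.restraints import (
    DistanceRestraint,
    RestraintEntry,
    RestraintSet,
    template_weights,
)

__all__ = [
    "SIGMA_FLOOR", "SigmaRecord", "SigmaProfile",
    "optimal_sigma_single", "optimal_multi_params", "sigma_profile",
    "apply_optimal_parameters",
]

SIGMA_FLOOR = 0.05  # Angstrom


@dataclass(frozen=True)
class SigmaRecord:
    atom_i: tuple[int, str]
    atom_j: tuple[int, str]
    group: str
    template_indices: tuple[int, ...]
    abs_deltas: tuple[float, ...]       # raw |d_n - d_t| per template, Angstrom
    signed_deltas: tuple[float, ...]    # d_n - d_t per template, Angstrom
    applied_sigmas: tuple[float, ...]   # floored values actually deployed


@dataclass
class SigmaProfile:
    """Per-restraint optimal-sigma records plus per-group observed means."""

    records: list[SigmaRecord]

    @property
    def group_means(self) -> dict[str, float]:
        """Mean applied sigma (m_obs) per group, on the floored values."""
        sums: dict[str, list[float]] = {}
        for rec in self.records:
            sums.setdefault(rec.group, []).extend(rec.applied_sigmas)
        return {g: float(np.mean(v)) for g, v in sums.items() if v}

    def deltas_by_group(self, group: str, template_index: int = 1) -> np.ndarray:
        """Signed native-minus-template deltas for one group and template."""
        out = [
            rec.signed_deltas[rec.template_indices.index(template_index)]
            for rec in self.records
            if rec.group == group and template_index in rec.template_indices
        ]
        return np.asarray(out, dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["group\tres_i\tatom_i\tres_j\tatom_j\tu\tdelta\tsigma"]
        for rec in self.records:
            for u, d, s in zip(rec.template_indices, rec.signed_deltas, rec.applied_sigmas):
                lines.append(
                    f"{rec.group}\t{rec.atom_i[0]}\t{rec.atom_i[1]}"
                    f"\t{rec.atom_j[0]}\t{rec.atom_j[1]}\t{u}\t{d:.6f}\t{s:.6f}"
                )
        Path(path).write_text("\n".join(lines) + "\n")


def optimal_sigma_single(d_n: float, d_t: float, floor: float = SIGMA_FLOOR) -> float:
    """max(|d_n - d_t|, floor): the likelihood-maximizing Gaussian sigma."""
    if d_n <= 0 or d_t <= 0:
        raise ValueError(f"distances must be positive, got d_n={d_n}, d_t={d_t}")
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    return max(abs(d_n - d_t), floor)


def _native_distance(native: Structure, restraint: DistanceRestraint) -> float:
    try:
        res_i = native.residue_by_index(restraint.atom_i[0])
        res_j = native.residue_by_index(restraint.atom_j[0])
        a = res_i.atom(restraint.atom_i[1])
        b = res_j.atom(restraint.atom_j[1])
    except KeyError as exc:
        raise ValueError(f"restrained atom absent from native structure: {exc}") from exc
    return float(np.linalg.norm(a.position - b.position))


def optimal_multi_params(
    native: Structure, restraint: DistanceRestraint, floor: float = SIGMA_FLOOR
) -> DistanceRestraint:
    """Rewrite a restraint with per-template optimal sigmas and OL weights.

    The floor is applied before the argmin, so two templates both below the
    floor tie and the lower template index wins.
    """
    d_n = _native_distance(native, restraint)
    sigmas = [optimal_sigma_single(d_n, e.d_t, floor) for e in restraint.entries]
    weights = template_weights("only_lowest", sigmas=sigmas)
    entries = [
        RestraintEntry(e.template_index, e.d_t, s, w)
        for e, s, w in zip(restraint.entries, sigmas, weights)
    ]
    return restraint.with_entries(entries)


def sigma_profile(
    native: Structure,
    restraints: RestraintSet,
    floor: float = SIGMA_FLOOR,
) -> tuple[RestraintSet, SigmaProfile]:
    """Apply optimal parameters to every restraint and record the profile."""
    new_restraints = []
    records = []
    for r in restraints:
        d_n = _native_distance(native, r)
        raw = [d_n - e.d_t for e in r.entries]
        updated = optimal_multi_params(native, r, floor)
        new_restraints.append(updated)
        records.append(
            SigmaRecord(
                r.atom_i, r.atom_j, r.group,
                tuple(e.template_index for e in r.entries),
                tuple(abs(d) for d in raw),
                tuple(raw),
                tuple(e.sigma for e in updated.entries),
            )
        )
    return RestraintSet(new_restraints, provenance=restraints.provenance), SigmaProfile(records)


# Backwards-friendly alias used by the experiment layer.
apply_optimal_parameters = sigma_profile
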