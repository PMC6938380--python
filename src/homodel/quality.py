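"""Model quality assessment: superposition RMSD, GDT-HA and lDDT.

GDT-HA averages, over the 0.5/1/2/4 A cutoffs, the largest fraction of CA
atoms that fit simultaneously under some rigid superposition (found
heuristically from contiguous-fragment seeds with iterative extension).
lDDT is superposition-free: it averages, over the same thresholds, the
fraction of native interatomic distances (inter-residue, within a 15 A
inclusion radius) preserved by the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from homodel.io_formats import Structure

__all__ = [
    "GDT_CUTOFFS", "LDDT_THRESHOLDS", "LDDT_INCLUSION_RADIUS",
    "QualityReport", "superpose_rmsd", "gdt_ha", "lddt", "score_decoys",
]

GDT_CUTOFFS = (0.5, 1.0, 2.0, 4.0)       # Angstrom
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)   # Angstrom
LDDT_INCLUSION_RADIUS = 15.0             # Angstrom


def _kabsch(mobile: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with fixed ~ mobile @ R.T + t."""
    cm = mobile.mean(axis=0)
    cf = fixed.mean(axis=0)
    h = (mobile - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cf - rot @ cm
    return rot, t


def superpose_rmsd(
    model_ca: np.ndarray, native_ca: np.ndarray
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Optimal rigid superposition RMSD of two corresponded point sets."""
    model_ca = np.asarray(model_ca, dtype=float)
    native_ca = np.asarray(native_ca, dtype=float)
    if model_ca.shape != native_ca.shape or model_ca.ndim != 2 or model_ca.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    if model_ca.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    if np.linalg.matrix_rank(model_ca - model_ca.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, t = _kabsch(model_ca, native_ca)
    moved = model_ca @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - native_ca) ** 2, axis=1))))
    return rmsd, (rot, t)


def _corresponded_ca(model: Structure, native: Structure) -> tuple[np.ndarray, np.ndarray]:
    common = sorted(
        set(r.index for r in model.residues) & set(r.index for r in native.residues)
    )
    if not common:
        raise ValueError("no residues in common between model and native")
    m = np.array([model.residue_by_index(i).atom("CA").position for i in common])
    n = np.array([native.residue_by_index(i).atom("CA").position for i in common])
    return m, n


def _max_fit_fraction(model_ca, native_ca, cutoff, fragment_lengths=(3, 5, 7),
                      max_iter=10, exhaustive_below=13):
    n = model_ca.shape[0]
    seeds: list[np.ndarray] = [np.arange(n)]
    for fl in fragment_lengths:
        for start in range(0, max(1, n - fl + 1)):
            seeds.append(np.arange(start, min(start + fl, n)))
    if n < exhaustive_below:
        import itertools as _it
        seeds.extend(np.array(c) for c in _it.combinations(range(n), 3))
    else:
        rng = np.random.default_rng(0)  # fixed: scoring must be deterministic
        for _ in range(4 * n):
            seeds.append(rng.choice(n, size=3, replace=False))
    best = 0
    for seed in seeds:
        if seed.size < 3:
            continue
        sel = seed
        for _ in range(max_iter):
            try:
                rot, t = _kabsch(model_ca[sel], native_ca[sel])
            except np.linalg.LinAlgError:
                break
            moved = model_ca @ rot.T + t
            dist = np.linalg.norm(moved - native_ca, axis=1)
            inliers = np.nonzero(dist <= cutoff)[0]
            if inliers.size >= 3:
                if inliers.size == sel.size and np.array_equal(inliers, sel):
                    break
                sel = inliers
            else:
                break
        rot, t = _kabsch(model_ca[sel], native_ca[sel])
        moved = model_ca @ rot.T + t
        count = int(np.sum(np.linalg.norm(moved - native_ca, axis=1) <= cutoff))
        best = max(best, count)
    return best / n


def gdt_ha(model: Structure, native: Structure, cutoffs: Sequence[float] = GDT_CUTOFFS) -> float:
    """High-accuracy global distance test score in [0, 1]."""
    m, n = _corresponded_ca(model, native)
    if m.shape[0] < 4:
        raise ValueError("GDT-HA needs at least 4 corresponded residues")
    return float(np.mean([_max_fit_fraction(m, n, c) for c in cutoffs]))


def lddt(
    model: Structure,
    native: Structure,
    thresholds: Sequence[float] = LDDT_THRESHOLDS,
    inclusion_radius: float = LDDT_INCLUSION_RADIUS,
) -> float:
    """Superposition-free local distance difference test in [0, 1].

    Distance-only variant over all corresponded heavy-atom pairs from
    different residues whose native distance is within the inclusion radius.
    """
    coords_m = []
    coords_n = []
    res_of = []
    lookup_n = {}
    for r in native.residues:
        for a in r.atoms:
            lookup_n[(r.index, a.name)] = a.position
    for r in model.residues:
        for a in r.atoms:
            key = (r.index, a.name)
            if key in lookup_n:
                coords_m.append(a.position)
                coords_n.append(lookup_n[key])
                res_of.append(r.index)
    cm = np.asarray(coords_m)
    cn = np.asarray(coords_n)
    res_of = np.asarray(res_of)
    dm = np.linalg.norm(cm[:, None, :] - cm[None, :, :], axis=-1)
    dn = np.linalg.norm(cn[:, None, :] - cn[None, :, :], axis=-1)
    iu, ju = np.triu_indices(len(cm), k=1)
    keep = (res_of[iu] != res_of[ju]) & (dn[iu, ju] <= inclusion_radius)
    if not np.any(keep):
        raise ValueError("no qualifying atom pairs inside the inclusion radius")
    diff = np.abs(dm[iu, ju][keep] - dn[iu, ju][keep])
    fracs = [float(np.mean(diff < t)) for t in thresholds]
    return float(np.mean(fracs))


@dataclass
class QualityReport:
    """Per-decoy scores plus decoy averages."""

    gdt_ha_scores: list[float] = field(default_factory=list)
    lddt_scores: list[float] = field(default_factory=list)
    rmsd_scores: list[float] = field(default_factory=list)
    n_failed: int = 0

    @property
    def mean_gdt_ha(self) -> float:
        return float(np.mean(self.gdt_ha_scores))

    @property
    def mean_lddt(self) -> float:
        return float(np.mean(self.lddt_scores))

    @property
    def mean_rmsd(self) -> float:
        return float(np.mean(self.rmsd_scores))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["decoy\tgdt_ha\tlddt\tca_rmsd"]
        for k, (g, l, r) in enumerate(
            zip(self.gdt_ha_scores, self.lddt_scores, self.rmsd_scores), start=1
        ):
            lines.append(f"{k}\t{g:.4f}\t{l:.4f}\t{r:.4f}")
        lines.append(
            f"average\t{self.mean_gdt_ha:.4f}\t{self.mean_lddt:.4f}\t{self.mean_rmsd:.4f}"
        )
        Path(path).write_text("\n".join(lines) + "\n")


def score_decoys(decoys: Sequence[Structure], native: Structure) -> QualityReport:
    """Score every decoy against the native and aggregate decoy averages."""
    report = QualityReport()
    for d in decoys:
        m, n = _corresponded_ca(d, native)
        rmsd, _ = superpose_rmsd(m, n)
        report.gdt_ha_scores.append(gdt_ha(d, native))
        report.lddt_scores.append(lddt(d, native))
        report.rmsd_scores.append(rmsd)
    return report
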