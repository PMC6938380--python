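"""Homology-derived distance restraints (HDDRs).

Restraints are built for four atom groups — CA-CA, backbone N-O, side
chain/main chain (SCMC) and side chain/side chain (SCSC) — from a joined
target-templates alignment plus template coordinates. Each restraint holds
one (d_t, sigma, weight) entry per covering template; its probability
density is the weighted Gaussian mixture over those entries and its
objective-function term is the negative log of that density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from homodel.io_formats import (
    BACKBONE_ATOMS,
    JoinedAlignment,
    PairwiseAlignment,
    Structure,
    residue_correspondence,
)

__all__ = [
    "AtomRef", "RestraintEntry", "DistanceRestraint", "RestraintSet",
    "GROUPS", "DEFAULT_CUTOFFS", "DEFAULT_MIN_SEPARATION",
    "build_hddrs", "gaussian_objective_term", "mixture_density",
    "template_weights", "local_similarity_profile",
]

GROUPS = ("CA-CA", "N-O", "SCMC", "SCSC")

#: Template-distance ceilings per group (Angstrom). Explicit config: the
#: upstream defaults are not published, so these are logged wherever used.
DEFAULT_CUTOFFS = {"CA-CA": 14.0, "N-O": 11.0, "SCMC": 6.5, "SCSC": 6.5}

#: Minimum sequence separation |i - j| between the two restrained residues.
#: Bonded/near-bonded geometry is handled by the stereochemical terms.
DEFAULT_MIN_SEPARATION = {"CA-CA": 2, "N-O": 2, "SCMC": 1, "SCSC": 1}

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

AtomRef = tuple[int, str]  # (1-based residue index, atom name)


@dataclass(frozen=True)
class RestraintEntry:
    template_index: int   # u, 1-based position in the joined alignment
    d_t: float            # template distance, Angstrom
    sigma: float          # standard deviation, Angstrom
    weight: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.d_t <= 0:
            raise ValueError(f"d_t must be > 0, got {self.d_t}")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must lie in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class DistanceRestraint:
    atom_i: AtomRef
    atom_j: AtomRef
    group: str
    entries: tuple[RestraintEntry, ...]

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown restraint group {self.group!r}")
        if self.atom_i == self.atom_j:
            raise ValueError("restraint must connect two distinct atoms")
        if not self.entries:
            raise ValueError("restraint needs at least one template entry")
        total = sum(e.weight for e in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"entry weights must sum to 1, got {total}")

    @property
    def n_templates(self) -> int:
        return len(self.entries)

    def with_entries(self, entries: Sequence[RestraintEntry]) -> "DistanceRestraint":
        return DistanceRestraint(self.atom_i, self.atom_j, self.group, tuple(entries))

    def objective(self, d_m: float) -> float:
        """-ln of the mixture density at model distance ``d_m``."""
        dens = mixture_density(
            d_m, [(e.weight, e.d_t, e.sigma) for e in self.entries]
        )
        if dens <= 0.0:
            return math.inf
        return -math.log(dens)


@dataclass
class RestraintSet:
    restraints: list[DistanceRestraint]
    provenance: str = ""

    def __post_init__(self):
        seen: set[tuple[str, frozenset[AtomRef]]] = set()
        for r in self.restraints:
            key = (r.group, frozenset((r.atom_i, r.atom_j)))
            if key in seen:
                raise ValueError(
                    f"duplicate restraint in group {r.group} on atoms {r.atom_i}, {r.atom_j}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    @property
    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in GROUPS}
        for r in self.restraints:
            counts[r.group] += 1
        return counts

    def by_group(self, group: str) -> list[DistanceRestraint]:
        return [r for r in self.restraints if r.group == group]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["group\tres_i\tatom_i\tres_j\tatom_j\tu\td_t\tsigma\tw"]
        for r in self.restraints:
            for e in r.entries:
                lines.append(
                    f"{r.group}\t{r.atom_i[0]}\t{r.atom_i[1]}\t{r.atom_j[0]}\t{r.atom_j[1]}"
                    f"\t{e.template_index}\t{e.d_t:.6f}\t{e.sigma:.6f}\t{e.weight:.9f}"
                )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RestraintSet":
        lines = Path(path).read_text().splitlines()
        header = lines[0].split("\t")
        expected = ["group", "res_i", "atom_i", "res_j", "atom_j", "u", "d_t", "sigma", "w"]
        if header != expected:
            raise ValueError(f"{path}: unexpected header {header}")
        grouped: dict[tuple, list[RestraintEntry]] = {}
        order: list[tuple] = []
        for line in lines[1:]:
            if not line.strip():
                continue
            g, ri, ai, rj, aj, u, dt, sg, w = line.split("\t")
            key = (g, (int(ri), ai), (int(rj), aj))
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            grouped[key].append(RestraintEntry(int(u), float(dt), float(sg), float(w)))
        restraints = [
            DistanceRestraint(key[1], key[2], key[0], tuple(grouped[key])) for key in order
        ]
        return cls(restraints, provenance=str(path))


def gaussian_objective_term(d_m: float, d_t: float, sigma: float) -> float:
    """Harmonic objective term: -ln of a Gaussian density at ``d_m``.

    Equals ``(d_m - d_t)^2 / (2 sigma^2) + ln(sigma sqrt(2 pi))``; minimized
    at ``d_m == d_t`` and a deviation of exactly one sigma adds exactly 1/2.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return (d_m - d_t) ** 2 / (2.0 * sigma**2) + math.log(sigma) + _LOG_SQRT_2PI


def mixture_density(d_m: float, entries: Iterable[tuple[float, float, float]]) -> float:
    """Weighted Gaussian mixture density at ``d_m``.

    ``entries`` holds (weight, d_t, sigma) triples; weights must sum to 1.
    """
    entries = list(entries)
    w = np.array([e[0] for e in entries], dtype=float)
    d_t = np.array([e[1] for e in entries], dtype=float)
    sig = np.array([e[2] for e in entries], dtype=float)
    if np.any(sig <= 0):
        raise ValueError("all sigma values must be > 0")
    if np.all(w == 0):
        raise ValueError("at least one mixture weight must be non-zero")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1, got {w.sum()}")
    dens = w / (sig * math.sqrt(2.0 * math.pi)) * np.exp(-((d_m - d_t) ** 2) / (2.0 * sig**2))
    return float(dens.sum())


def template_weights(
    scheme: str,
    *,
    sigmas: Sequence[float] | None = None,
    similarities: Sequence[float] | None = None,
    n_templates: int | None = None,
) -> list[float]:
    """Per-template restraint weights under one of three schemes.

    ``uniform`` gives 1/U each; ``only_lowest`` gives all weight to the
    template with the smallest sigma (ties broken by lowest template index);
    ``similarity`` normalizes supplied local-similarity scores (floored at
    0.05) to sum 1.
    """
    if scheme == "uniform":
        if n_templates is None:
            n_templates = len(sigmas) if sigmas is not None else (
                len(similarities) if similarities is not None else None
            )
        if not n_templates:
            raise ValueError("uniform weighting needs a non-empty template list")
        return [1.0 / n_templates] * n_templates
    if scheme == "only_lowest":
        if not sigmas:
            raise ValueError("only_lowest weighting needs sigma values")
        best = int(np.argmin(sigmas))  # argmin takes the first minimum on ties
        return [1.0 if k == best else 0.0 for k in range(len(sigmas))]
    if scheme == "similarity":
        if not similarities:
            raise ValueError("similarity weighting needs similarity scores")
        s = np.maximum(np.asarray(similarities, dtype=float), 0.05)
        return list(s / s.sum())
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def local_similarity_profile(
    aln: PairwiseAlignment, target: Structure, window: int = 11
) -> dict[int, float]:
    """Windowed identity fraction per target residue for one template.

    For each target residue, the fraction of residues in a ``window``-wide
    window (centered on it, clipped at the chain ends) that are aligned to an
    identical template residue.
    """
    n = len(target)
    identical = np.zeros(n, dtype=float)
    ti = si = 0
    tmpl_ungapped = aln.template_seq.replace("-", "")
    for a, b in zip(aln.target_seq, aln.template_seq):
        if a != "-" and b != "-" and a == b:
            identical[ti] = 1.0
        if a != "-":
            ti += 1
        if b != "-":
            si += 1
    half = window // 2
    out: dict[int, float] = {}
    for k, res in enumerate(target.residues):
        lo, hi = max(0, k - half), min(n, k + half + 1)
        out[res.index] = float(identical[lo:hi].mean())
    return out


def _group_atom_pairs(topology: Structure, group: str, min_sep: int):
    """Candidate (AtomRef, AtomRef) pairs for one restraint group."""
    res = topology.residues
    pairs: list[tuple[AtomRef, AtomRef]] = []
    if group == "CA-CA":
        for a in range(len(res)):
            for b in range(a + 1, len(res)):
                if res[b].index - res[a].index >= min_sep:
                    pairs.append(((res[a].index, "CA"), (res[b].index, "CA")))
    elif group == "N-O":
        for a in range(len(res)):
            if not res[a].has_atom("N"):
                continue
            for b in range(len(res)):
                if abs(res[b].index - res[a].index) < min_sep or not res[b].has_atom("O"):
                    continue
                pairs.append(((res[a].index, "N"), (res[b].index, "O")))
    elif group == "SCMC":
        for a in range(len(res)):
            sc = res[a].side_chain_atoms
            if not sc:
                continue
            for b in range(len(res)):
                if abs(res[b].index - res[a].index) < min_sep:
                    continue
                for sa in sc:
                    for name in BACKBONE_ATOMS:
                        if res[b].has_atom(name):
                            pairs.append(((res[a].index, sa.name), (res[b].index, name)))
    elif group == "SCSC":
        for a in range(len(res)):
            sc_a = res[a].side_chain_atoms
            if not sc_a:
                continue
            for b in range(a + 1, len(res)):
                if res[b].index - res[a].index < min_sep:
                    continue
                for sa in sc_a:
                    for sb in res[b].side_chain_atoms:
                        pairs.append(((res[a].index, sa.name), (res[b].index, sb.name)))
    else:
        raise ValueError(f"unknown group {group!r}")
    return pairs


def build_hddrs(
    aln: JoinedAlignment,
    templates: Sequence[Structure],
    model_topology: Structure,
    cutoffs: dict[str, float] | None = None,
    min_separation: dict[str, int] | None = None,
    default_sigma: float = 1.0,
    weight_scheme: str = "uniform",
) -> RestraintSet:
    """Build the four HDDR groups from a joined alignment + templates.

    For every candidate model atom pair, each template whose equivalent atoms
    both exist and lie within the group's distance ceiling contributes one
    (d_t, sigma, w) entry; a restraint is emitted when at least one template
    contributes. ``default_sigma`` seeds all entries (strategies rewrite it
    downstream); ``weight_scheme`` is one of :func:`template_weights`'.
    """
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    min_separation = {**DEFAULT_MIN_SEPARATION, **(min_separation or {})}
    if len(templates) != aln.n_templates:
        raise ValueError(
            f"alignment has {aln.n_templates} templates but {len(templates)} structures given"
        )

    # Per-template residue maps and coordinate lookups.
    res_maps: list[dict[int, int]] = []
    coord_maps: list[dict[AtomRef, np.ndarray]] = []
    sim_profiles: list[dict[int, float]] = []
    for pw, tmpl in zip(aln.pairwise, templates):
        res_maps.append(dict(residue_correspondence(pw, model_topology, tmpl)))
        coord_maps.append(
            {(r.index, a.name): a.position for r in tmpl.residues for a in r.atoms}
        )
        sim_profiles.append(local_similarity_profile(pw, model_topology))

    restraints: list[DistanceRestraint] = []
    for group in GROUPS:
        ceiling = cutoffs[group]
        for ref_i, ref_j in _group_atom_pairs(model_topology, group, min_separation[group]):
            raw: list[tuple[int, float, float]] = []  # (u, d_t, similarity)
            for u in range(len(templates)):
                ri = res_maps[u].get(ref_i[0])
                rj = res_maps[u].get(ref_j[0])
                if ri is None or rj is None:
                    continue
                pos_i = coord_maps[u].get((ri, ref_i[1]))
                pos_j = coord_maps[u].get((rj, ref_j[1]))
                if pos_i is None or pos_j is None:
                    continue
                d_t = float(np.linalg.norm(pos_i - pos_j))
                if d_t <= 0 or d_t > ceiling:
                    continue
                sim = 0.5 * (sim_profiles[u][ref_i[0]] + sim_profiles[u][ref_j[0]])
                raw.append((u + 1, d_t, sim))
            if not raw:
                continue
            sigmas = [default_sigma] * len(raw)
            weights = template_weights(
                weight_scheme,
                sigmas=sigmas,
                similarities=[s for _, _, s in raw],
                n_templates=len(raw),
            )
            entries = tuple(
                RestraintEntry(u, d_t, default_sigma, w)
                for (u, d_t, _), w in zip(raw, weights)
            )
            restraints.append(DistanceRestraint(ref_i, ref_j, group, entries))
    return RestraintSet(restraints, provenance=aln.target_id)
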