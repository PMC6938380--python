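"""Synthetic native/template corpora with controlled divergence.

Natives are built from ideal secondary-structure internal coordinates
(helix, hairpin or mixed folds) with reduced side chains (CB plus one CG
pseudo-atom), so their stereochemistry sits at the minimum of the physical
terms. Templates are natives deformed by smooth, mode-structured
displacement fields rescaled to hit a requested CA RMSD; alignments are
identity alignments with a requested fraction of +/-1 register shifts.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from homodel.io_formats import (
    Atom,
    JoinedAlignment,
    PairwiseAlignment,
    Residue,
    Structure,
    write_structure,
)
from homodel.quality import superpose_rmsd

__all__ = ["ToySpec", "generate_pair", "generate_corpus", "build_native"]

# Reduced residue alphabet: every residue carries N/CA/C/O, plus CB and a CG
# pseudo-atom unless it is glycine.
_RESIDUES_3 = ("LEU", "GLU", "LYS", "PHE", "ASP", "ILE", "THR", "ARG", "GLN", "TYR")
_ONE = {"LEU": "L", "GLU": "E", "LYS": "K", "PHE": "F", "ASP": "D",
        "ILE": "I", "THR": "T", "ARG": "R", "GLN": "Q", "TYR": "Y", "GLY": "G"}

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-O": 1.231, "C-N": 1.329,
         "CA-CB": 1.530, "CB-CG": 1.520}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "N-CA-CB": 110.5, "CA-CB-CG": 114.0}

_PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}


@dataclass(frozen=True)
class ToySpec:
    length: int
    fold: str = "helix"
    divergence: float = 1.0        # target CA RMSD of template vs native, A
    alignment_error_rate: float = 0.0
    n_templates: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 10 <= self.length <= 120:
            raise ValueError("length must lie in [10, 120]")
        if self.fold not in ("helix", "hairpin", "mixed"):
            raise ValueError(f"unknown fold {self.fold!r}")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if not 0.0 <= self.alignment_error_rate <= 0.5:
            raise ValueError("alignment error rate must lie in [0, 0.5]")
        if self.n_templates < 1:
            raise ValueError("need at least one template")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           r: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """Natural-extension placement of atom D bonded to C."""
    theta = math.radians(theta_deg)
    chi = math.radians(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -r * math.cos(theta),
        r * math.sin(theta) * math.cos(chi),
        r * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _fold_dihedrals(fold: str, n: int) -> list[tuple[float, float]]:
    if fold == "helix":
        return [_PHI_PSI["helix"]] * n
    if fold == "hairpin":
        mid = n // 2
        out = []
        for i in range(n):
            if i in (mid - 1, mid):
                out.append((-60.0, -30.0) if i == mid - 1 else (-90.0, 0.0))
            else:
                out.append(_PHI_PSI["strand"])
        return out
    # mixed: N-terminal helix, short turn, C-terminal strand
    cut = n // 2
    out = [_PHI_PSI["helix"]] * cut
    out += [(-90.0, 0.0), (-60.0, -30.0)]
    out += [_PHI_PSI["strand"]] * (n - len(out))
    return out[:n]


def build_native(length: int, fold: str, sequence: str, identifier: str) -> Structure:
    """Construct an idealized native structure for a given sequence."""
    dihedrals = _fold_dihedrals(fold, length)
    residues: list[Residue] = []
    prev_n = prev_ca = prev_c = None
    for i in range(length):
        phi, psi = dihedrals[i]
        if i == 0:
            n_pos = np.zeros(3)
            ca_pos = np.array([_BOND["N-CA"], 0.0, 0.0])
            theta = math.radians(_ANGLE["N-CA-C"])
            c_pos = ca_pos + _BOND["CA-C"] * np.array([-math.cos(theta), math.sin(theta), 0.0])
        else:
            prev_phi, prev_psi = dihedrals[i - 1]
            n_pos = _place(prev_n, prev_ca, prev_c, _BOND["C-N"], _ANGLE["CA-C-N"], prev_psi)
            ca_pos = _place(prev_ca, prev_c, n_pos, _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
            c_pos = _place(prev_c, n_pos, ca_pos, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        o_pos = _place(n_pos, ca_pos, c_pos, _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0)
        atoms = [
            Atom("N", "N", n_pos), Atom("CA", "C", ca_pos),
            Atom("C", "C", c_pos), Atom("O", "O", o_pos),
        ]
        if sequence[i] != "G":
            cb = _place(c_pos, n_pos, ca_pos, _BOND["CA-CB"], _ANGLE["N-CA-CB"], -122.6)
            cg = _place(n_pos, ca_pos, cb, _BOND["CB-CG"], _ANGLE["CA-CB-CG"], -60.0)
            atoms += [Atom("CB", "C", cb), Atom("CG", "C", cg)]
        three = next(k for k, v in _ONE.items() if v == sequence[i])
        residues.append(Residue(i + 1, three, tuple(atoms)))
        prev_n, prev_ca, prev_c = n_pos, ca_pos, c_pos
    return Structure(identifier, residues)


def _random_sequence(rng: np.random.Generator, length: int, gly_fraction: float = 0.08) -> str:
    seq = []
    for _ in range(length):
        if rng.random() < gly_fraction:
            seq.append("G")
        else:
            seq.append(_ONE[_RESIDUES_3[rng.integers(len(_RESIDUES_3))]])
    return "".join(seq)


def _displacement_field(rng: np.random.Generator, n_res: int, n_modes: int = 3) -> np.ndarray:
    """Smooth per-residue displacement (n_res, 3): rigid-ish segment modes."""
    field = np.zeros((n_res, 3))
    idx = np.arange(n_res)
    for _ in range(n_modes):
        center = rng.uniform(0, n_res)
        width = rng.uniform(n_res / 8, n_res / 3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        profile = np.exp(-0.5 * ((idx - center) / width) ** 2)
        field += profile[:, None] * direction * rng.uniform(0.5, 1.5)
    return field


def _deform(native: Structure, rng: np.random.Generator, target_rmsd: float,
            identifier: str, jitter: float = 0.05, max_iter: int = 12) -> Structure:
    if target_rmsd == 0:
        return Structure(identifier, list(native.residues))
    field = _displacement_field(rng, len(native))
    per_atom_jitter = rng.normal(scale=1.0, size=(sum(len(r.atoms) for r in native.residues), 3))
    scale = 1.0
    base = native.coords()
    res_slot = np.concatenate([
        np.full(len(r.atoms), k) for k, r in enumerate(native.residues)
    ])
    native_ca = native.ca_coords()
    realized = None
    for _ in range(max_iter):
        coords = base + scale * (field[res_slot] + jitter * per_atom_jitter)
        moved = native.with_coords(coords)
        realized, _ = superpose_rmsd(moved.ca_coords(), native_ca)
        if abs(realized - target_rmsd) <= 0.10 * target_rmsd:
            return Structure(identifier, list(moved.residues))
        if realized <= 0:
            break
        scale *= target_rmsd / realized
    if realized is not None and abs(realized - target_rmsd) <= 0.15 * target_rmsd:
        return Structure(identifier, list(moved.residues))
    raise ValueError(
        f"could not reach divergence {target_rmsd:.2f} A for length {len(native)} "
        f"(got {realized})"
    )


def _shifted_mapping(
    rng: np.random.Generator, n: int, error_rate: float
) -> tuple[list[int | None], float]:
    """Identity residue mapping with +1 register-shift windows.

    Returns ``mapping`` (0-based target residue -> template residue or None)
    and the realized shifted fraction.
    """
    mapping: list[int | None] = list(range(n))
    want = int(round(error_rate * n))
    shifted = 0
    attempts = 0
    blocked = np.zeros(n, dtype=bool)
    while shifted < want and attempts < 200:
        attempts += 1
        win = int(min(rng.integers(1, 4), want - shifted))
        a = int(rng.integers(1, n - win - 2))
        span = slice(max(0, a - 1), a + win + 2)
        if blocked[span].any():
            continue
        for i in range(a, a + win):
            mapping[i] = i + 1
        mapping[a + win] = None
        blocked[span] = True
        shifted += win
    return mapping, shifted / n


def _join_mappings(sequence: str, mappings: list[list[int | None]]) -> list[str]:
    """Merge per-template residue mappings into equal-length gapped rows.

    Row 0 is the target; rows 1..U are the templates (every template has the
    target's sequence here, only its register differs).
    """
    n = len(sequence)
    n_t = len(mappings)
    rows: list[list[str]] = [[] for _ in range(n_t + 1)]
    ptr = [0] * n_t

    def flush(u: int, upto: int) -> None:
        while ptr[u] < upto:
            rows[0].append("-")
            for v in range(n_t):
                rows[v + 1].append(sequence[ptr[u]] if v == u else "-")
            ptr[u] += 1

    for i in range(n):
        for u in range(n_t):
            m = mappings[u][i]
            if m is not None:
                flush(u, m)
        rows[0].append(sequence[i])
        for u in range(n_t):
            m = mappings[u][i]
            if m is None:
                rows[u + 1].append("-")
            else:
                rows[u + 1].append(sequence[m])
                ptr[u] = m + 1
    for u in range(n_t):
        flush(u, n)
    return ["".join(r) for r in rows]


def generate_pair(spec: ToySpec) -> tuple[Structure, list[Structure], JoinedAlignment]:
    """One native, its templates, and the joined target-templates alignment."""
    rng = np.random.default_rng(spec.seed)
    sequence = _random_sequence(rng, spec.length)
    native = build_native(spec.length, spec.fold, sequence, f"toy{spec.seed}")
    templates: list[Structure] = []
    mappings: list[list[int | None]] = []
    for u in range(spec.n_templates):
        tmpl = _deform(native, rng, spec.divergence, f"{native.identifier}_t{u + 1}")
        mapping, _ = _shifted_mapping(rng, spec.length, spec.alignment_error_rate)
        templates.append(tmpl)
        mappings.append(mapping)
    rows = _join_mappings(sequence, mappings)
    pairwise = tuple(
        PairwiseAlignment(native.identifier, t.identifier, rows[0], rows[u + 1])
        for u, t in enumerate(templates)
    )
    return native, templates, JoinedAlignment(native.identifier, pairwise)


def generate_corpus(
    n_targets: int,
    out_dir: str | Path,
    seed: int = 0,
    length_range: tuple[int, int] = (18, 30),
    divergence_range: tuple[float, float] = (0.5, 3.0),
    error_rate_range: tuple[float, float] = (0.0, 0.1),
    n_templates_choices: Sequence[int] = (1,),
    folds: Sequence[str] = ("helix", "hairpin", "mixed"),
) -> Path:
    """Write a deterministic benchmark corpus; returns the manifest path.

    Emits one PDB per native/template, one PIR per target, and a manifest
    TSV (target id, file paths, realized divergence, realized error rate).
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = [
        "target_id\tlength\tfold\tnative\ttemplates\talignment"
        "\trequested_divergence\trealized_divergence\terror_rate"
    ]
    for t in range(n_targets):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        fold = folds[int(rng.integers(len(folds)))]
        div = float(rng.uniform(*divergence_range))
        err = float(rng.uniform(*error_rate_range))
        n_templates = int(n_templates_choices[int(rng.integers(len(n_templates_choices)))])
        spec = ToySpec(length, fold, div, err, n_templates, seed=int(rng.integers(2**31)))
        native, templates, aln = generate_pair(spec)
        tid = f"target{t:03d}"
        native_path = out_dir / f"{tid}_native.pdb"
        write_structure(native, native_path)
        tmpl_paths = []
        for u, tmpl in enumerate(templates):
            p = out_dir / f"{tid}_template{u + 1}.pdb"
            write_structure(tmpl, p)
            tmpl_paths.append(p.name)
        aln_path = out_dir / f"{tid}.pir"
        _write_pir(aln, aln_path)
        realized = float(np.mean([
            superpose_rmsd(tm.ca_coords(), native.ca_coords())[0] for tm in templates
        ]))
        rows.append(
            f"{tid}\t{length}\t{fold}\t{native_path.name}\t{';'.join(tmpl_paths)}"
            f"\t{aln_path.name}\t{div:.3f}\t{realized:.3f}\t{err:.3f}"
        )
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def _write_pir(aln: JoinedAlignment, path: Path) -> None:
    blocks = []
    target = aln.pairwise[0]
    blocks.append(f">P1;{aln.target_id}\nsequence:{aln.target_id}::::::::\n{target.target_seq}*")
    for pw in aln.pairwise:
        blocks.append(
            f">P1;{pw.template_id}\nstructureX:{pw.template_id}::::::::\n{pw.template_seq}*"
        )
    path.write_text("\n".join(blocks) + "\n")


def corpus_digest(manifest: Path) -> str:
    """Stable digest over the manifest plus every file it references."""
    manifest = Path(manifest)
    h = hashlib.sha256(manifest.read_bytes())
    for line in manifest.read_text().splitlines()[1:]:
        parts = line.split("\t")
        for name in [parts[3], *parts[4].split(";"), parts[5]]:
            h.update((manifest.parent / name).read_bytes())
    return h.hexdigest()
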