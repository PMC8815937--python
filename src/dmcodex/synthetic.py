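"""Synthetic Cα backbones with controlled repeat structure.

The generators provide the two texture classes the pipeline is built to
contrast: solenoids -- a rigid repeat unit translated (and slightly
twisted) along an axis, which imprints periodic off-diagonal bands on the
distance matrix -- and compact self-avoiding globular chains with no
periodicity.  Ideal helices and strands supply local-structure fixtures.
All randomness flows from explicit seeds, so corpora regenerate
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .distmat import distance_matrix, to_gray_image, write_gray_png
from .structure_io import CaTrace

__all__ = [
    "BackboneSpec",
    "make_helix",
    "make_strand",
    "make_solenoid",
    "make_globular",
    "make_corpus",
    "write_ca_pdb",
    "benchmark_specs",
]

CA_STEP = 3.8  # Å, canonical consecutive Cα-Cα distance

# ideal α-helix geometry
HELIX_RADIUS = 2.3  # Å
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue

# default solenoid coil geometry (LRR-like elongated repeat)
SOLENOID_RISE = 4.8  # Å per repeat
SOLENOID_TWIST = 15.0  # degrees per repeat
DEFAULT_UNIT_SIZE = 24


@dataclass(frozen=True)
class BackboneSpec:
    """Recipe for one synthetic domain."""

    kind: str  # helix | strand | solenoid | globular
    n_residues: int
    repeat_unit: int = DEFAULT_UNIT_SIZE
    noise_A: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "strand", "solenoid", "globular"):
            raise ValueError(f"unknown backbone kind: {self.kind!r}")
        if self.n_residues < 10:
            raise ValueError("n_residues must be at least 10")
        if self.kind == "solenoid":
            if self.repeat_unit < 5:
                raise ValueError("solenoid repeat unit must be >= 5 residues")
            if self.n_residues < 3 * self.repeat_unit:
                raise ValueError("solenoid needs at least 3 repeats")
        if self.noise_A < 0:
            raise ValueError("noise must be nonnegative")


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_helix(n: int, id: str = "helix") -> CaTrace:
    """Ideal α-helix: radius 2.3 Å, rise 1.5 Å/residue, 100°/residue.

    The resulting consecutive Cα-Cα chord is √((2r sin 50°)² + rise²)
    ≈ 3.83 Å, identical for every residue pair (i, i+1).
    """
    if n < 4:
        raise ValueError("helix needs at least 4 residues")
    j = np.arange(n)
    t = np.deg2rad(HELIX_TWIST) * j
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(t), HELIX_RADIUS * np.sin(t), HELIX_RISE * j]
    )
    return CaTrace(id=id, coords=coords)


def make_strand(n: int, id: str = "strand") -> CaTrace:
    """Extended zigzag strand with exact 3.8 Å steps."""
    if n < 2:
        raise ValueError("strand needs at least 2 residues")
    angle = np.deg2rad(15.0)
    dx = CA_STEP * np.cos(angle)
    dy = CA_STEP * np.sin(angle)
    j = np.arange(n)
    coords = np.column_stack(
        [dx * j, dy * (j % 2), np.zeros(n)]
    )
    return CaTrace(id=id, coords=coords)


def _default_unit(m: int) -> np.ndarray:
    """Helix-turn repeat unit of m residues, extended along +y.

    A short α-helical segment runs outward; a straight turn of 6 residues
    returns toward the solenoid axis so consecutive repeats stack head to
    tail.
    """
    n_turn = 6
    n_helix = m - n_turn
    if n_helix < 4:
        raise ValueError("repeat unit too small for a helix-turn motif")
    j = np.arange(n_helix)
    t = np.deg2rad(HELIX_TWIST) * j
    helix = np.column_stack(
        [HELIX_RADIUS * np.cos(t), HELIX_RISE * j, HELIX_RADIUS * np.sin(t)]
    )
    start = helix[-1]
    end = np.array([6.5, 0.0, 2.0])
    frac = (np.arange(1, n_turn + 1) / (n_turn + 1))[:, None]
    turn = start + frac * (end - start)
    return np.vstack([helix, turn])


def make_solenoid(
    n_repeats: int,
    unit_size: int = DEFAULT_UNIT_SIZE,
    rise_per_repeat: float = SOLENOID_RISE,
    twist_per_repeat: float = SOLENOID_TWIST,
    noise_A: float = 0.0,
    seed: int = 0,
    unit: Optional[np.ndarray] = None,
    id: str = "solenoid",
) -> CaTrace:
    """Stack copies of a rigid repeat unit along the z axis.

    Repeat r is the unit rotated by r·twist about z and translated by
    r·rise along z; with zero noise the distance between residues i of
    repeat r and j of repeat r' therefore depends only on (i, j, |r-r'|),
    which is exactly the periodic off-diagonal banding of solenoid
    distance matrices.  Optional isotropic Gaussian noise perturbs every
    coordinate.
    """
    if n_repeats < 3:
        raise ValueError("need at least 3 repeats")
    u = _default_unit(unit_size) if unit is None else np.asarray(unit, float)
    blocks = []
    for r in range(n_repeats):
        R = _rot_z(twist_per_repeat * r)
        blocks.append(u @ R.T + np.array([0.0, 0.0, rise_per_repeat * r]))
    coords = np.vstack(blocks)
    if noise_A > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_A, coords.shape)
    return CaTrace(id=id, coords=coords)


def make_globular(
    n: int,
    seed: int = 0,
    id: str = "globular",
    max_restarts: int = 200,
    max_tries_per_step: int = 300,
) -> CaTrace:
    """Compact self-avoiding random chain with no repeat structure.

    Steps are exactly 3.8 Å; every non-bonded pair (|i-j| >= 2) is kept at
    least 4.0 Å apart; all residues stay inside a sphere of radius
    3.0·n^(1/3) Å centered on the start, which also bounds the radius of
    gyration.  Built by rejection sampling with whole-chain restarts.
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    radius = 3.0 * n ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        pts = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(max_tries_per_step):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = pts[i - 1] + CA_STEP * v
                if np.linalg.norm(cand) > radius:
                    continue
                if i >= 2:
                    d = np.linalg.norm(pts[: i - 1] - cand, axis=1)
                    if d.min() < 4.0:
                        continue
                pts[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return CaTrace(id=id, coords=pts)
    raise RuntimeError(
        f"could not place a {n}-residue self-avoiding chain inside radius "
        f"{radius:.1f} Å after {max_restarts} restarts"
    )


def generate(spec: BackboneSpec, id: str) -> CaTrace:
    """Realize one backbone spec into a trace (noise applied if requested)."""
    if spec.kind == "helix":
        trace = make_helix(spec.n_residues, id=id)
    elif spec.kind == "strand":
        trace = make_strand(spec.n_residues, id=id)
    elif spec.kind == "solenoid":
        n_rep = int(np.ceil(spec.n_residues / spec.repeat_unit))
        trace = make_solenoid(
            max(n_rep, 3),
            unit_size=spec.repeat_unit,
            noise_A=0.0,
            id=id,
        )
        trace = CaTrace(id=id, coords=trace.coords[: spec.n_residues])
    else:
        return make_globular(spec.n_residues, seed=spec.seed, id=id)

    if spec.noise_A > 0 and spec.kind != "globular":
        rng = np.random.default_rng(spec.seed)
        trace = CaTrace(
            id=id,
            coords=trace.coords + rng.normal(0.0, spec.noise_A, trace.coords.shape),
        )
    return trace


def write_ca_pdb(trace: CaTrace, path) -> None:
    """Write a Cα-only PDB file (chain A, one ALA residue per position)."""
    n = len(trace)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(trace.coords, dtype=np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.full(n, "ALA")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def benchmark_specs(
    n_solenoid: int = 10,
    n_globular: int = 10,
    n_residues: int = 150,
    noise_A: float = 0.3,
    seed: int = 0,
) -> List[BackboneSpec]:
    """Standard contrast corpus: noisy solenoids vs globular chains.

    Residue counts are jittered ±20% around ``n_residues`` so domain size
    does not trivially separate the classes.
    """
    rng = np.random.default_rng(seed)
    child = rng.integers(0, 2**31 - 1, size=n_solenoid + n_globular)
    specs = []
    for i in range(n_solenoid):
        n = max(int(n_residues * rng.uniform(0.8, 1.2)), 3 * DEFAULT_UNIT_SIZE)
        specs.append(
            BackboneSpec(
                kind="solenoid", n_residues=n, noise_A=noise_A, seed=int(child[i])
            )
        )
    for i in range(n_globular):
        n = int(n_residues * rng.uniform(0.8, 1.2))
        specs.append(
            BackboneSpec(
                kind="globular",
                n_residues=n,
                noise_A=0.0,
                seed=int(child[n_solenoid + i]),
            )
        )
    return specs


def make_corpus(specs: Sequence[BackboneSpec], out_dir, seed: int = 0) -> pd.DataFrame:
    """Write PDBs, grayscale PNGs and a labeled manifest for a spec list.

    Item ids are ``<kind><index>``; the manifest TSV has columns id, path,
    binary_label, kind, n_residues, seed.  Fully reproducible: the same
    specs and seed give byte-identical files.
    """
    if not specs:
        raise ValueError("empty spec list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        item_id = f"{spec.kind}{i:03d}"
        trace = generate(spec, id=item_id)
        pdb_path = out_dir / f"{item_id}.pdb"
        write_ca_pdb(trace, pdb_path)
        img = to_gray_image(distance_matrix(trace))
        write_gray_png(img, out_dir / f"{item_id}.png")
        binary = (
            "solenoid" if spec.kind == "solenoid"
            else ("globular" if spec.kind == "globular" else "")
        )
        rows.append(
            {
                "id": item_id,
                "path": pdb_path.name,
                "binary_label": binary,
                "kind": spec.kind,
                "n_residues": len(trace),
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
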