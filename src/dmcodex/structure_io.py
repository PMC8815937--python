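"""Reading Cα traces from PDB files and handling SCOP-style hierarchy labels.

A protein domain enters the pipeline as the ordered sequence of its Cα
coordinates; everything downstream (distance matrix, image, features) is a
function of this trace alone.  Labels follow the four-level SCOP(e)
hierarchy -- class, fold, superfamily, family -- encoded in sids such as
``a.1.1.1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "CaTrace",
    "ScopLabel",
    "read_ca_trace",
    "parse_scop_sid",
    "match_level",
    "read_manifest",
]

SCOP_LEVELS = ("class", "fold", "superfamily", "family")

_SID_RE = re.compile(r"^([a-z])\.(\d+)\.(\d+)\.(\d+)$")


@dataclass(frozen=True)
class ScopLabel:
    """Four nested levels of a SCOP-style sid, each a dot-joined prefix."""

    cls: str
    fold: str
    superfamily: str
    family: str

    def level(self, name: str) -> str:
        if name not in SCOP_LEVELS:
            raise ValueError(f"unknown hierarchy level: {name!r}")
        return {
            "class": self.cls,
            "fold": self.fold,
            "superfamily": self.superfamily,
            "family": self.family,
        }[name]

    @property
    def sid(self) -> str:
        return self.family


@dataclass
class CaTrace:
    """Ordered 3-D Cα coordinates of one protein domain.

    Parameters
    ----------
    id : str
        Domain identifier (e.g. file stem or SCOPe sid).
    coords : (N, 3) float array
        Cα positions in Å, in residue sequence order.
    label : ScopLabel, optional
        SCOP-style hierarchical label.
    binary_label : str, optional
        ``"solenoid"`` or ``"globular"``.
    """

    id: str
    coords: np.ndarray
    label: Optional[ScopLabel] = None
    binary_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.coords) < 2:
            raise ValueError("a Cα trace needs at least 2 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.binary_label is not None and self.binary_label not in (
            "solenoid",
            "globular",
        ):
            raise ValueError(f"invalid binary label: {self.binary_label!r}")

    def __len__(self) -> int:
        return len(self.coords)


def parse_scop_sid(sid: str) -> ScopLabel:
    """Parse a sid like ``"a.1.1.1"`` into its four prefix levels.

    >>> parse_scop_sid("a.1.1.1").superfamily
    'a.1.1'
    """
    m = _SID_RE.match(sid.strip())
    if m is None:
        raise ValueError(
            f"not a valid SCOP sid (expected letter.int.int.int): {sid!r}"
        )
    c, f, s, fam = m.groups()
    return ScopLabel(
        cls=c,
        fold=f"{c}.{f}",
        superfamily=f"{c}.{f}.{s}",
        family=f"{c}.{f}.{s}.{fam}",
    )


def match_level(a: ScopLabel, b: ScopLabel, level: str) -> bool:
    """True iff the labels agree on the dot-joined prefix up to ``level``.

    Two sids ``a.1.1.1`` and ``a.1.2.1`` agree at class and fold but
    disagree at superfamily and family.
    """
    return a.level(level) == b.level(level)


def read_ca_trace(path, chain: Optional[str] = None, id: Optional[str] = None) -> CaTrace:
    """Read the Cα trace of a single domain from a PDB file.

    Keeps the first model and, for alternate locations, the first altloc.
    Residue order follows record order in the file.  If the file contains
    more than one chain, ``chain`` must select one.
    """
    path = Path(path)
    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="first")

    ca = atoms[atoms.atom_name == "CA"]
    # exclude calcium ions, which share the atom name
    ca = ca[~ca.hetero]
    if ca.array_length() == 0:
        raise ValueError(f"{path}: no Cα atoms found")

    chains = np.unique(ca.chain_id)
    if chain is not None:
        ca = ca[ca.chain_id == chain]
        if ca.array_length() == 0:
            raise ValueError(f"{path}: chain {chain!r} has no Cα atoms")
    elif len(chains) > 1:
        raise ValueError(
            f"{path}: multiple chains {sorted(chains)}; select one explicitly"
        )
    if ca.array_length() < 2:
        raise ValueError(f"{path}: fewer than 2 Cα atoms")
    return CaTrace(id=id or path.stem, coords=np.array(ca.coord, dtype=float))


def read_manifest(path) -> list[dict]:
    """Read a corpus manifest TSV.

    Columns: ``id``, ``path`` (required); ``scop_sid``, ``binary_label``
    (optional).  Paths are resolved relative to the manifest's directory.
    Returns one dict per row with ``scop_sid`` parsed into a
    :class:`ScopLabel` (or None).
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "path"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} lacks required column {col!r}")
    rows = []
    for rec in df.to_dict("records"):
        p = Path(rec["path"])
        if not p.is_absolute():
            p = path.parent / p
        label = rec.get("scop_sid")
        rows.append(
            {
                "id": rec["id"],
                "path": p,
                "label": parse_scop_sid(label) if isinstance(label, str) else None,
                "binary_label": rec.get("binary_label")
                if isinstance(rec.get("binary_label"), str)
                else None,
            }
        )
    return rows
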