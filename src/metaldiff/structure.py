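"""Reading, cleaning, and writing of protein structures and predicted metal sites.

Structures are parsed from PDB text with :mod:`gemmi` into a lightweight
array-backed :class:`ProteinStructure`.  Zinc ions are split out of the atom
list into ``metal_sites`` at parse time; all other HETATM records are retained
(with their element) until :func:`clean_structure` removes them.

Conventions
-----------
* All coordinates are in Angstrom, kept in the file's frame (no re-centering).
* Hydrogens are dropped on parse; the method operates on heavy atoms.
* For alternate locations the highest-occupancy conformer is kept, ties broken
  by altloc letter order.
* The representative residue coordinate is the C-alpha atom, falling back to
  the centroid of the residue's heavy atoms when no C-alpha is present.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    ContractError,
    EmptyStructureError,
    ParseError,
    TooManyResiduesError,
)

#: default residue-count cap applied by :func:`clean_structure`
MAX_RESIDUES_DEFAULT = 3000

_ZINC_ELEMENT = "ZN"


@dataclass(frozen=True)
class ProteinStructure:
    """A single-model protein structure with optional zinc ground truth.

    Residue arrays are aligned index-wise; ``atom_parent[i]`` is the index of
    atom *i*'s parent residue.  ``metal_sites`` holds zinc coordinates only.
    """

    residue_chains: tuple[str, ...]
    residue_indices: np.ndarray  # (n_res,) int, author residue numbers
    residue_names: tuple[str, ...]
    residue_coords: np.ndarray  # (n_res, 3) float, representative atom (CA)
    residue_het: np.ndarray  # (n_res,) bool, True for HETATM residues
    atom_elements: tuple[str, ...]
    atom_coords: np.ndarray  # (n_atoms, 3) float
    atom_parent: np.ndarray  # (n_atoms,) int
    metal_sites: np.ndarray  # (n_metal, 3) float
    model_id: int = 1
    n_models: int = 1
    source_id: str = "structure"
    cleaned: bool = False

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_elements)

    @property
    def n_metal_sites(self) -> int:
        return int(self.metal_sites.shape[0])

    def validate(self) -> None:
        """Check internal invariants; raise :class:`ContractError` on failure."""
        if self.atom_parent.size and (
            self.atom_parent.min() < 0 or self.atom_parent.max() >= self.n_residues
        ):
            raise ContractError("atom parent index out of range")
        for arr in (self.residue_coords, self.atom_coords, self.metal_sites):
            if arr.size and not np.isfinite(arr).all():
                raise ContractError("non-finite coordinate in structure")

    def bounding_box(self, pad: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box over residue+atom coordinates, padded."""
        pts = [self.residue_coords, self.atom_coords]
        pts = [p for p in pts if p.size]
        if not pts:
            raise EmptyStructureError("cannot compute bounding box of empty structure")
        allp = np.vstack(pts)
        return allp.min(axis=0) - pad, allp.max(axis=0) + pad


def _is_zinc(residue: gemmi.Residue, atom: gemmi.Atom) -> bool:
    el = atom.element.name.upper()
    return el == _ZINC_ELEMENT or (residue.het_flag == "H" and residue.name.strip().upper() == "ZN")


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy altloc per atom name; ties by altloc letter."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        key = atom.name
        prev = best.get(key)
        if prev is None:
            best[key] = atom
            continue
        alt_prev = prev.altloc if prev.altloc != "\x00" else ""
        alt_new = atom.altloc if atom.altloc != "\x00" else ""
        if (atom.occ, -ord(alt_new or "~")) > (prev.occ, -ord(alt_prev or "~")):
            best[key] = atom
    return list(best.values())


def parse_structure(
    pdb_text: str, model_id: int | None = None, source_id: str = "structure"
) -> ProteinStructure:
    """Parse PDB text into a :class:`ProteinStructure`.

    Parameters
    ----------
    pdb_text
        PDB-format text with at least one ATOM record.
    model_id
        PDB MODEL number to extract; default is the first model.
    source_id
        Identifier recorded on the returned structure.

    Raises
    ------
    ParseError
        On empty input, input without ATOM records, or unparseable records
        (the message names the offending line).
    """
    if not pdb_text or not pdb_text.strip():
        raise ParseError("empty PDB input")
    has_atom = any(
        line.startswith(("ATOM", "HETATM")) for line in pdb_text.splitlines()
    )
    if not has_atom:
        raise ParseError("no ATOM/HETATM record found in input")
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
            raise ParseError(f"truncated coordinate record at line {lineno}: {line!r}")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports line numbers
        raise ParseError(f"PDB parse failure: {exc}") from exc
    if len(st) == 0:
        raise ParseError("no model found in PDB input")

    n_models = len(st)
    model = None
    if model_id is None:
        model = st[0]
    else:
        for m in st:
            if m.num == model_id:
                model = m
                break
        if model is None:
            raise ParseError(f"model {model_id} not present (file has {n_models} models)")

    res_chains: list[str] = []
    res_indices: list[int] = []
    res_names: list[str] = []
    res_coords: list[np.ndarray] = []
    res_het: list[bool] = []
    atom_elements: list[str] = []
    atom_coords: list[np.ndarray] = []
    atom_parent: list[int] = []
    metal_sites: list[np.ndarray] = []

    for chain in model:
        for residue in chain:
            atoms = _resolve_altlocs(residue)
            # split zinc off into metal_sites
            zn = [a for a in atoms if _is_zinc(residue, a)]
            for a in zn:
                metal_sites.append(np.array([a.pos.x, a.pos.y, a.pos.z]))
            heavy = [
                a
                for a in atoms
                if not a.element.is_hydrogen and not _is_zinc(residue, a)
            ]
            if not heavy:
                continue
            ca = next((a for a in heavy if a.name.strip() == "CA"), None)
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in heavy])
            rep = (
                np.array([ca.pos.x, ca.pos.y, ca.pos.z])
                if ca is not None
                else coords.mean(axis=0)
            )
            ridx = len(res_names)
            res_chains.append(chain.name)
            res_indices.append(residue.seqid.num)
            res_names.append(residue.name.strip())
            res_coords.append(rep)
            res_het.append(residue.het_flag == "H")
            for a in heavy:
                atom_elements.append(a.element.name.upper())
                atom_coords.append(np.array([a.pos.x, a.pos.y, a.pos.z]))
                atom_parent.append(ridx)

    s = ProteinStructure(
        residue_chains=tuple(res_chains),
        residue_indices=np.array(res_indices, dtype=int),
        residue_names=tuple(res_names),
        residue_coords=(
            np.array(res_coords) if res_coords else np.zeros((0, 3))
        ),
        residue_het=np.array(res_het, dtype=bool),
        atom_elements=tuple(atom_elements),
        atom_coords=np.array(atom_coords) if atom_coords else np.zeros((0, 3)),
        atom_parent=np.array(atom_parent, dtype=int),
        metal_sites=(
            np.array(metal_sites) if metal_sites else np.zeros((0, 3))
        ),
        model_id=model.num,
        n_models=n_models,
        source_id=source_id,
    )
    s.validate()
    return s


def clean_structure(
    s: ProteinStructure, max_residues: int = MAX_RESIDUES_DEFAULT
) -> ProteinStructure:
    """Remove exogenous heteroatoms and enforce the residue cap.

    Waters, ligands and non-zinc ions (all HETATM residues) are removed; zinc
    sites, already held in ``metal_sites``, are retained.  Structures larger
    than ``max_residues`` after cleaning are rejected with
    :class:`TooManyResiduesError` rather than truncated.  The input is not
    mutated; cleaning is idempotent.
    """
    keep = ~s.residue_het
    if not keep.any():
        raise EmptyStructureError(
            f"{s.source_id}: no residues remain after removing heteroatoms"
        )
    new_index = np.cumsum(keep) - 1  # old residue idx -> new
    atom_keep = keep[s.atom_parent]
    cleaned = replace(
        s,
        residue_chains=tuple(c for c, k in zip(s.residue_chains, keep) if k),
        residue_indices=s.residue_indices[keep],
        residue_names=tuple(n for n, k in zip(s.residue_names, keep) if k),
        residue_coords=s.residue_coords[keep],
        residue_het=s.residue_het[keep],
        atom_elements=tuple(
            e for e, k in zip(s.atom_elements, atom_keep) if k
        ),
        atom_coords=s.atom_coords[atom_keep],
        atom_parent=new_index[s.atom_parent[atom_keep]],
        cleaned=True,
    )
    if cleaned.n_residues > max_residues:
        raise TooManyResiduesError(
            f"{s.source_id}: {cleaned.n_residues} residues exceeds cap {max_residues}"
        )
    cleaned.validate()
    return cleaned


# ---------------------------------------------------------------------------
# writing


def _pdb_atom_name(name: str) -> str:
    return name if len(name) >= 4 else f" {name:<3s}"


def _hetatm_zn_line(serial: int, resseq: int, xyz: np.ndarray, b: float) -> str:
    x, y, z = (float(v) for v in xyz)
    return (
        f"HETATM{serial:5d} ZN    ZN A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}          ZN"
    )


def write_predictions(
    sites: np.ndarray, probs: np.ndarray, fmt: str = "csv"
) -> str:
    """Serialize predicted metal sites with confidences.

    ``fmt='pdb'`` emits one ZN HETATM per site with the confidence in the
    B-factor column (fixed-width, 3-decimal coordinates); ``fmt='csv'`` emits
    a ``x,y,z,confidence`` table.
    """
    sites = np.asarray(sites, dtype=float).reshape(-1, 3)
    probs = np.asarray(probs, dtype=float).reshape(-1)
    if sites.shape[0] != probs.shape[0]:
        raise ContractError(
            f"sites ({sites.shape[0]}) and probs ({probs.shape[0]}) length mismatch"
        )
    if fmt == "csv":
        df = pd.DataFrame(
            {
                "x": sites[:, 0],
                "y": sites[:, 1],
                "z": sites[:, 2],
                "confidence": probs,
            }
        )
        buf = io.StringIO()
        df.to_csv(buf, index=False, float_format="%.3f")
        return buf.getvalue()
    if fmt == "pdb":
        lines = [
            _hetatm_zn_line(i + 1, i + 1, sites[i], float(probs[i]))
            for i in range(sites.shape[0])
        ]
        lines.append("END")
        return "\n".join(lines) + "\n"
    raise ContractError(f"unknown prediction format {fmt!r}")


def read_predictions_csv(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`write_predictions` for the CSV dialect."""
    df = pd.read_csv(io.StringIO(text))
    return df[["x", "y", "z"]].to_numpy(float), df["confidence"].to_numpy(float)


_ELEMENT_ATOM_NAMES = {"C": "C", "N": "N", "O": "O", "S": "S", "P": "P"}


def write_structure_pdb(s: ProteinStructure) -> str:
    """Write a structure (atoms + zinc sites) as fixed-width PDB text.

    Atom names are regenerated as CA for the residue representative atom and
    element+counter otherwise; good enough for round-tripping synthetic and
    cleaned structures.
    """
    lines: list[str] = []
    serial = 0
    per_res_count: dict[int, int] = {}
    for i in range(s.n_atoms):
        ridx = int(s.atom_parent[i])
        cnt = per_res_count.get(ridx, 0)
        per_res_count[ridx] = cnt + 1
        el = s.atom_elements[i]
        is_rep = cnt == 0 and el == "C" and np.allclose(
            s.atom_coords[i], s.residue_coords[ridx], atol=1e-6
        )
        name = "CA" if is_rep else f"{_ELEMENT_ATOM_NAMES.get(el, el)}{cnt + 1}"
        serial += 1
        x, y, z = (float(v) for v in s.atom_coords[i])
        lines.append(
            f"ATOM  {serial:5d} {_pdb_atom_name(name)}{s.residue_names[ridx]:>3s} "
            f"{s.residue_chains[ridx][:1] or 'A'}{int(s.residue_indices[ridx]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {el:>2s}"
        )
    for j in range(s.n_metal_sites):
        serial += 1
        lines.append(_hetatm_zn_line(serial, 900 + j, s.metal_sites[j], 0.0))
    lines.append("END")
    return "\n".join(lines) + "\n"
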