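"""C-alpha coordinate superposition between structural models.

Reads C-alpha atoms from PDB files (optionally excluding a residue range,
e.g. the EH domain, residues 443-538 in EHD2 numbering), pairs residues by
number or by order, and computes the optimal least-squares rigid
superposition (Kabsch algorithm with a proper-rotation guard) and the RMSD
over the paired atoms.  Used to quantify how closely a membrane-bound
conformation matches a crystal structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .errors import ValidationError

#: Default excluded residue range: the EH domain in EHD2 numbering.
EH_DOMAIN_RANGE = (443, 538)


@dataclass
class CaCoordinateSet:
    """C-alpha positions of one chain: (chain, residue number, xyz in Angstrom)."""

    chains: np.ndarray  # str array, per residue
    residue_numbers: np.ndarray  # int array
    coords: np.ndarray  # (n, 3) Angstrom
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.chains = np.asarray(self.chains, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be (n, 3)")
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite coordinates")
        for ch in np.unique(self.chains):
            nums = self.residue_numbers[self.chains == ch]
            if len(np.unique(nums)) != len(nums):
                raise ValidationError(f"duplicate residue numbers in chain {ch}")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class SuperpositionResult:
    """Rigid transform mapping the mobile set onto the reference, plus RMSD."""

    rmsd: float  # Angstrom
    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rmsd_angstrom": self.rmsd,
                    "rotation": self.rotation.tolist(),
                    "translation": self.translation.tolist(),
                    "n_pairs": self.n_pairs,
                },
                indent=2,
                sort_keys=True,
            )
        )


def read_ca(
    pdb_file: str | Path,
    chain: str | None = None,
    exclude_residues: tuple[int, int] | None = None,
) -> CaCoordinateSet:
    """Read C-alpha atoms of one chain from a PDB file.

    ``exclude_residues`` is an inclusive (first, last) residue-number range
    to drop (e.g. ``EH_DOMAIN_RANGE``).  Altloc A is preferred when present;
    residues with insertion codes are rejected since numeric pairing would
    be ambiguous.
    """
    structure = gemmi.read_structure(str(pdb_file))
    if len(structure) == 0:
        raise ValidationError(f"{pdb_file}: no models found")
    model = structure[0]
    chain_names = [c.name for c in model]
    if chain is None:
        if len(chain_names) != 1:
            raise ValidationError(
                f"{pdb_file}: multiple chains {chain_names}; specify one"
            )
        chain = chain_names[0]
    if chain not in chain_names:
        raise ValidationError(f"{pdb_file}: chain {chain!r} not found (have {chain_names})")

    chains, numbers, coords = [], [], []
    for residue in model[chain]:
        if residue.seqid.icode not in (" ", ""):
            raise ValidationError(
                f"{pdb_file}: residue {residue.seqid.num}{residue.seqid.icode} has an "
                "insertion code; renumber before pairing"
            )
        num = residue.seqid.num
        if exclude_residues is not None and exclude_residues[0] <= num <= exclude_residues[1]:
            continue
        ca = None
        for atom in residue:
            if atom.name == "CA" and atom.element.name == "C" and atom.altloc in ("", "A", "\x00"):
                ca = atom
                break
        if ca is None:
            continue
        chains.append(chain)
        numbers.append(num)
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not coords:
        raise ValidationError(f"{pdb_file}: no C-alpha atoms found in chain {chain}")
    return CaCoordinateSet(
        chains=np.array(chains, dtype=object),
        residue_numbers=np.array(numbers, dtype=int),
        coords=np.array(coords, dtype=float),
        source_label=str(pdb_file),
    )


def _pair_coordinates(
    a: CaCoordinateSet,
    b: CaCoordinateSet,
    pairing: str,
    b_numbering_offset: int,
) -> tuple[np.ndarray, np.ndarray]:
    if pairing == "by_order":
        n = min(len(a), len(b))
        return a.coords[:n], b.coords[:n]
    if pairing == "by_residue_number":
        b_nums = b.residue_numbers + b_numbering_offset
        common, ia, ib = np.intersect1d(a.residue_numbers, b_nums, return_indices=True)
        return a.coords[ia], b.coords[ib]
    raise ValidationError("pairing must be 'by_residue_number' or 'by_order'")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation + translation mapping mobile onto reference.

    Standard SVD solution of the orthogonal Procrustes problem with the
    reflection guard: if the best orthogonal matrix is a reflection, the
    smallest singular direction is flipped to return a proper rotation
    (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = cr - rotation @ cm
    return rotation, translation


def superpose_rmsd(
    a: CaCoordinateSet,
    b: CaCoordinateSet,
    pairing: str = "by_residue_number",
    b_numbering_offset: int = 0,
) -> SuperpositionResult:
    """RMSD of ``a`` onto ``b`` after optimal rigid superposition.

    Residues are paired by residue number (after adding
    ``b_numbering_offset`` to b's numbers, for structures with shifted
    numbering) or by order.  At least 3 pairs are required.
    """
    pa, pb = _pair_coordinates(a, b, pairing, b_numbering_offset)
    if len(pa) < 3:
        raise ValidationError(f"need >= 3 paired residues, got {len(pa)}")
    if np.allclose(pa, pa[0]) or np.allclose(pb, pb[0]):
        raise ValidationError("all paired points coincident; superposition undefined")
    rotation, translation = kabsch(pa, pb)
    moved = pa @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - pb) ** 2, axis=1))))
    return SuperpositionResult(
        rmsd=rmsd, rotation=rotation, translation=translation, n_pairs=len(pa)
    )
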