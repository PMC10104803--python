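"""Structure-derived pocket metrics from PDB/mmCIF coordinates.

Covers the quantities used to compare ligand-bound receptor structures:
atom-pair distances (e.g. the V3.36 C-alpha to F45.52 C-zeta pocket
width), residue-matched C-alpha RMSD after optimal rigid superposition,
per-residue B-factors normalized by the overall receptor B-factor (a
flexibility measure comparable between crystals), their between-structure
deltas, and four-atom torsion angles.

Parsing is delegated to gemmi; only the first model is kept and
alternate locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from betapharm.errors import DomainError, MatchingError, SelectionError, ValidationError

logger = logging.getLogger("betapharm")

AtomSelector = tuple[str, int, str]  # (chain_id, residue_number, atom_name)


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    altloc: str
    occupancy: float
    element: str
    xyz: tuple[float, float, float]
    b_factor: float

    @property
    def is_hydrogen(self) -> bool:
        return self.element in {"H", "D"}


@dataclass
class StructureModel:
    """Flat atom table for one model of a coordinate file."""

    atoms: list[AtomRecord]
    model_id: str = "1"
    source: str = ""
    _index: dict[tuple[str, int, str, str], AtomRecord] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError(f"structure {self.source!r} contains no atoms")
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValidationError(f"non-finite coordinates for {a}")
        self._index = {
            (a.chain_id, a.residue_number, a.insertion_code, a.atom_name): a
            for a in self.atoms
        }

    def find_atoms(self, chain_id: str, residue_number: int, atom_name: str
                   ) -> list[AtomRecord]:
        return [
            a for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
            and a.atom_name == atom_name
        ]

    def resolve(self, sel: AtomSelector) -> AtomRecord:
        """Resolve a selector to exactly one atom or raise SelectionError."""
        chain_id, resnum, atom_name = sel
        hits = self.find_atoms(chain_id, int(resnum), atom_name)
        if len(hits) != 1:
            raise SelectionError(
                f"selector (chain={chain_id}, residue={resnum}, atom={atom_name}) "
                f"resolved to {len(hits)} atoms in {self.source!r}"
            )
        return hits[0]

    def chains(self) -> list[str]:
        return sorted({a.chain_id for a in self.atoms})


@dataclass
class ResidueBFactorProfile:
    """Per-residue mean B-factors normalized by the overall regional mean."""

    entries: list[tuple[str, int, str, float, float]]  # chain, resnum, name, mean_b, normalized_b
    overall_b: float
    n_atoms_per_residue: dict[tuple[str, int], int] = field(default_factory=dict)

    def normalized(self) -> dict[tuple[str, int], float]:
        return {(c, r): nb for c, r, _n, _mb, nb in self.entries}


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one atom per (chain, residue, atom_name): highest occupancy, ties -> altloc 'A'."""
    groups: dict[tuple[str, int, str, str], list[AtomRecord]] = {}
    order: list[tuple[str, int, str, str]] = []
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.atom_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    out = []
    for key in order:
        cands = groups[key]
        if len(cands) == 1:
            out.append(cands[0])
        else:
            cands.sort(key=lambda a: (-a.occupancy, a.altloc != "A", a.altloc))
            out.append(cands[0])
    return out


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    First model only; alternate locations resolved to the highest
    occupancy conformer (ties prefer altloc 'A'); hydrogens retained
    (B-factor statistics exclude them downstream).
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValidationError(f"{path} contains no models")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or " ").strip(),
                        residue_name=residue.name,
                        atom_name=atom.name,
                        altloc=atom.altloc or "",
                        occupancy=float(atom.occ),
                        element=atom.element.name.upper(),
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        b_factor=float(atom.b_iso),
                    )
                )
    if not atoms:
        raise ValidationError(f"{path} contains no atom records")
    return StructureModel(atoms=_resolve_altlocs(atoms), model_id=str(model.num),
                          source=str(path))


def atom_distance(model: StructureModel, sel_a: AtomSelector, sel_b: AtomSelector) -> float:
    """Euclidean distance (angstrom) between two uniquely selected atoms."""
    a = model.resolve(sel_a)
    b = model.resolve(sel_b)
    return float(np.linalg.norm(np.subtract(a.xyz, b.xyz)))


def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (SVD with reflection guard)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Pc @ R.T - Qc
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _select_calpha(model: StructureModel, chain_id: str | None,
                   residue_range: tuple[int, int] | None
                   ) -> dict[tuple[str, int, str], np.ndarray]:
    out = {}
    for a in model.atoms:
        if a.atom_name != "CA" or a.is_hydrogen:
            continue
        if chain_id is not None and a.chain_id != chain_id:
            continue
        if residue_range is not None and not (
            residue_range[0] <= a.residue_number <= residue_range[1]
        ):
            continue
        out[(a.chain_id, a.residue_number, a.insertion_code)] = np.array(a.xyz)
    return out


def calpha_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_id: str | None = None,
    residue_range: tuple[int, int] | None = None,
) -> tuple[float, int]:
    """C-alpha RMSD between two structures after optimal superposition.

    Residues are matched by (chain, residue number, insertion code)
    intersection within the selection.  Returns (rmsd, n_matched).
    """
    ca_a = _select_calpha(model_a, chain_id, residue_range)
    ca_b = _select_calpha(model_b, chain_id, residue_range)
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise MatchingError(
            f"only {len(common)} matched C-alpha pairs (need >= 3); "
            f"selection chain={chain_id}, range={residue_range}"
        )
    P = np.array([ca_a[k] for k in common])
    Q = np.array([ca_b[k] for k in common])
    return _kabsch_rmsd(P, Q), len(common)


def normalized_bfactors(
    model: StructureModel,
    chain_id: str | None = None,
    residue_range: tuple[int, int] | None = None,
    calpha_only: bool = False,
) -> ResidueBFactorProfile:
    """Per-residue B-factors divided by the overall B-factor of the selection.

    residue mean_b = unweighted mean over the residue's non-hydrogen
    atoms (or its C-alpha only); overall_b = mean over all selected
    non-hydrogen atoms; normalized_b = mean_b / overall_b.  The
    atom-count-weighted mean of normalized_b over the selection is 1 by
    construction.
    """
    per_res: dict[tuple[str, int], list[float]] = {}
    res_names: dict[tuple[str, int], str] = {}
    all_b: list[float] = []
    for a in model.atoms:
        if a.is_hydrogen:
            continue
        if chain_id is not None and a.chain_id != chain_id:
            continue
        if residue_range is not None and not (
            residue_range[0] <= a.residue_number <= residue_range[1]
        ):
            continue
        if calpha_only and a.atom_name != "CA":
            continue
        key = (a.chain_id, a.residue_number)
        per_res.setdefault(key, []).append(a.b_factor)
        res_names[key] = a.residue_name
        all_b.append(a.b_factor)
    if not per_res:
        raise SelectionError(
            f"empty selection (chain={chain_id}, range={residue_range})"
        )
    overall = float(np.mean(all_b))
    if overall <= 0:
        raise DomainError(f"overall B-factor of selection is {overall}; cannot normalize")
    entries = [
        (c, r, res_names[(c, r)], float(np.mean(bs)), float(np.mean(bs) / overall))
        for (c, r), bs in sorted(per_res.items())
    ]
    return ResidueBFactorProfile(
        entries=entries, overall_b=overall,
        n_atoms_per_residue={k: len(v) for k, v in per_res.items()},
    )


def bfactor_delta(
    profile_a: ResidueBFactorProfile, profile_b: ResidueBFactorProfile
) -> list[tuple[str, int, float, str]]:
    """Per-residue normalized-B difference (a - b) with a sign class.

    The class is ``decreased`` (normalized B smaller in structure a —
    the "blue" coloring convention for stabilization), ``increased``
    ("red"), or ``unchanged``.  Raises MatchingError if no residues match.
    """
    na = profile_a.normalized()
    nb = profile_b.normalized()
    common = sorted(set(na) & set(nb))
    if not common:
        raise MatchingError("profiles share no residues")
    out = []
    for c, r in common:
        delta = na[(c, r)] - nb[(c, r)]
        cls = "unchanged" if delta == 0 else ("decreased" if delta < 0 else "increased")
        out.append((c, r, float(delta), cls))
    return out


def dihedral(
    model: StructureModel,
    sel1: AtomSelector,
    sel2: AtomSelector,
    sel3: AtomSelector,
    sel4: AtomSelector,
) -> float:
    """Signed torsion angle (degrees, (-180, 180]) over four atoms.

    IUPAC convention: looking down the 2->3 bond, the angle from the
    1-2-3 plane to the 2-3-4 plane, positive clockwise.
    """
    sels = [sel1, sel2, sel3, sel4]
    atoms = [model.resolve(s) for s in sels]
    if len({id(a) for a in atoms}) != 4 or len(set(sels)) != 4:
        raise SelectionError("dihedral requires four distinct atoms")
    p = [np.array(a.xyz) for a in atoms]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DomainError("undefined torsion: three consecutive atoms are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang
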