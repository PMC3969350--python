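"""Peptide structure model, PDB I/O and geometry utilities.

The data model is deliberately small: a peptide is an ordered list of
residues, each holding its atoms with van der Waals radii, side-chain
membership, formal-charge shares and hydrogen-bond-donor flags already
assigned.  Cyclic-cystine-knot (CCK) peptides additionally carry the
inter-cysteine loop annotation (loops 1-6) that anchors all sequence
comparison between cyclotide subfamilies.

vdW radii follow Bondi (1964), applied uniformly to every structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Peptide",
    "BONDI_RADII",
    "read_pdb",
    "write_pdb",
    "assign_loops",
    "build_extended_tripeptide",
    "rmsd_ca",
    "ParseError",
    "AnnotationError",
    "UnsupportedResidueError",
]

# Bondi (1964) vdW radii, Å.  Uniform table; elements absent default to carbon.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
}
_DEFAULT_RADIUS = 1.70

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"}

# Formal charges of side chains at pH 7.4 and the heavy atoms the charge is
# shared over (the terminal atoms of the charged group).
_CHARGE_TABLE = {
    "ARG": (+1, ("NH1", "NH2")),
    "LYS": (+1, ("NZ",)),
    "ASP": (-1, ("OD1", "OD2")),
    "GLU": (-1, ("OE1", "OE2")),
    # modified residues of the packaged scale: acetyl-Lys is neutral,
    # cyclohexanedione-Arg keeps the +1 of the parent guanidinium
    "CDR": (+1, ("NH1", "NH2")),
    "ACK": (0, ()),
}


class ParseError(ValueError):
    """Raised for unreadable or empty structure files."""


class AnnotationError(ValueError):
    """Raised when CCK loop annotation preconditions fail."""


class UnsupportedResidueError(KeyError):
    """Raised for residue codes with no geometry template or scale entry."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    vdw_radius: float
    formal_charge_share: float = 0.0
    is_sidechain: bool = False
    is_hbd: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    code: str
    index: int
    atoms: list[Atom] = field(default_factory=list)
    loop_id: int | None = None
    formal_charge: int = 0

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.code}{self.index} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_sidechain]

    def sidechain_heavy_centroid(self) -> np.ndarray | None:
        pts = [a.coords for a in self.sidechain_atoms if a.is_heavy]
        if not pts:
            return None
        return np.mean(pts, axis=0)


@dataclass
class Peptide:
    label: str
    residues: list[Residue] = field(default_factory=list)
    cyclic: bool = False
    disulfides: list[tuple[int, int]] = field(default_factory=list)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def center(self) -> np.ndarray:
        """Unweighted geometric center of the heavy atoms."""
        pts = [a.coords for a in self.atoms if a.is_heavy]
        if not pts:
            raise ParseError(f"peptide {self.label!r} has no heavy atoms")
        return np.mean(pts, axis=0)

    @property
    def sequence(self) -> list[str]:
        return [r.code for r in self.residues]

    def cys_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.residues) if r.code == "CYS"]

    def translate(self, shift) -> "Peptide":
        shift = np.asarray(shift, dtype=float)
        for a in self.atoms:
            a.coords = a.coords + shift
        return self

    def rotate(self, rotation: np.ndarray) -> "Peptide":
        rotation = np.asarray(rotation, dtype=float)
        for a in self.atoms:
            a.coords = rotation @ a.coords
        return self


def _finalize_residue(res: Residue) -> None:
    """Assign side-chain membership, formal-charge shares and HBD flags."""
    for a in res.atoms:
        a.is_sidechain = a.name not in BACKBONE_ATOMS
    charge, group = _CHARGE_TABLE.get(res.code, (0, ()))
    res.formal_charge = charge
    if charge == 0:
        return
    carriers = [a for a in res.atoms if a.name in group]
    if not carriers:
        # fall back to side-chain N/O, then to any side-chain heavy atom
        carriers = [a for a in res.atoms if a.is_sidechain and a.element in ("N", "O")]
    if not carriers:
        carriers = [a for a in res.atoms if a.is_sidechain and a.is_heavy]
    for a in carriers:
        a.formal_charge_share = charge / len(carriers)
    if charge > 0:
        # HBD surface substrate: donor heavy atoms of positively charged side
        # chains and any hydrogens bonded to them (matched here by name prefix).
        donor_names = {a.name for a in carriers}
        for a in res.atoms:
            if a.name in donor_names:
                a.is_hbd = True
            elif a.element == "H" and a.is_sidechain and any(
                a.name.startswith("H" + dn[1:]) for dn in donor_names
            ):
                a.is_hbd = True


def make_residue(code: str, index: int, atoms: list[Atom]) -> Residue:
    """Build a residue and run the standard annotation pass."""
    res = Residue(code=code, index=index, atoms=atoms)
    _finalize_residue(res)
    return res


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def read_pdb(path, label: str | None = None, cyclic: bool = False) -> Peptide:
    """Read a single-model PDB file into a :class:`Peptide`.

    Unknown residue codes are kept as-is; radii come from the Bondi table.
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises assorted types
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(f"PDB file {path} contains no atoms")

    residues: list[Residue] = []
    order: list[tuple] = []
    groups: dict[tuple, list[int]] = {}
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], arr.res_id[i], arr.ins_code[i])
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)

    for seq_index, key in enumerate(order, start=1):
        idx = groups[key]
        code = str(arr.res_name[idx[0]]).strip().upper()
        atoms = []
        for i in idx:
            element = str(arr.element[i]).strip().upper()
            atoms.append(
                Atom(
                    name=str(arr.atom_name[i]).strip(),
                    element=element,
                    coords=np.array(arr.coord[i], dtype=float),
                    vdw_radius=BONDI_RADII.get(element, _DEFAULT_RADIUS),
                )
            )
        residues.append(make_residue(code, seq_index, atoms))

    return Peptide(label=label or path.stem, residues=residues, cyclic=cyclic)


def write_pdb(peptide: Peptide, path) -> None:
    """Write a peptide as a single-model PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n = sum(len(r.atoms) for r in peptide.residues)
    arr = struc.AtomArray(n)
    i = 0
    for res in peptide.residues:
        for a in res.atoms:
            arr.coord[i] = a.coords
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            arr.res_name[i] = res.code
            arr.res_id[i] = res.index
            arr.chain_id[i] = "A"
            arr.hetero[i] = False
            i += 1
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# CCK loop annotation
# ---------------------------------------------------------------------------

def _canonical_anchor(peptide: Peptide) -> int:
    """Pick the anchor Cys giving the lexicographically smallest rotation.

    This makes loop numbering invariant to cyclic rotation of the input
    residue order, which the file convention (first residue = loop-1 Cys)
    is not.
    """
    codes = peptide.sequence
    n = len(codes)
    best = None
    best_rot = None
    for c in peptide.cys_indices():
        rot = tuple(codes[(c + k) % n] for k in range(n))
        if best_rot is None or rot < best_rot:
            best_rot = rot
            best = c
    return best


def assign_loops(peptide: Peptide, anchor: int | None = None) -> Peptide:
    """Annotate inter-cysteine loops 1-6 in place (and return the peptide).

    Loop ``k`` comprises the residues strictly between Cys ``k`` and Cys
    ``k+1``; loop 6 wraps across the ligation point for cyclic peptides and
    is split at the chain termini for linear ones.  Cysteines themselves
    carry no loop id.

    Parameters
    ----------
    anchor
        0-based residue index of the loop-1 cysteine.  Defaults to the
        canonical (rotation-invariant) choice for cyclic peptides and to
        the first cysteine in chain order for linear ones.
    """
    cys = peptide.cys_indices()
    if len(cys) != 6:
        raise AnnotationError(
            f"CCK annotation requires exactly 6 Cys, found {len(cys)} in {peptide.label!r}"
        )
    n = len(peptide.residues)
    for r in peptide.residues:
        r.loop_id = None

    if anchor is None:
        anchor = _canonical_anchor(peptide) if peptide.cyclic else cys[0]
    if anchor not in cys:
        raise AnnotationError(f"anchor index {anchor} is not a cysteine")

    # cysteines in cyclic order starting from the anchor
    k0 = cys.index(anchor)
    ordered = cys[k0:] + cys[:k0]
    for k in range(6):
        a = ordered[k]
        b = ordered[(k + 1) % 6]
        pos = (a + 1) % n
        while pos != b:
            peptide.residues[pos].loop_id = k + 1
            pos = (pos + 1) % n
    if not peptide.cyclic:
        # loop 6 is split at the termini; membership is identical, the chain
        # break simply means the segment is open.  Nothing further to do: the
        # wrap above already labels the pre-anchor and post-Cys6 residues 6.
        pass
    return peptide


# ---------------------------------------------------------------------------
# Extended Gly-X-Gly tripeptide builder
# ---------------------------------------------------------------------------

# ideal backbone internal coordinates (Engh & Huber averages)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = math.radians(111.0)
_A_CA_C_N = math.radians(116.6)
_A_C_N_CA = math.radians(121.7)
_A_CA_C_O = math.radians(120.5)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement of atom d given chain a-b-c and internal coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(angle),
        -bond * math.sin(angle) * math.cos(dihedral),
        -bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids so that R @ (P - cP) ≈ Q - cQ."""
    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    H = (P - cP).T @ (Q - cQ)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cP, cQ


def _residue_template(code: str, geometry: dict | None = None):
    """Idealized atom template: list of (name, element, coords) for one residue."""
    if geometry is not None and code in geometry:
        return geometry[code]
    import biotite.structure.info as info

    try:
        arr = info.residue(code)
    except Exception as exc:
        raise UnsupportedResidueError(
            f"no geometry template for residue code {code!r}; supply a geometry file"
        ) from exc
    if arr is None:
        raise UnsupportedResidueError(
            f"no geometry template for residue code {code!r}; supply a geometry file"
        )
    return [
        (str(arr.atom_name[i]), str(arr.element[i]).upper(), np.array(arr.coord[i], dtype=float))
        for i in range(arr.array_length())
    ]


def build_extended_tripeptide(code: str, geometry: dict | None = None,
                              include_hydrogens: bool = True) -> Peptide:
    """Build Gly-X-Gly with Φ = ψ = ω = 180° and X's side chain attached.

    The backbone is generated from ideal internal coordinates in the fully
    extended conformation.  The side chain of the central residue is taken
    from an idealized residue template (bundled chemical-component geometry,
    or a user-supplied ``geometry`` mapping ``code -> [(name, element,
    xyz)]``) and grafted by superposing the template's N/CA/C frame onto
    the built backbone.  Side-chain hydrogens are kept by default so the
    maximal side-chain surface areas include the hydrogen envelope.
    """
    code = code.upper()
    template = _residue_template(code, geometry)

    # --- extended backbone for three residues -----------------------------
    pi = math.pi
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    c0 = _place(np.array([-1.0, 1.0, 0.0]), n0, ca0, _B_CA_C, _A_N_CA_C, pi)
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(2):
        prev = coords[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, pi)   # psi = 180
        ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, pi)          # omega = 180
        c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, pi)                   # phi = 180
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: dihedral N-CA-C-O = psi + 180 = 0
    for i in range(3):
        nxt_n = coords[i + 1]["N"] if i < 2 else None
        if nxt_n is None:
            o = _place(coords[i]["N"], coords[i]["CA"], coords[i]["C"], _B_C_O, _A_CA_C_O, 0.0)
        else:
            o = _place(coords[i]["N"], coords[i]["CA"], coords[i]["C"], _B_C_O, _A_CA_C_O, 0.0)
        coords[i]["O"] = o

    residues = []
    for i, res_code in enumerate(["GLY", code, "GLY"]):
        atoms = [
            Atom(name=nm, element=nm[0], coords=coords[i][nm],
                 vdw_radius=BONDI_RADII[nm[0]])
            for nm in ("N", "CA", "C", "O")
        ]
        residues.append(make_residue(res_code, i + 1, atoms))

    # --- graft side chain of X --------------------------------------------
    tmpl_by_name = {nm: (el, xyz) for nm, el, xyz in template}
    for req in ("N", "CA", "C"):
        if req not in tmpl_by_name:
            raise UnsupportedResidueError(
                f"geometry template for {code!r} lacks backbone atom {req}"
            )
    P = np.array([tmpl_by_name[nm][1] for nm in ("N", "CA", "C")])
    Q = np.array([coords[1][nm] for nm in ("N", "CA", "C")])
    R, cP, cQ = _kabsch_rotation(P, Q)
    central = residues[1]
    for nm, el, xyz in template:
        if nm in BACKBONE_ATOMS:
            continue
        if el == "H" and not include_hydrogens:
            continue
        new = R @ (xyz - cP) + cQ
        central.atoms.append(
            Atom(name=nm, element=el, coords=new,
                 vdw_radius=BONDI_RADII.get(el, _DEFAULT_RADIUS))
        )
    _finalize_residue(central)
    pep = Peptide(label=f"G{code.capitalize()}G", residues=residues, cyclic=False)
    return pep


# ---------------------------------------------------------------------------
# Cα RMSD
# ---------------------------------------------------------------------------

def rmsd_ca(a: Peptide, b: Peptide, superpose: bool = True) -> float:
    """Cα root-mean-square deviation in Å, optionally after optimal
    least-squares rigid superposition (Kabsch)."""
    if len(a.residues) != len(b.residues):
        raise ValueError(
            f"residue count mismatch: {len(a.residues)} vs {len(b.residues)}"
        )
    P = np.array([r.atom("CA").coords for r in a.residues])
    Q = np.array([r.atom("CA").coords for r in b.residues])
    if superpose:
        R, cP, cQ = _kabsch_rotation(P, Q)
        P = (P - cP) @ R.T + cQ
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
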