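"""Domain types, standard-format I/O, and synthetic protein–ligand fixtures.

The package represents a molecule (or pocket) as a typed 3D point set: a
one-hot element matrix, Cartesian coordinates in Å, and a mask separating
real atoms from virtual padding slots used by the variable-size R-group
stage.  Standard formats go through the usual libraries — PDB files through
Biopython, SDF v2000 through RDKit.

A small catalog of ideal-geometry molecules (tabulated bond lengths and
angles) plus a pseudo-atom pocket shell makes every downstream module
testable without any external data: the catalog's reference bond lists are
consistent with its geometries, so fixtures double as ground truth for bond
reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    CatalogError,
    EmptyInputError,
    FormatError,
    ParameterError,
)

# Shared element vocabulary.  Hydrogens are implicit everywhere except the
# explicit-H option on fixtures; anything outside the list maps to "other".
# A final "virtual" category marks padding slots in the R-group stage.
ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "other")
VIRTUAL = "virtual"
CATEGORIES = ELEMENTS + (VIRTUAL,)
N_CATEGORIES = len(CATEGORIES)
VIRTUAL_INDEX = N_CATEGORIES - 1

BOND_CLASSES = ("single", "double", "aromatic", "triple")

#: Tetrahedral angle, degrees.
TETRAHEDRAL = math.degrees(math.acos(-1.0 / 3.0))


def element_index(symbol: str) -> int:
    """Map an element symbol to its category index ("other" if unknown)."""
    if symbol == VIRTUAL:
        return VIRTUAL_INDEX
    try:
        return ELEMENTS.index(symbol)
    except ValueError:
        return ELEMENTS.index("other")


def onehot_from_symbols(symbols) -> np.ndarray:
    out = np.zeros((len(symbols), N_CATEGORIES))
    for i, s in enumerate(symbols):
        out[i, element_index(s)] = 1.0
    return out


@dataclass
class AtomSet:
    """Typed 3D point set: one-hot elements, coordinates (Å), real mask."""

    element_onehot: np.ndarray
    coords: np.ndarray
    real_mask: np.ndarray

    def __post_init__(self):
        self.element_onehot = np.asarray(self.element_onehot, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.real_mask = np.asarray(self.real_mask, dtype=bool).reshape(-1)
        n = len(self.real_mask)
        if self.element_onehot.shape != (n, N_CATEGORIES):
            raise ParameterError(
                f"element_onehot shape {self.element_onehot.shape} != "
                f"({n}, {N_CATEGORIES})"
            )
        if self.coords.shape != (n, 3):
            raise ParameterError("coords shape mismatch")
        if not np.isfinite(self.coords).all():
            raise ParameterError("non-finite coordinates")
        rowsum = self.element_onehot.sum(axis=1)
        if n and not np.allclose(rowsum, 1.0):
            raise ParameterError("one-hot rows must sum to 1")

    @classmethod
    def from_symbols(cls, symbols, coords, real_mask=None) -> "AtomSet":
        if real_mask is None:
            real_mask = np.ones(len(symbols), dtype=bool)
        return cls(onehot_from_symbols(symbols), coords, real_mask)

    @property
    def n(self) -> int:
        return len(self.real_mask)

    @property
    def symbols(self) -> list:
        return [CATEGORIES[i] for i in self.element_onehot.argmax(axis=1)]

    def subset(self, indices) -> "AtomSet":
        idx = np.asarray(indices, dtype=int)
        return AtomSet(
            self.element_onehot[idx], self.coords[idx], self.real_mask[idx]
        )

    def copy(self) -> "AtomSet":
        return AtomSet(
            self.element_onehot.copy(),
            self.coords.copy(),
            self.real_mask.copy(),
        )


def concat_atomsets(sets) -> AtomSet:
    sets = list(sets)
    return AtomSet(
        np.concatenate([s.element_onehot for s in sets]),
        np.concatenate([s.coords for s in sets]),
        np.concatenate([s.real_mask for s in sets]),
    )


@dataclass
class PocketContext:
    """Heavy-atom protein pocket with per-atom residue labels."""

    atoms: AtomSet
    residue_labels: list
    source_id: str = ""

    def __post_init__(self):
        if len(self.residue_labels) != self.atoms.n:
            raise ParameterError("one residue label per pocket atom")
        if not self.atoms.real_mask.all():
            raise ParameterError("pockets contain no virtual atoms")


@dataclass
class FragmentSeed:
    """A fragment with anchor atoms marking growth sites.

    ``record`` optionally carries the fragment's bonded subgraph as a
    :class:`MoleculeRecord` (set by the fragmenter); descriptor computation
    falls back to geometric bond perception when it is absent.
    """

    atoms: AtomSet
    anchors: tuple = ()
    record: object = None

    def __post_init__(self):
        self.anchors = tuple(int(a) for a in self.anchors)
        if any(a < 0 or a >= self.atoms.n for a in self.anchors):
            raise ParameterError("anchor index out of range")


@dataclass
class MoleculeRecord:
    """Assembled molecule: atoms, typed bonds, validity, properties.

    ``symbols`` carries the true element symbols (the one-hot vocabulary
    collapses rare elements to "other", which cannot be serialized).
    """

    atoms: AtomSet
    symbols: list
    bonds: list
    valid: bool = True
    properties: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.symbols) != self.atoms.n:
            raise ParameterError("one symbol per atom")
        seen = set()
        for i, j, cls in self.bonds:
            if i == j:
                raise ParameterError("self-bond")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ParameterError("duplicate bond")
            seen.add(key)
            if cls not in BOND_CLASSES:
                raise ParameterError(f"unknown bond class {cls!r}")

    @property
    def n_heavy(self) -> int:
        return sum(1 for s in self.symbols if s != "H")

    def bond_set(self) -> set:
        return {(min(i, j), max(i, j), c) for i, j, c in self.bonds}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Deterministic recipe for a synthetic pocket–ligand complex."""

    template_name: str
    pocket_shell_radius: float = 6.0
    seed: int = 0
    n_pocket_atoms: int = 16
    explicit_h: bool = False


# ---------------------------------------------------------------------------
# RDKit bridge
# ---------------------------------------------------------------------------

_RD_BOND = None


def _rd():
    global _RD_BOND
    from rdkit import Chem

    if _RD_BOND is None:
        _RD_BOND = {
            "single": Chem.BondType.SINGLE,
            "double": Chem.BondType.DOUBLE,
            "aromatic": Chem.BondType.AROMATIC,
            "triple": Chem.BondType.TRIPLE,
        }
    return Chem


def to_rdkit(record: MoleculeRecord, sanitize: bool = True):
    """Build an RDKit molecule (with conformer) from a record."""
    Chem = _rd()
    rw = Chem.RWMol()
    for s in record.symbols:
        try:
            rw.AddAtom(Chem.Atom(s))
        except Exception:
            rw.AddAtom(Chem.Atom(0))  # non-element category -> dummy atom
    for i, j, cls in record.bonds:
        rw.AddBond(int(i), int(j), _RD_BOND[cls])
        if cls == "aromatic":
            rw.GetAtomWithIdx(int(i)).SetIsAromatic(True)
            rw.GetAtomWithIdx(int(j)).SetIsAromatic(True)
    mol = rw.GetMol()
    conf = Chem.Conformer(record.atoms.n)
    for i, xyz in enumerate(record.atoms.coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    mol.AddConformer(conf)
    if sanitize:
        Chem.SanitizeMol(mol)
    return mol


def from_rdkit(mol, keep_hs: bool = False) -> MoleculeRecord:
    """Convert an RDKit molecule (3D conformer expected) to a record."""
    Chem = _rd()
    valid = True
    try:
        Chem.SanitizeMol(Chem.Mol(mol))
    except Exception:
        valid = False
    if not keep_hs:
        try:
            mol = Chem.RemoveHs(mol, sanitize=valid)
        except Exception:
            valid = False
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    if mol.GetNumConformers():
        coords = mol.GetConformer().GetPositions()
    else:
        coords = np.zeros((len(symbols), 3))
    inv_bond = {v: k for k, v in _RD_BOND.items()}
    bonds = []
    for b in mol.GetBonds():
        cls = inv_bond.get(b.GetBondType())
        if cls is None:
            cls = "single"
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), cls))
    props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
    rec = MoleculeRecord(
        AtomSet.from_symbols(symbols, coords), symbols, bonds, valid, props
    )
    if rec.valid:
        # validity must hold for the rebuilt graph, not just the parsed one
        try:
            to_rdkit(rec, sanitize=True)
        except Exception:
            rec.valid = False
    return rec


# ---------------------------------------------------------------------------
# PDB / SDF I/O
# ---------------------------------------------------------------------------


def read_pocket(path, ligand: MoleculeRecord | None = None,
                radius: float = 10.0) -> PocketContext:
    """Extract a heavy-atom pocket from a PDB file.

    Residue-level inclusion: every heavy atom of residues having any atom
    within ``radius`` Å of the ligand is kept (all heavy atoms if no ligand
    is given).  Waters are skipped.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    if radius <= 0:
        raise ParameterError("radius must be positive")
    try:
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("pocket", str(path))
    except (PDBConstructionException, ValueError, KeyError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    lig_coords = None
    if ligand is not None:
        lig_coords = ligand.atoms.coords[ligand.atoms.real_mask]

    symbols, coords, labels = [], [], []
    model = next(iter(structure), None)
    if model is None:
        raise FormatError(f"no model in PDB file {path}")
    for chain in model:
        for residue in chain:
            if residue.get_resname().strip() == "HOH":
                continue
            res_atoms = [
                a for a in residue
                if (a.element or "").strip().upper() not in ("H", "D", "")
            ]
            if not res_atoms:
                continue
            if lig_coords is not None:
                rc = np.array([a.coord for a in res_atoms], dtype=float)
                if cdist(rc, lig_coords).min() > radius:
                    continue
            label = (
                f"{chain.id}:{residue.get_resname().strip()}:"
                f"{residue.get_id()[1]}"
            )
            for a in res_atoms:
                symbols.append(a.element.strip().capitalize())
                coords.append(np.asarray(a.coord, dtype=float))
                labels.append(label)
    if not symbols:
        raise EmptyInputError(f"empty pocket selection from {path}")
    return PocketContext(
        AtomSet.from_symbols(symbols, np.array(coords)), labels, str(path)
    )


def write_pocket(pocket: PocketContext, path) -> None:
    """Serialize a pocket as a PDB file (one atom per ATOM record)."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("pocket")
    builder.init_model(0)
    builder.init_seg("    ")
    current = None
    serial = 1
    counts: dict = {}
    for sym, xyz, label in zip(
        pocket.atoms.symbols, pocket.atoms.coords, pocket.residue_labels
    ):
        chain_id, resname, resseq = label.split(":")
        if current != label:
            if current is None or current.split(":")[0] != chain_id:
                builder.init_chain(chain_id)
            builder.init_residue(resname, " ", int(resseq), " ")
            current = label
            counts = {}
        counts[sym] = counts.get(sym, 0) + 1
        name = f"{sym.upper()}{counts[sym]}"[:4]
        builder.init_atom(
            name,
            np.asarray(xyz, dtype=float),
            0.0,
            1.0,
            " ",
            name,
            serial,
            element=sym.upper(),
        )
        serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def read_ligands(path) -> list:
    """Read a (possibly multi-record) SDF; invalid records are kept with
    ``valid=False`` rather than dropped."""
    Chem = _rd()
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    records = []
    n_seen = 0
    for mol in supplier:
        n_seen += 1
        if mol is None:
            records.append(
                MoleculeRecord(
                    AtomSet.from_symbols([], np.zeros((0, 3))),
                    [],
                    [],
                    valid=False,
                    properties={"error": "unparseable SDF record"},
                )
            )
            continue
        records.append(from_rdkit(mol))
    if n_seen == 0:
        raise EmptyInputError(f"no records in SDF file {path}")
    return records


def read_smiles(path) -> list:
    """Read a SMILES list (one per line, optional name column)."""
    Chem = _rd()
    records = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                continue
            rec = from_rdkit(mol)
            if len(parts) > 1:
                rec.properties["name"] = parts[1]
            records.append(rec)
    if not records:
        raise EmptyInputError(f"no SMILES parsed from {path}")
    return records


def write_molecules(records, path) -> None:
    """Write records as SDF v2000; virtual atoms are never serialized."""
    Chem = _rd()
    if not records:
        raise EmptyInputError("no records to write")
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for rec in records:
            if not rec.atoms.real_mask.all():
                keep = np.flatnonzero(rec.atoms.real_mask)
                remap = {int(o): i for i, o in enumerate(keep)}
                rec = MoleculeRecord(
                    rec.atoms.subset(keep),
                    [rec.symbols[int(o)] for o in keep],
                    [
                        (remap[i], remap[j], c)
                        for i, j, c in rec.bonds
                        if i in remap and j in remap
                    ],
                    rec.valid,
                    dict(rec.properties),
                )
            mol = to_rdkit(rec, sanitize=False)
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                pass
            for k, v in rec.properties.items():
                mol.SetProp(str(k), str(v))
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Ideal-geometry fixture catalog
# ---------------------------------------------------------------------------


def _chain(lengths, angle_deg=TETRAHEDRAL):
    """Planar zig-zag chain with given bond lengths and vertex angle."""
    delta = math.radians(180.0 - angle_deg)
    coords = [np.zeros(3)]
    for k, length in enumerate(lengths):
        h = 0.0 if k % 2 == 0 else delta
        coords.append(
            coords[-1] + length * np.array([math.cos(h), math.sin(h), 0.0])
        )
    return np.array(coords)


def _place(origin, toward, length, angle_deg, sign=1):
    """Place a new atom at ``length`` from ``origin`` making ``angle_deg``
    with the origin→toward direction, in the xy-plane."""
    u = np.asarray(toward, float) - np.asarray(origin, float)
    u = u / np.linalg.norm(u)
    th = sign * math.radians(angle_deg)
    rot = np.array(
        [
            [math.cos(th), -math.sin(th), 0.0],
            [math.sin(th), math.cos(th), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    return np.asarray(origin, float) + length * (rot @ u)


def _ring6(side=1.39):
    r = side  # hexagon circumradius equals its side
    return np.array(
        [
            [r * math.cos(k * math.pi / 3), r * math.sin(k * math.pi / 3), 0]
            for k in range(6)
        ]
    )


def _build_catalog():
    cat = {}

    def add(name, symbols, coords, bonds, partition=None, h_coords=None):
        cat[name] = {
            "symbols": list(symbols),
            "coords": np.asarray(coords, float),
            "bonds": [(int(i), int(j), c) for i, j, c in bonds],
            "partition": partition,
            "h_coords": h_coords,
        }

    # methane with optional explicit hydrogens (tetrahedral, C-H 1.09 Å)
    h_dirs = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
    ) / math.sqrt(3.0)
    add("methane", ["C"], [[0, 0, 0]], [], h_coords=1.09 * h_dirs)

    add(
        "ethane", ["C", "C"], _chain([1.54]), [(0, 1, "single")],
        partition={"fragment": [0], "anchors": [0],
                   "scaffold": [0, 1], "rgroup": []},
    )
    add("ethylene", ["C", "C"], _chain([1.33]), [(0, 1, "double")])
    add("acetylene", ["C", "C"], _chain([1.20]), [(0, 1, "triple")])
    add("methanol", ["C", "O"], _chain([1.43]), [(0, 1, "single")])
    add("methylamine", ["C", "N"], _chain([1.47]), [(0, 1, "single")])
    add("formaldehyde", ["C", "O"], _chain([1.21]), [(0, 1, "double")])
    add(
        "ethanol",
        ["C", "C", "O"],
        _chain([1.54, 1.43]),
        [(0, 1, "single"), (1, 2, "single")],
        partition={"fragment": [0], "anchors": [0],
                   "scaffold": [0, 1], "rgroup": [2]},
    )
    add(
        "propane",
        ["C", "C", "C"],
        _chain([1.54, 1.54]),
        [(0, 1, "single"), (1, 2, "single")],
        partition={"fragment": [0], "anchors": [0],
                   "scaffold": [0, 1], "rgroup": [2]},
    )
    add(
        "dimethyl_ether",
        ["C", "O", "C"],
        _chain([1.43, 1.43], angle_deg=111.0),
        [(0, 1, "single"), (1, 2, "single")],
    )
    add(
        "acetonitrile",
        ["C", "C", "N"],
        _chain([1.46, 1.16], angle_deg=180.0),
        [(0, 1, "single"), (1, 2, "triple")],
    )

    # acetic acid: C0-C1(=O2)-O3
    c0 = np.zeros(3)
    c1 = np.array([1.50, 0.0, 0.0])
    o2 = _place(c1, c0, 1.21, 126.0, +1)
    o3 = _place(c1, c0, 1.36, 112.0, -1)
    add(
        "acetic_acid",
        ["C", "C", "O", "O"],
        [c0, c1, o2, o3],
        [(0, 1, "single"), (1, 2, "double"), (1, 3, "single")],
    )

    # N-methylacetamide: C0-C1(=O2)-N3-C4 (trans amide)
    c1 = np.array([1.51, 0.0, 0.0])
    o2 = _place(c1, c0, 1.23, 121.0, +1)
    n3 = _place(c1, c0, 1.34, 115.0, -1)
    c4a = _place(n3, c1, 1.45, 122.0, +1)
    c4b = _place(n3, c1, 1.45, 122.0, -1)
    c4 = c4a if np.linalg.norm(c4a - o2) > np.linalg.norm(c4b - o2) else c4b
    add(
        "n_methylacetamide",
        ["C", "C", "O", "N", "C"],
        [c0, c1, o2, n3, c4],
        [(0, 1, "single"), (1, 2, "double"), (1, 3, "single"),
         (3, 4, "single")],
    )

    ring = _ring6()
    ring_bonds = [(k, (k + 1) % 6, "aromatic") for k in range(6)]
    add(
        "benzene", ["C"] * 6, ring, ring_bonds,
        partition={"fragment": [0, 1, 2], "anchors": [0, 2],
                   "scaffold": [0, 1, 2, 3, 4, 5], "rgroup": []},
    )

    o6 = np.array([1.39 + 1.36, 0.0, 0.0])
    add(
        "phenol", ["C"] * 6 + ["O"],
        np.vstack([ring, o6]),
        ring_bonds + [(0, 6, "single")],
    )

    o6 = np.array([1.39 + 1.36, 0.0, 0.0])
    c7 = _place(o6, ring[0], 1.43, 117.0, +1)
    add(
        "methyl_phenyl_ether",
        ["C"] * 6 + ["O", "C"],
        np.vstack([ring, o6, c7]),
        ring_bonds + [(0, 6, "single"), (6, 7, "single")],
        partition={"fragment": [0, 1, 2], "anchors": [0, 2],
                   "scaffold": [0, 1, 2, 3, 4, 5], "rgroup": [6, 7]},
    )

    # 4-methoxy-N-methylaniline: methoxyphenyl scaffold + N-methyl R-group
    o6 = _place(ring[3], ring[0], 1.36, 180.0)
    c7 = _place(o6, ring[3], 1.43, 117.0, +1)
    n8 = _place(ring[0], ring[3], 1.40, 180.0)
    c9 = _place(n8, ring[0], 1.45, 116.0, +1)
    add(
        "methoxy_methylaniline",
        ["C"] * 6 + ["O", "C", "N", "C"],
        np.vstack([ring, o6, c7, n8, c9]),
        ring_bonds
        + [(3, 6, "single"), (6, 7, "single"), (0, 8, "single"),
           (8, 9, "single")],
        partition={"fragment": [0, 1, 2], "anchors": [0, 2],
                   "scaffold": [0, 1, 2, 3, 4, 5, 6, 7],
                   "rgroup": [8, 9]},
    )
    return cat


_CATALOG = _build_catalog()


def list_templates() -> list:
    """Names of all fixture molecules in the internal catalog."""
    return sorted(_CATALOG)


def fixture_molecule(name: str, explicit_h: bool = False) -> MoleculeRecord:
    """Build the ideal-geometry fixture molecule ``name``."""
    if name not in _CATALOG:
        raise CatalogError(f"unknown template {name!r}")
    entry = _CATALOG[name]
    symbols = list(entry["symbols"])
    coords = entry["coords"].copy()
    bonds = list(entry["bonds"])
    if explicit_h:
        if entry["h_coords"] is None:
            raise CatalogError(f"template {name!r} has no explicit-H data")
        n0 = len(symbols)
        for k, xyz in enumerate(entry["h_coords"]):
            symbols.append("H")
            coords = np.vstack([coords, xyz])
            bonds.append((0, n0 + k, "single"))
    rec = MoleculeRecord(
        AtomSet.from_symbols(symbols, coords), symbols, bonds
    )
    try:
        to_rdkit(rec, sanitize=True)
        rec.valid = True
    except Exception:
        rec.valid = False
    rec.properties["template"] = name
    return rec


def fixture_panel(explicit_h: bool = False) -> list:
    """All catalog molecules (heavy-atom form unless ``explicit_h``)."""
    out = []
    for name in list_templates():
        try:
            out.append(fixture_molecule(name, explicit_h=explicit_h))
        except CatalogError:
            out.append(fixture_molecule(name))
    return out


def make_toy_complex(spec: ToyComplexSpec):
    """Deterministic synthetic complex for a catalog template.

    Returns ``(pocket, ligand, fragment_seed, scaffold, rgroup)``.  The
    pocket is a shell of pseudo-atoms at ``pocket_shell_radius`` around the
    ligand centroid; the fragment/scaffold/R-group partition comes from the
    template (fragment ⊆ scaffold ⊆ molecule, anchors at the partition
    boundary).
    """
    if spec.template_name not in _CATALOG:
        raise CatalogError(f"unknown template {spec.template_name!r}")
    entry = _CATALOG[spec.template_name]
    if entry["partition"] is None:
        raise CatalogError(
            f"template {spec.template_name!r} has no scaffold/R-group "
            "partition; see list_templates()"
        )
    ligand = fixture_molecule(spec.template_name, explicit_h=spec.explicit_h)
    heavy = ligand.atoms.coords[: len(entry["symbols"])]
    center = heavy.mean(axis=0)
    extent = float(np.linalg.norm(heavy - center, axis=1).max())
    if spec.pocket_shell_radius <= extent:
        raise ParameterError(
            f"pocket radius {spec.pocket_shell_radius} must exceed ligand "
            f"extent {extent:.2f}"
        )

    rng = np.random.default_rng(spec.seed)
    dirs = rng.normal(size=(spec.n_pocket_atoms, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pocket_coords = center + spec.pocket_shell_radius * dirs
    pocket_symbols = list(
        rng.choice(["C", "N", "O", "S"], size=spec.n_pocket_atoms,
                   p=[0.6, 0.15, 0.2, 0.05])
    )
    labels = [f"A:UNK:{i + 1}" for i in range(spec.n_pocket_atoms)]
    pocket = PocketContext(
        AtomSet.from_symbols(pocket_symbols, pocket_coords),
        labels,
        source_id=f"toy:{spec.template_name}:{spec.seed}",
    )

    part = entry["partition"]
    lig_atoms = ligand.atoms.subset(range(len(entry["symbols"])))
    frag_atoms = lig_atoms.subset(part["fragment"])
    fragment = FragmentSeed(frag_atoms, anchors=part["anchors"])
    scaffold = lig_atoms.subset(part["scaffold"])
    if part["rgroup"]:
        rgroup = lig_atoms.subset(part["rgroup"])
    else:
        rgroup = AtomSet.from_symbols([], np.zeros((0, 3)))
    return pocket, ligand, fragment, scaffold, rgroup


def template_partition(name: str) -> dict:
    """Atom-index partition (fragment/scaffold/rgroup/anchors) of a
    complex-capable template."""
    if name not in _CATALOG or _CATALOG[name]["partition"] is None:
        raise CatalogError(f"no partition for template {name!r}")
    return dict(_CATALOG[name]["partition"])
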