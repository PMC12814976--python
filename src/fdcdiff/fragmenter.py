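"""Reaction-informed preprocessing: BRICS fragmentation, Rule-of-Three
filtering, SMIRKS-template scaffold/R-group slicing, dataset assembly.

Molecules are cut twice.  A reaction-template pass slices each molecule
into a scaffold/R-group pair along a single acyclic bond matched by one of
the SMIRKS templates, so every cut corresponds to a feasible synthetic
disconnection.  A BRICS pass then cuts each scaffold at prototypical
synthetically accessible bonds; the cleavage sites become growth anchors,
and the resulting seeds are kept only if they are fragment-like under the
Rule of Three: MW < 300 Da, logP <= 3, at most 3 H-bond donors and 3
acceptors, TPSA <= 60 Å², and no rotatable bonds.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .chem_data import AtomSet, FragmentSeed, MoleculeRecord, to_rdkit
from .errors import EmptyInputError, ParameterError, ValidityError

__all__ = [
    "DescriptorRecord",
    "ReactionTemplate",
    "ScaffoldRGroupPair",
    "load_templates",
    "default_templates",
    "brics_decompose",
    "compute_descriptors",
    "ro3_filter",
    "slice_scaffold_rgroups",
    "build_dataset",
]


@dataclass
class DescriptorRecord:
    """The Rule-of-Three quantities of a fragment or molecule."""

    mw: float
    logp: float
    hbd: int
    hba: int
    tpsa: float
    rot_bonds: int

    def __post_init__(self):
        if self.mw <= 0 or self.hbd < 0 or self.hba < 0 or self.tpsa < 0:
            raise ParameterError("descriptor out of range")


@dataclass
class ReactionTemplate:
    """One reaction SMIRKS cleaving the bond between map atoms :1 and :2."""

    id: str
    smirks: str
    description: str = ""

    def __post_init__(self):
        from rdkit import Chem

        reactant = self.smirks.split(">>")[0]
        patt = Chem.MolFromSmarts(reactant)
        if patt is None:
            raise ParameterError(f"template {self.id}: bad SMIRKS pattern")
        mapped = {
            a.GetAtomMapNum(): a.GetIdx()
            for a in patt.GetAtoms()
            if a.GetAtomMapNum() in (1, 2)
        }
        if set(mapped) != {1, 2}:
            raise ParameterError(
                f"template {self.id}: needs map atoms :1 and :2"
            )
        if patt.GetBondBetweenAtoms(mapped[1], mapped[2]) is None:
            raise ParameterError(
                f"template {self.id}: map atoms :1 and :2 must be bonded"
            )
        self._pattern = patt
        self._map_idx = (mapped[1], mapped[2])


@dataclass
class ScaffoldRGroupPair:
    """A single-cut decomposition of a molecule.

    Attachment indices are local to each side's atom set; ``*_indices``
    map back to the source molecule so the pair provably reassembles.
    """

    scaffold: AtomSet
    scaffold_attachment: int
    rgroup: AtomSet
    rgroup_attachment: int
    template_id: str
    source: str = ""
    scaffold_indices: tuple = ()
    rgroup_indices: tuple = ()
    scaffold_record: MoleculeRecord | None = None
    rgroup_record: MoleculeRecord | None = None


def load_templates(path=None) -> list:
    """Load reaction templates from a YAML file (the shipped 10-template
    starter set when ``path`` is None)."""
    if path is None:
        ref = importlib.resources.files("fdcdiff.data").joinpath(
            "reaction_templates.yaml"
        )
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    templates = [
        ReactionTemplate(e["id"], e["smirks"], e.get("description", ""))
        for e in raw["templates"]
    ]
    if not templates:
        raise EmptyInputError("no templates in file")
    return templates


def default_templates() -> list:
    return load_templates(None)


def _subgraph_record(mol: MoleculeRecord, indices) -> MoleculeRecord:
    """Induced subgraph of a record, with local atom numbering."""
    indices = [int(i) for i in indices]
    remap = {o: k for k, o in enumerate(indices)}
    bonds = [
        (remap[i], remap[j], c)
        for i, j, c in mol.bonds
        if i in remap and j in remap
    ]
    rec = MoleculeRecord(
        mol.atoms.subset(indices),
        [mol.symbols[i] for i in indices],
        bonds,
        valid=mol.valid,
        properties={"source": mol.properties.get("template", "")},
    )
    try:
        to_rdkit(rec, sanitize=True)
        rec.valid = True
    except Exception:
        rec.valid = False
    return rec


def brics_decompose(mol: MoleculeRecord) -> list:
    """BRICS fragmentation with cleavage sites as growth anchors.

    The fragments partition the molecule's heavy atoms; each fragment's
    anchors are its atoms incident to cleaved bonds, and coordinates are
    inherited from the input.
    """
    from rdkit.Chem import BRICS

    if not mol.valid:
        raise ValidityError("brics_decompose requires a valid molecule")
    rd = to_rdkit(mol, sanitize=True)
    cut_bonds = [tuple(b[0]) for b in BRICS.FindBRICSBonds(rd)]
    n = mol.atoms.n
    # connected components of the graph minus the cut bonds
    adj = [[] for _ in range(n)]
    cut_set = {(min(i, j), max(i, j)) for i, j in cut_bonds}
    for i, j, _ in mol.bonds:
        if (min(i, j), max(i, j)) not in cut_set:
            adj[i].append(j)
            adj[j].append(i)
    comp = [-1] * n
    n_comp = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = n_comp
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp[v] < 0:
                    comp[v] = n_comp
                    stack.append(v)
        n_comp += 1
    anchor_atoms = {a for b in cut_bonds for a in b}
    seeds = []
    for c in range(n_comp):
        indices = [i for i in range(n) if comp[i] == c]
        local_anchor = [
            k for k, i in enumerate(indices) if i in anchor_atoms
        ]
        rec = _subgraph_record(mol, indices)
        seeds.append(
            FragmentSeed(rec.atoms, anchors=local_anchor, record=rec)
        )
    return seeds


def _as_rdkit(obj):
    if isinstance(obj, MoleculeRecord):
        return to_rdkit(obj, sanitize=True)
    if isinstance(obj, FragmentSeed):
        if obj.record is not None:
            return to_rdkit(obj.record, sanitize=True)
        # no stored subgraph: perceive bonds from geometry
        from .bond_builder import assemble_molecule, perceive_bonds_reference

        rec = assemble_molecule(obj.atoms, perceive_bonds_reference(obj.atoms))
        if not rec.valid:
            raise ValidityError("cannot sanitize fragment geometry")
        return to_rdkit(rec, sanitize=True)
    raise ParameterError(f"cannot compute descriptors for {type(obj)}")


def compute_descriptors(frag) -> DescriptorRecord:
    """Standard descriptor panel for a fragment or molecule.

    Donor/acceptor counting follows the simple heuristic the Rule of Three
    uses: donors are N-H/O-H hydrogens, acceptors are N and O atoms.
    """
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    try:
        rd = _as_rdkit(frag)
    except ValidityError:
        raise
    except Exception as exc:
        raise ValidityError(f"unsanitizable structure: {exc}") from exc
    return DescriptorRecord(
        mw=float(Descriptors.MolWt(rd)),
        logp=float(Crippen.MolLogP(rd)),
        hbd=int(Lipinski.NHOHCount(rd)),
        hba=int(Lipinski.NOCount(rd)),
        tpsa=float(rdMolDescriptors.CalcTPSA(rd)),
        rot_bonds=int(rdMolDescriptors.CalcNumRotatableBonds(rd)),
    )


def ro3_filter(frag) -> bool:
    """Rule-of-Three fragment-likeness: the conjunction of all six bounds."""
    d = compute_descriptors(frag)
    return (
        d.mw < 300.0
        and d.logp <= 3.0
        and d.hbd <= 3
        and d.hba <= 3
        and d.tpsa <= 60.0
        and d.rot_bonds == 0
    )


def slice_scaffold_rgroups(mol: MoleculeRecord, templates) -> list:
    """One scaffold/R-group pair per (template, matched acyclic bond).

    The larger component is the scaffold (ties broken by the lower minimum
    canonical rank); coordinates are inherited from the input.
    """
    from rdkit import Chem

    if not mol.valid:
        raise ValidityError("slice requires a valid molecule")
    if not templates:
        raise EmptyInputError("no templates given")
    rd = to_rdkit(mol, sanitize=True)
    ranks = list(Chem.CanonicalRankAtoms(rd))
    n = mol.atoms.n
    pairs = []
    seen_cuts = set()
    for tpl in templates:
        i1, i2 = tpl._map_idx
        for match in rd.GetSubstructMatches(tpl._pattern, uniquify=True):
            a, b = match[i1], match[i2]
            key = (tpl.id, min(a, b), max(a, b))
            if key in seen_cuts:
                continue
            bond = rd.GetBondBetweenAtoms(a, b)
            if bond is None or bond.IsInRing():
                continue
            seen_cuts.add(key)
            # components of the molecule with bond (a, b) removed
            adj = [[] for _ in range(n)]
            for i, j, _ in mol.bonds:
                if {i, j} == {a, b}:
                    continue
                adj[i].append(j)
                adj[j].append(i)
            side = [-1] * n
            stack, side[a] = [a], 0
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if side[v] < 0:
                        side[v] = 0
                        stack.append(v)
            comp_a = tuple(i for i in range(n) if side[i] == 0)
            comp_b = tuple(i for i in range(n) if side[i] != 0)
            if not comp_b:
                continue  # ring bond not split (shouldn't occur)
            size_a, size_b = len(comp_a), len(comp_b)
            if size_a > size_b:
                scaf_idx, rg_idx = comp_a, comp_b
            elif size_b > size_a:
                scaf_idx, rg_idx = comp_b, comp_a
            elif min(ranks[i] for i in comp_a) <= min(
                ranks[i] for i in comp_b
            ):
                scaf_idx, rg_idx = comp_a, comp_b
            else:
                scaf_idx, rg_idx = comp_b, comp_a
            scaf_rec = _subgraph_record(mol, scaf_idx)
            rg_rec = _subgraph_record(mol, rg_idx)
            s_att = scaf_idx.index(a if a in scaf_idx else b)
            r_att = rg_idx.index(b if a in scaf_idx else a)
            pairs.append(
                ScaffoldRGroupPair(
                    scaffold=scaf_rec.atoms,
                    scaffold_attachment=s_att,
                    rgroup=rg_rec.atoms,
                    rgroup_attachment=r_att,
                    template_id=tpl.id,
                    source=mol.properties.get("template", ""),
                    scaffold_indices=scaf_idx,
                    rgroup_indices=rg_idx,
                    scaffold_record=scaf_rec,
                    rgroup_record=rg_rec,
                )
            )
    return pairs


def build_dataset(complexes, templates, ratios=(0.8, 0.1, 0.1),
                  seed: int = 0):
    """Assemble (pocket, seed, scaffold, rgroup) tuples with a split
    manifest.

    Per molecule: slice into scaffold/R-group pairs, BRICS-cut each
    scaffold, keep only Rule-of-Three-passing seeds (the scaffold's
    attachment atom is added to the anchors of the seed containing it),
    then split deterministically by seeded shuffle.
    """
    if not complexes:
        raise EmptyInputError("no complexes")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ParameterError("split ratios must sum to 1")
    tuples, rows = [], []
    for ci, (pocket, mol) in enumerate(complexes):
        complex_id = mol.properties.get("template", f"complex{ci}")
        for pair in slice_scaffold_rgroups(mol, templates):
            scaf_rec = pair.scaffold_record
            if scaf_rec is None or not scaf_rec.valid:
                continue
            for seed_frag in brics_decompose(scaf_rec):
                anchors = set(seed_frag.anchors)
                # attachment atom (local within the seed) is a growth site
                att = pair.scaffold_attachment
                seed_globals = None
                if seed_frag.record is not None:
                    pass
                # locate the scaffold attachment inside this seed
                scaf_local = [
                    k
                    for k, xyz in enumerate(seed_frag.atoms.coords)
                    if np.allclose(xyz, pair.scaffold.coords[att])
                ]
                if scaf_local:
                    anchors.add(scaf_local[0])
                seed_frag = FragmentSeed(
                    seed_frag.atoms,
                    anchors=sorted(anchors),
                    record=seed_frag.record,
                )
                if not ro3_filter(seed_frag):
                    continue
                tuples.append(
                    (pocket, seed_frag, pair.scaffold, pair.rgroup)
                )
                rows.append(
                    {
                        "complex_id": complex_id,
                        "template_id": pair.template_id,
                        "seed_atoms": seed_frag.atoms.n,
                        "scaffold_atoms": pair.scaffold.n,
                        "rgroup_atoms": pair.rgroup.n,
                    }
                )
    if not tuples:
        raise EmptyInputError("all molecules filtered out")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tuples))
    n = len(tuples)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    split = [""] * n
    for pos, k in enumerate(order):
        if pos < n_train:
            split[k] = "train"
        elif pos < n_train + n_val:
            split[k] = "validation"
        else:
            split[k] = "test"
    if n and "train" not in split:
        split[int(order[0])] = "train"
    manifest = pd.DataFrame(rows)
    manifest["split"] = split
    return tuples, manifest
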