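"""Molecule-quality battery: drug-likeness panel, atomic composition,
similarity/diversity, geometric distributions and their KL divergence.

The panel covers the standard structure-based drug design metrics: QED
(desirability-product drug-likeness), synthetic accessibility normalized to
[0, 1] with higher = easier, Crippen logP, a Lipinski rule-compliance count
on a 0–5 scale, and the atomic-composition R value — the fraction of heavy
atoms that are not carbon, whose drug-like range is roughly 0.05–0.50.

Geometric scrutiny works on element-pattern keys ("C-O" bond lengths,
"C-O-C" angles, "C-C-C-C" dihedrals; lengths in Å, angles and dihedrals in
radians), histogrammed on shared bin edges so distributions from different
molecule sets are directly comparable through KL divergence.
"""

from __future__ import annotations

import os
import sys
import warnings
from dataclasses import dataclass

import numpy as np

from .chem_data import MoleculeRecord, to_rdkit
from .errors import ParameterError, ValidityError

__all__ = [
    "MetricsPanel",
    "GeometryHistogram",
    "property_panel",
    "r_value",
    "diversity",
    "similarity_to_ref",
    "geometry_distributions",
    "kl_divergence",
    "threshold_joint_count",
]

_SASCORER = None


def _sascorer():
    """RDKit's contributed synthetic-accessibility scorer."""
    global _SASCORER
    if _SASCORER is None:
        from rdkit.Chem import RDConfig

        path = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if path not in sys.path:
            sys.path.append(path)
        import sascorer

        _SASCORER = sascorer
    return _SASCORER


@dataclass
class MetricsPanel:
    """Per-molecule property panel."""

    qed: float
    sa_norm: float
    logp: float
    lipinski: int
    mw: float
    tpsa: float
    r_value: float
    n_heavy: int
    n_total: int
    n_rings: int

    def __post_init__(self):
        if not (0.0 <= self.qed <= 1.0 and 0.0 <= self.sa_norm <= 1.0):
            raise ParameterError("qed/sa_norm out of [0,1]")
        if not 0 <= self.lipinski <= 5:
            raise ParameterError("lipinski count out of 0..5")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _rd_valid(mol: MoleculeRecord):
    if not mol.valid:
        raise ValidityError("metrics require a valid molecule")
    return to_rdkit(mol, sanitize=True)


def r_value(mol: MoleculeRecord) -> float:
    """Fraction of heavy atoms that are not carbon."""
    heavy = [s for s in mol.symbols if s != "H"]
    if not heavy:
        raise ParameterError("no heavy atoms")
    return sum(1 for s in heavy if s != "C") / len(heavy)


def _lipinski_count(rd) -> int:
    """Rule-of-Five compliance on a 0–5 scale: MW < 500, logP in [-2, 5],
    HBD <= 5, HBA <= 10, rotatable bonds <= 10."""
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    rules = [
        Descriptors.MolWt(rd) < 500,
        -2.0 <= Crippen.MolLogP(rd) <= 5.0,
        Lipinski.NumHDonors(rd) <= 5,
        Lipinski.NumHAcceptors(rd) <= 10,
        rdMolDescriptors.CalcNumRotatableBonds(rd) <= 10,
    ]
    return int(sum(rules))


def property_panel(mol: MoleculeRecord) -> MetricsPanel:
    """Standard drug-likeness panel for one valid molecule.

    SA is the fragment-contribution synthetic-accessibility score (raw
    range 1–10, lower = easier) mapped to [0, 1] via (10 - raw) / 9 so
    that higher means easier to synthesize.
    """
    from rdkit.Chem import Crippen, Descriptors, QED, rdMolDescriptors

    rd = _rd_valid(mol)
    raw_sa = float(_sascorer().calculateScore(rd))
    sa_norm = min(1.0, max(0.0, (10.0 - raw_sa) / 9.0))
    n_heavy = mol.n_heavy
    n_total = rd.GetNumAtoms() + sum(
        a.GetTotalNumHs() for a in rd.GetAtoms()
    )
    return MetricsPanel(
        qed=float(QED.qed(rd)),
        sa_norm=sa_norm,
        logp=float(Crippen.MolLogP(rd)),
        lipinski=_lipinski_count(rd),
        mw=float(Descriptors.MolWt(rd)),
        tpsa=float(rdMolDescriptors.CalcTPSA(rd)),
        r_value=r_value(mol),
        n_heavy=n_heavy,
        n_total=int(n_total),
        n_rings=int(rdMolDescriptors.CalcNumRings(rd)),
    )


# ---------------------------------------------------------------------------
# fingerprint similarity
# ---------------------------------------------------------------------------


def _fingerprints(mols):
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return [gen.GetFingerprint(_rd_valid(m)) for m in mols]


def diversity(mols) -> float:
    """1 minus the average pairwise Tanimoto similarity."""
    from rdkit import DataStructs

    if len(mols) < 2:
        warnings.warn("diversity of fewer than 2 molecules is defined as 0")
        return 0.0
    fps = _fingerprints(mols)
    sims = [
        DataStructs.TanimotoSimilarity(fps[i], fps[j])
        for i in range(len(fps))
        for j in range(i + 1, len(fps))
    ]
    return 1.0 - float(np.mean(sims))


def similarity_to_ref(mols, ref_set) -> float:
    """Mean over molecules of the maximum Tanimoto against a reference
    set (novelty proxy: lower = more novel)."""
    from rdkit import DataStructs

    if not mols or not ref_set:
        raise ParameterError("both molecule sets must be nonempty")
    fps = _fingerprints(mols)
    ref_fps = _fingerprints(ref_set)
    best = [
        max(DataStructs.TanimotoSimilarity(fp, rf) for rf in ref_fps)
        for fp in fps
    ]
    return float(np.mean(best))


# ---------------------------------------------------------------------------
# geometric distributions
# ---------------------------------------------------------------------------


@dataclass
class GeometryHistogram:
    """Normalized histogram of one geometric feature pattern."""

    key: str
    bin_edges: np.ndarray
    densities: np.ndarray
    n_samples: int = 0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if len(self.densities) != len(self.bin_edges) - 1:
            raise ParameterError("bin/density length mismatch")
        if self.n_samples and not np.isclose(self.densities.sum(), 1.0):
            raise ParameterError("densities must sum to 1")


#: default measurement ranges: lengths in Å, angles/dihedrals in radians
_DEFAULT_RANGES = {2: (0.5, 3.0), 3: (0.0, np.pi), 4: (-np.pi, np.pi)}


def _parse_key(key: str) -> list:
    parts = key.split("-")
    if len(parts) not in (2, 3, 4) or not all(parts):
        raise ParameterError(f"bad geometry key {key!r}")
    return parts


def _paths(mol: MoleculeRecord, length: int):
    """Simple bonded paths of ``length`` atoms, each counted once."""
    adj = [[] for _ in range(mol.atoms.n)]
    for i, j, _ in mol.bonds:
        adj[i].append(j)
        adj[j].append(i)
    out = []

    def extend(path):
        if len(path) == length:
            if path[0] < path[-1] or (
                path[0] == path[-1] and path < path[::-1]
            ):
                out.append(tuple(path))
            return
        for nxt in adj[path[-1]]:
            if nxt not in path:
                extend(path + [nxt])

    for start in range(mol.atoms.n):
        extend([start])
    return out


def _measure(coords, path) -> float:
    pts = [coords[i] for i in path]
    if len(path) == 2:
        return float(np.linalg.norm(pts[1] - pts[0]))
    if len(path) == 3:
        u = pts[0] - pts[1]
        v = pts[2] - pts[1]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.arccos(np.clip(cosang, -1.0, 1.0)))
    b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def geometry_distributions(mols, keys, n_bins: int = 64,
                           ranges: dict | None = None) -> list:
    """Histogram bond lengths / angles / dihedrals matching element
    patterns.

    A pattern and its reversal are the same key; each undirected path is
    measured once.  All histograms for a given arity share bin edges.
    """
    if not mols:
        raise ParameterError("no molecules")
    ranges = {**_DEFAULT_RANGES, **(ranges or {})}
    out = []
    for key in keys:
        pattern = _parse_key(key)
        arity = len(pattern)
        lo, hi = ranges[arity]
        edges = np.linspace(lo, hi, n_bins + 1)
        values = []
        for mol in mols:
            symbols = mol.symbols
            for path in _paths(mol, arity):
                syms = [symbols[i] for i in path]
                if syms == pattern or syms == pattern[::-1]:
                    values.append(_measure(mol.atoms.coords, path))
        if not values:
            warnings.warn(f"no matches for geometry key {key!r}")
            out.append(
                GeometryHistogram(key, edges, np.zeros(n_bins), 0)
            )
            continue
        counts, _ = np.histogram(values, bins=edges)
        total = counts.sum()
        dens = counts / total if total else counts.astype(float)
        out.append(GeometryHistogram(key, edges, dens, len(values)))
    return out


def kl_divergence(p: GeometryHistogram, q: GeometryHistogram,
                  eps: float = 1e-10) -> float:
    """KL(P || Q) over shared bins; Q is floored by ``eps`` before the
    log and zero-mass P bins contribute nothing."""
    if p.bin_edges.shape != q.bin_edges.shape or not np.allclose(
        p.bin_edges, q.bin_edges
    ):
        raise ParameterError("histograms must share bin edges")
    pd = p.densities
    qd = np.maximum(q.densities, eps)
    mask = pd > 0
    return float(np.sum(pd[mask] * np.log(pd[mask] / qd[mask])))


def threshold_joint_count(panels, sa_min: float, qed_min: float) -> int:
    """Number of panels with sa_norm >= sa_min and qed >= qed_min."""
    if not panels:
        raise ParameterError("no panels")
    return sum(
        1 for p in panels if p.sa_norm >= sa_min and p.qed >= qed_min
    )
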