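"""Normalised principal-moments-of-inertia (PMI/NPR) shape descriptors.

A molecule's three principal moments of inertia PM1 <= PM2 <= PM3, taken in
the centre-of-mass frame, locate it on the rod-disk-sphere triangle via the
normalised ratios NPR1 = PM1/PM3 and NPR2 = PM2/PM3: a rod sits at (0, 1),
a flat symmetric disk at (0.5, 0.5), a sphere at (1, 1), and every rigid
body satisfies NPR1 + NPR2 >= 1. The inertia math is implemented here so
the geometric core needs no cheminformatics toolkit; conformer generation
(10 embeddings, MMFF94 optimisation, lowest-energy pick) delegates to RDKit
and is imported lazily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ShapeDescriptor", "inertia_descriptors", "conformer_descriptors"]


@dataclass(frozen=True)
class ShapeDescriptor:
    pm1: float
    pm2: float
    pm3: float
    npr1: float
    npr2: float


class DegenerateGeometryError(ValueError):
    """All points coincide; the inertia tensor is identically zero."""


def inertia_descriptors(
    coordinates: np.ndarray, masses: np.ndarray | None = None
) -> ShapeDescriptor:
    """Principal moments and NPR ratios of a rigid point-mass body.

    ``coordinates`` is n x 3 (Angstrom); ``masses`` defaults to unit masses.
    Invariant under rotation, translation and uniform scaling of the masses
    (the ratios, not the raw moments).
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise ValueError("coordinates must be an n x 3 array with n >= 2")
    m = (
        np.ones(coords.shape[0])
        if masses is None
        else np.asarray(masses, dtype=float)
    )
    if m.shape[0] != coords.shape[0] or np.any(m <= 0):
        raise ValueError("masses must be positive, one per coordinate row")

    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    r = coords - com
    if np.allclose(r, 0):
        raise DegenerateGeometryError("all points coincide")

    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    ixx = float(np.sum(m * (y**2 + z**2)))
    iyy = float(np.sum(m * (x**2 + z**2)))
    izz = float(np.sum(m * (x**2 + y**2)))
    ixy = -float(np.sum(m * x * y))
    ixz = -float(np.sum(m * x * z))
    iyz = -float(np.sum(m * y * z))
    tensor = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
    pm1, pm2, pm3 = np.linalg.eigvalsh(tensor)
    pm1 = max(pm1, 0.0)  # clip eigenvalue round-off at the rod limit
    return ShapeDescriptor(
        pm1=float(pm1),
        pm2=float(pm2),
        pm3=float(pm3),
        npr1=float(pm1 / pm3),
        npr2=float(pm2 / pm3),
    )


def conformer_descriptors(
    structure: str, n_conformers: int = 10, seed: int = 42
) -> ShapeDescriptor:
    """NPR descriptors of the lowest-energy conformer of a SMILES structure.

    Hydrogens are added, ``n_conformers`` 3D embeddings are generated with a
    fixed random seed, each is optimised with the MMFF94 force field, and
    the lowest-energy conformer's inertia descriptors are returned.
    Deterministic for a given seed.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    mol = Chem.AddHs(mol)
    conf_ids = AllChem.EmbedMultipleConfs(
        mol, numConfs=n_conformers, randomSeed=seed
    )
    if len(conf_ids) == 0:
        raise ValueError(f"3D embedding failed for {structure!r}")
    results = AllChem.MMFFOptimizeMoleculeConfs(mol)
    energies = [
        (energy if converged == 0 else np.inf, cid)
        for cid, (converged, energy) in zip(conf_ids, results)
    ]
    # fall back to unconverged energies if nothing converged fully
    if all(np.isinf(e) for e, _ in energies):
        energies = [(energy, cid) for cid, (_, energy) in zip(conf_ids, results)]
    _, best = min(energies)
    conf = mol.GetConformer(int(best))
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
    )
    masses = np.array([atom.GetMass() for atom in mol.GetAtoms()])
    return inertia_descriptors(coords, masses)
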