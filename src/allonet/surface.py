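"""Solvent-accessible surface area, interfaces, and ligand contacts.

SASA uses the Shrake–Rupley rolling-probe point sampling: each atom's
sphere is inflated by the probe radius (default 1.4 Å), covered with a
near-uniform point set (default 960 points, golden-spiral construction),
and the accessible fraction — points not buried inside any neighbour's
inflated sphere — scaled by 4π(r+probe)².

Interface residues between two structural parts are those losing more
than 1.0 Å² of SASA when the parts are joined:
ΔSASA_r = SASA_r(isolated part) − SASA_r(complex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import DomainMap, Ensemble, StructureModel, REGIONS

__all__ = [
    "SasaResult",
    "InterfaceSet",
    "sasa",
    "interface_residues",
    "interdomain_interfaces",
    "pocket_surface_area",
    "ligand_contact_occupancy",
]

DEFAULT_PROBE = 1.4        # Å, water probe
DEFAULT_N_POINTS = 960
DEFAULT_DELTA_SASA = 1.0   # Å², interface call threshold


@dataclass
class SasaResult:
    per_atom: np.ndarray           # Å²
    per_residue: dict[int, float]  # residue id -> Å²
    total: float
    probe: float
    n_points: int


@dataclass
class InterfaceSet:
    """Interface residues of one system with their ΔSASA (Å²)."""
    residues: set[int]
    delta_sasa: dict[int, float]
    threshold: float


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform unit-sphere points via the golden spiral."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def sasa(structure: StructureModel, probe: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_N_POINTS,
         radii: np.ndarray | None = None) -> SasaResult:
    """Shrake–Rupley SASA per atom, per residue, and total.

    Radii default to the element table on the structure (C 1.70, N 1.55,
    O 1.52, S 1.80, P 1.80 Å); a missing element is an error.
    """
    if radii is None:
        radii = structure.radii()
    radii = np.asarray(radii, dtype=float)
    coords = structure.coords
    n_atoms = len(coords)
    inflated = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * inflated.max()
    per_atom = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + inflated[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], inflated[i] + inflated.max())
                     if j != i]
        if neighbors:
            nb = np.array(neighbors)
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = (d2 < (inflated[nb][None, :] ** 2)).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * inflated[i] ** 2 * frac
    per_residue: dict[int, float] = {}
    for rid, a in zip(structure.res_id, per_atom):
        per_residue[int(rid)] = per_residue.get(int(rid), 0.0) + float(a)
    return SasaResult(per_atom, per_residue, float(per_atom.sum()),
                      probe, n_points)


def interface_residues(structure: StructureModel,
                       partition: tuple[np.ndarray, np.ndarray],
                       threshold: float = DEFAULT_DELTA_SASA,
                       probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS) -> InterfaceSet:
    """Residues buried on association of two structural parts.

    ``partition`` gives the residue ids of the two parts; only atoms of
    those residues enter the calculation.  Per residue,
    ΔSASA = SASA(in its isolated part) − SASA(in the two-part complex),
    and residues with ΔSASA > threshold are returned.  Symmetric in the
    partition order.
    """
    part_a = np.asarray(partition[0], dtype=int)
    part_b = np.asarray(partition[1], dtype=int)
    if len(part_a) == 0 or len(part_b) == 0:
        raise ValueError("both partition sides must be non-empty")
    if np.intersect1d(part_a, part_b).size:
        raise ValueError("partition sides overlap")
    mask_a = np.isin(structure.res_id, part_a)
    mask_b = np.isin(structure.res_id, part_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("a partition side matches no atoms")
    complex_ = structure.select(mask_a | mask_b)
    sasa_complex = sasa(complex_, probe, n_points).per_residue
    delta: dict[int, float] = {}
    for mask in (mask_a, mask_b):
        iso = sasa(structure.select(mask), probe, n_points).per_residue
        for rid, area in iso.items():
            delta[rid] = area - sasa_complex[rid]
    residues = {r for r, d in delta.items() if d > threshold}
    return InterfaceSet(residues, delta, threshold)


def interdomain_interfaces(structure: StructureModel, domain_map: DomainMap,
                           threshold: float = DEFAULT_DELTA_SASA,
                           probe: float = DEFAULT_PROBE,
                           n_points: int = DEFAULT_N_POINTS) -> InterfaceSet:
    """Union of interface residues over all structural-region pairs.

    ΔSASA recorded per residue is the maximum over the pairs in which it
    was tested.
    """
    present = [r for r in REGIONS if len(domain_map.residues_in(r))]
    residues: set[int] = set()
    delta: dict[int, float] = {}
    for ai in range(len(present)):
        for bi in range(ai + 1, len(present)):
            ra = domain_map.residues_in(present[ai])
            rb = domain_map.residues_in(present[bi])
            if not (np.isin(structure.res_id, ra).any()
                    and np.isin(structure.res_id, rb).any()):
                continue
            iface = interface_residues(structure, (ra, rb), threshold,
                                       probe, n_points)
            residues |= iface.residues
            for rid, d in iface.delta_sasa.items():
                delta[rid] = max(delta.get(rid, -np.inf), d)
    return InterfaceSet(residues, delta, threshold)


def pocket_surface_area(structure: StructureModel, ligand: np.ndarray,
                        radius: float = 5.0, include_ligand: bool = False,
                        ligand_radii: np.ndarray | None = None,
                        probe: float = DEFAULT_PROBE,
                        n_points: int = DEFAULT_N_POINTS) -> float:
    """SASA of the ligand-surrounding pocket region (Å²).

    Pocket residues are all residues with any atom within ``radius`` of any
    ligand atom.  By default the ligand itself is excluded from occlusion,
    so the value is the area of the unliganded pocket surface; with
    ``include_ligand`` the ligand atoms (carbon radii unless given) occlude
    the pocket.
    """
    ligand = np.atleast_2d(np.asarray(ligand, dtype=float))
    if ligand.size == 0:
        raise ValueError("ligand coordinates are empty")
    if radius <= 0:
        warnings.warn("non-positive pocket radius: no pocket residues")
        return 0.0
    tree = cKDTree(ligand)
    dmin = tree.query(structure.coords)[0]
    pocket_res = set(structure.res_id[dmin <= radius].tolist())
    if not pocket_res:
        warnings.warn("no residue within the pocket radius of the ligand")
        return 0.0
    if include_ligand:
        nlig = len(ligand)
        lig_radii = (np.full(nlig, 1.70) if ligand_radii is None
                     else np.asarray(ligand_radii, dtype=float))
        aug = StructureModel(
            coords=np.vstack([structure.coords, ligand]),
            atom_name=np.concatenate([structure.atom_name, ["LIG"] * nlig]),
            element=np.concatenate([structure.element, ["C"] * nlig]),
            res_id=np.concatenate([structure.res_id,
                                   [structure.res_id.max() + 1] * nlig]),
            res_name=np.concatenate([structure.res_name, ["LIG"] * nlig]),
            chain_id=np.concatenate([structure.chain_id, ["L"] * nlig]),
        )
        radii = np.concatenate([structure.radii(), lig_radii])
        res = sasa(aug, probe, n_points, radii=radii)
    else:
        res = sasa(structure, probe, n_points)
    return float(sum(res.per_residue[r] for r in pocket_res))


def ligand_contact_occupancy(ensemble: Ensemble, ligand_coords: np.ndarray,
                             radius: float = 5.0) -> dict[int, float]:
    """Fraction of frames each residue lies within ``radius`` of the ligand.

    ``ligand_coords`` has shape (F, n_ligand_atoms, 3) and must cover every
    frame of the ensemble.
    """
    ligand_coords = np.asarray(ligand_coords, dtype=float)
    if ligand_coords.ndim != 3 or ligand_coords.shape[0] != ensemble.n_frames:
        raise ValueError("ligand coordinates must be (F, n_atoms, 3) for every frame")
    if not np.all(np.isfinite(ligand_coords)):
        raise ValueError("missing (non-finite) ligand coordinates in a frame")
    counts = np.zeros(ensemble.n_residues)
    for f in range(ensemble.n_frames):
        tree = cKDTree(ligand_coords[f])
        dmin = tree.query(ensemble.coords[f])[0]
        counts += dmin <= radius
    freq = counts / ensemble.n_frames
    return {int(r): float(v) for r, v in zip(ensemble.res_ids, freq)}
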