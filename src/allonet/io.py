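"""Structures, ensembles, domain maps, and system manifests.

The package works on conformational ensembles of a multidomain protein
(a Src-family kinase with SH3, SH2, an interdomain linker, and a catalytic
SH1 domain split into N- and C-lobes).  Residue numbering follows the
author/construct convention (the first residue need not be 1); all matrix
and array indices are 0-based positions into the ordered selection, with an
explicit bidirectional mapping kept on each container.

Canonical on-disk formats:

* multi-model PDB for structures and ensembles (via biotite),
* a plain CSV frame table ``frame,residue_id,x,y,z`` as the synthetic
  generator's native output,
* JSON for domain maps and system manifests,
* CSV/TSV for every tabular result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "StructureModel",
    "Ensemble",
    "DomainMap",
    "SystemEntry",
    "SystemManifest",
    "MalformedEnsembleError",
    "read_ensemble",
    "write_ensemble",
    "read_structure",
    "write_structure",
    "load_domain_map",
    "save_domain_map",
    "load_manifest",
    "save_manifest",
]

#: The five structural regions of the full-length kinase.
REGIONS = ("SH3", "SH2", "L", "SH1N", "SH1C")

# Element-based van der Waals radii (Å) used for SASA when no explicit
# radii are supplied.  Values are the conventional single-atom radii.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}


class MalformedEnsembleError(ValueError):
    """Raised when an ensemble file is internally inconsistent."""


@dataclass
class StructureModel:
    """A single structure: parallel per-atom arrays plus a source label.

    Coordinates are in Å.  ``res_id`` keeps the author numbering of the
    construct (e.g. residues 60–502).
    """

    coords: np.ndarray          # (n_atoms, 3) float
    atom_name: np.ndarray       # (n_atoms,) str
    element: np.ndarray         # (n_atoms,) str
    res_id: np.ndarray          # (n_atoms,) int
    res_name: np.ndarray        # (n_atoms,) str
    chain_id: np.ndarray        # (n_atoms,) str
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        for name in ("atom_name", "element", "res_id", "res_name", "chain_id"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_atoms {n}")
            setattr(self, name, arr)
        self.res_id = self.res_id.astype(int)
        # residue ids must be non-decreasing within a chain
        for ch in np.unique(self.chain_id):
            rid = self.res_id[self.chain_id == ch]
            if np.any(np.diff(rid) < 0):
                raise ValueError(f"residue ids not ordered within chain {ch!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.coords[mask], self.atom_name[mask], self.element[mask],
            self.res_id[mask], self.res_name[mask], self.chain_id[mask],
            source=self.source,
        )

    def ca_only(self) -> "StructureModel":
        return self.select(self.atom_name == "CA")

    def radii(self, table: Mapping[str, float] | None = None) -> np.ndarray:
        """Per-atom vdW radii from the element table; error on unknowns."""
        table = dict(VDW_RADII if table is None else table)
        out = np.empty(self.n_atoms)
        for i, el in enumerate(self.element):
            key = str(el).strip().upper()
            if key not in table:
                raise KeyError(f"no radius assigned for element {el!r}")
            out[i] = table[key]
        if np.any(out <= 0):
            raise ValueError("all assigned radii must be positive")
        return out


@dataclass
class Ensemble:
    """Ordered frames of coordinates over a fixed residue selection.

    ``coords`` has shape (F, N, 3) in Å; ``res_ids`` is the ordered residue
    selection shared by every frame.  ``frame_interval`` is metadata only
    (e.g. ns between saved frames).
    """

    coords: np.ndarray
    res_ids: np.ndarray
    system: str = ""
    replicate: int = 0
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if self.coords.shape[1] != len(self.res_ids):
            raise MalformedEnsembleError(
                f"selection length {len(self.res_ids)} does not match "
                f"coordinate width {self.coords.shape[1]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise MalformedEnsembleError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def position_of(self, res_id: int) -> int:
        """0-based position of an author-numbered residue in the selection."""
        hits = np.flatnonzero(self.res_ids == res_id)
        if len(hits) == 0:
            raise KeyError(f"residue {res_id} not in selection")
        return int(hits[0])


@dataclass
class DomainMap:
    """Residue → structural-region assignment over the five-region vocabulary.

    The assignment must be a partition: every residue of the selection is
    covered exactly once.
    """

    region_of: dict[int, str]

    def __post_init__(self) -> None:
        bad = sorted({r for r in self.region_of.values() if r not in REGIONS})
        if bad:
            raise ValueError(f"unknown region label(s) {bad}; allowed: {REGIONS}")

    @property
    def res_ids(self) -> np.ndarray:
        return np.array(sorted(self.region_of), dtype=int)

    def __len__(self) -> int:
        return len(self.region_of)

    def labels_for(self, res_ids: Sequence[int]) -> np.ndarray:
        """Region labels in selection order; error on uncovered residues."""
        try:
            return np.array([self.region_of[int(r)] for r in res_ids])
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]} has no region assignment") from None

    def residues_in(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return np.array(sorted(r for r, lab in self.region_of.items() if lab == region), dtype=int)

    @classmethod
    def from_ranges(cls, ranges: Mapping[str, Iterable[Sequence[int]]]) -> "DomainMap":
        """Build from inclusive residue ranges, validating the partition.

        ``ranges`` maps region label → list of (first, last) inclusive pairs.
        Overlapping ranges are a validation error.
        """
        region_of: dict[int, str] = {}
        for label, spans in ranges.items():
            if label not in REGIONS:
                raise ValueError(f"unknown region label {label!r}")
            for span in spans:
                first, last = int(span[0]), int(span[1])
                if last < first:
                    raise ValueError(f"empty range {first}–{last} in {label}")
                for r in range(first, last + 1):
                    if r in region_of:
                        raise ValueError(
                            f"residue {r} assigned to both {region_of[r]} and {label}"
                        )
                    region_of[r] = label
        if not region_of:
            raise ValueError("domain map is empty")
        return cls(region_of)


@dataclass
class SystemEntry:
    condition: str                      # e.g. apo / ATP / DAS
    label: int                          # 1 = active-like, 0 = inactive-like
    ensembles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"activity label must be 0 or 1, got {self.label!r}")


@dataclass
class SystemManifest:
    """Named systems with condition, binary activity label, and ensemble paths."""

    entries: dict[str, SystemEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("manifest has no systems")

    @property
    def systems(self) -> list[str]:
        return list(self.entries)

    @property
    def y(self) -> np.ndarray:
        """Activity labels in manifest order (1 = active-like)."""
        return np.array([e.label for e in self.entries.values()], dtype=int)

    def require_both_classes(self) -> None:
        y = self.y
        if y.min() == y.max():
            raise ValueError(
                "manifest must contain at least one active-like and one "
                "inactive-like system for state-contrast analyses"
            )


# ---------------------------------------------------------------------------
# ensembles


def _read_pdb_ensemble(path: Path, selection_spec: str) -> Ensemble:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(pdb_file)  # AtomArrayStack, models must agree
    except Exception as exc:  # biotite raises on inconsistent models
        raise MalformedEnsembleError(
            f"{path}: inconsistent atom records across models ({exc})"
        ) from exc
    if stack.stack_depth() == 0:
        raise MalformedEnsembleError(f"{path}: no models")
    mask = stack.atom_name == selection_spec
    if not mask.any():
        raise ValueError(f"{path}: selection {selection_spec!r} matches no atoms")
    sub = stack[..., mask]
    return Ensemble(
        coords=np.asarray(sub.coord, dtype=float),
        res_ids=np.asarray(sub.res_id, dtype=int),
        system=path.stem,
    )


def _read_table_ensemble(path: Path) -> Ensemble:
    df = pd.read_csv(path)
    required = {"frame", "residue_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise MalformedEnsembleError(
            f"{path}: frame table needs columns {sorted(required)}"
        )
    frames = np.sort(df["frame"].unique())
    first = df[df["frame"] == frames[0]].sort_values("residue_id")
    res_ids = first["residue_id"].to_numpy(dtype=int)
    coords = np.empty((len(frames), len(res_ids), 3))
    for k, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("residue_id")
        if not np.array_equal(sub["residue_id"].to_numpy(dtype=int), res_ids):
            raise MalformedEnsembleError(
                f"{path}: frame {f} has a different residue selection"
            )
        coords[k] = sub[["x", "y", "z"]].to_numpy(dtype=float)
    return Ensemble(coords=coords, res_ids=res_ids, system=path.stem)


def read_ensemble(path: str | Path, selection_spec: str = "CA") -> Ensemble:
    """Read a conformational ensemble from multi-model PDB or a CSV frame table.

    The selection (default Cα) is applied to PDB input; frame tables are
    already residue-level.  Frames keep file order.
    """
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv"):
        return _read_table_ensemble(path)
    return _read_pdb_ensemble(path, selection_spec)


def write_ensemble(ensemble: Ensemble, path: str | Path) -> Path:
    """Write an ensemble as multi-model PDB (``.pdb``) or CSV frame table."""
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv"):
        recs = []
        for f in range(ensemble.n_frames):
            for i, rid in enumerate(ensemble.res_ids):
                x, y, z = ensemble.coords[f, i]
                recs.append((f, int(rid), x, y, z))
        pd.DataFrame(recs, columns=["frame", "residue_id", "x", "y", "z"]).to_csv(
            path, index=False, float_format="%.6f"
        )
        return path

    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ensemble.n_residues
    arr = struc.AtomArray(n)
    arr.coord = ensemble.coords[0]
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.res_id = ensemble.res_ids
    arr.res_name = np.full(n, "ALA")
    arr.chain_id = np.full(n, "A")
    stack = struc.stack([arr] * ensemble.n_frames)
    stack.coord = ensemble.coords.copy()
    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, stack)
    pdb_file.write(str(path))
    return path


# ---------------------------------------------------------------------------
# structures


def read_structure(path: str | Path, model: int = 1) -> StructureModel:
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    pdb_file = pdb.PDBFile.read(str(path))
    arr = pdb.get_structure(pdb_file, model=model)
    element = np.array([e if e else _guess_element(a) for e, a in
                        zip(arr.element, arr.atom_name)])
    return StructureModel(
        coords=np.asarray(arr.coord, dtype=float),
        atom_name=np.asarray(arr.atom_name),
        element=element,
        res_id=np.asarray(arr.res_id, dtype=int),
        res_name=np.asarray(arr.res_name),
        chain_id=np.asarray(arr.chain_id),
        source=str(path),
    )


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def write_structure(structure: StructureModel, path: str | Path) -> Path:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = structure.coords
    arr.atom_name = structure.atom_name.astype("U6")
    arr.element = structure.element.astype("U2")
    arr.res_id = structure.res_id
    arr.res_name = structure.res_name.astype("U5")
    arr.chain_id = structure.chain_id.astype("U4")
    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, arr)
    path = Path(path)
    pdb_file.write(str(path))
    return path


# ---------------------------------------------------------------------------
# configs


def load_domain_map(path: str | Path) -> DomainMap:
    """Load a domain map from JSON ``{"regions": {label: [[first, last], ...]}}``."""
    with open(path) as fh:
        cfg = json.load(fh)
    if "regions" not in cfg:
        raise ValueError(f"{path}: domain map JSON must have a 'regions' key")
    return DomainMap.from_ranges(cfg["regions"])


def save_domain_map(domain_map: DomainMap, path: str | Path) -> Path:
    # compress back to inclusive ranges per region
    ranges: dict[str, list[list[int]]] = {}
    for region in REGIONS:
        rids = domain_map.residues_in(region)
        if len(rids) == 0:
            continue
        spans: list[list[int]] = []
        start = prev = int(rids[0])
        for r in rids[1:]:
            r = int(r)
            if r == prev + 1:
                prev = r
            else:
                spans.append([start, prev])
                start = prev = r
        spans.append([start, prev])
        ranges[region] = spans
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"regions": ranges}, fh, indent=1)
    return path


def load_manifest(path: str | Path) -> SystemManifest:
    """Load a system manifest from JSON ``{"systems": {name: {...}}}``."""
    with open(path) as fh:
        cfg = json.load(fh)
    if "systems" not in cfg:
        raise ValueError(f"{path}: manifest JSON must have a 'systems' key")
    base = Path(path).parent
    entries = {}
    for name, ent in cfg["systems"].items():
        paths = [str(base / p) if not Path(p).is_absolute() else p
                 for p in ent.get("ensembles", [])]
        entries[name] = SystemEntry(
            condition=ent.get("condition", "apo"),
            label=int(ent["label"]),
            ensembles=paths,
        )
    return SystemManifest(entries)


def save_manifest(manifest: SystemManifest, path: str | Path) -> Path:
    path = Path(path)
    base = path.parent
    out = {"systems": {}}
    for name, ent in manifest.entries.items():
        rel = []
        for p in ent.ensembles:
            p = Path(p)
            try:
                rel.append(str(p.relative_to(base)))
            except ValueError:
                rel.append(str(p))
        out["systems"][name] = {
            "condition": ent.condition, "label": ent.label, "ensembles": rel,
        }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
    return path
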