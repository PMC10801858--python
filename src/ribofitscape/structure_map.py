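"""Atomic models, residue-residue distances, B-factor fitness export.

Reads PDB/mmCIF models through gemmi, maps chains onto subunit coordinate
systems, computes residue distance matrices (minimum heavy-atom or C1'
metrics) and writes per-position mean fitness into the B-factor column for
structure viewers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

PosKey = tuple[str, int]

B_MIN, B_MAX = -99.99, 999.99  # PDB fixed-width B-factor field limits


@dataclass
class ChainMap:
    """Maps a chain to a subunit coordinate system.

    subunit position = residue seqid + offset.
    """

    subunit_id: str
    offset: int = 0


@dataclass
class ResidueRecord:
    subunit_id: str
    position: int
    chain_id: str
    seqid: int
    name: str
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3), heavy atoms, altloc-resolved

    def atom_coord(self, name: str) -> Optional[np.ndarray]:
        try:
            return self.coords[self.atom_names.index(name)]
        except ValueError:
            return None


@dataclass
class StructureModel:
    """A parsed atomic model restricted to model 1, heavy atoms only."""

    residues: list[ResidueRecord]
    mapping: dict[str, ChainMap]
    structure: gemmi.Structure = field(repr=False, default=None)

    def residue(self, subunit_id: str, position: int) -> Optional[ResidueRecord]:
        return self._index().get((subunit_id, position))

    def _index(self) -> dict[PosKey, ResidueRecord]:
        if not hasattr(self, "_idx"):
            self._idx = {(r.subunit_id, r.position): r for r in self.residues}
        return self._idx

    @property
    def keys(self) -> list[PosKey]:
        return [(r.subunit_id, r.position) for r in self.residues]


def read_structure(
    path: Union[str, Path], mapping: dict[str, ChainMap]
) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Model 1 only (a warning is logged for multi-model files); hydrogens
    are ignored; alternate locations resolve to the highest occupancy.
    Chains without a mapping entry are skipped with a warning.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if len(st) > 1:
        logger.warning("%s has %d models; using model 1", path, len(st))
    model = st[0]
    residues: list[ResidueRecord] = []
    for chain in model:
        cmap = mapping.get(chain.name)
        if cmap is None:
            logger.warning("chain %r has no subunit mapping; skipped", chain.name)
            continue
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                continue
            names = list(best)
            coords = np.array([[best[n].pos.x, best[n].pos.y, best[n].pos.z] for n in names])
            residues.append(
                ResidueRecord(
                    subunit_id=cmap.subunit_id,
                    position=res.seqid.num + cmap.offset,
                    chain_id=chain.name,
                    seqid=res.seqid.num,
                    name=res.name,
                    atom_names=names,
                    coords=coords,
                )
            )
    if not residues:
        raise ValueError(f"no mapped residues in {path}")
    return StructureModel(residues=residues, mapping=dict(mapping), structure=st)


@dataclass
class DistanceMatrix:
    """Symmetric residue-residue distance matrix in Å.

    Entries without coordinates under the chosen metric are NaN.
    """

    keys: list[PosKey]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self._pos = {k: i for i, k in enumerate(self.keys)}

    def get(self, key_i: PosKey, key_j: PosKey) -> float:
        i = self._pos.get(tuple(key_i))
        j = self._pos.get(tuple(key_j))
        if i is None or j is None:
            return float("nan")
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: sub_i, pos_i, sub_j, pos_j, distance_A (i < j)."""
        rows = []
        for i in range(len(self.keys)):
            for j in range(i + 1, len(self.keys)):
                rows.append(
                    {
                        "sub_i": self.keys[i][0],
                        "pos_i": self.keys[i][1],
                        "sub_j": self.keys[j][0],
                        "pos_j": self.keys[j][1],
                        "distance_A": self.matrix[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: Union[str, Path]) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# metric: {self.metric}\n")
            frame.to_csv(fh, sep="\t", index=False)


def residue_distance_matrix(
    model: StructureModel, metric: str = "min_heavy_atom"
) -> DistanceMatrix:
    """Residue-residue distances under min_heavy_atom or c1prime.

    min_heavy_atom: minimum Euclidean distance over all heavy-atom pairs
    (the metric of closest approach, appropriate for contacts such as base
    pairs and stacks).  c1prime: distance between C1' atoms; residues
    lacking a C1' get NaN entries.
    """
    n = len(model.residues)
    mat = np.zeros((n, n))
    if metric == "c1prime":
        pts = np.full((n, 3), np.nan)
        for i, res in enumerate(model.residues):
            c1 = res.atom_coord("C1'")
            if c1 is None:
                logger.warning(
                    "residue %s:%d lacks C1'; c1prime entries set missing",
                    res.subunit_id,
                    res.position,
                )
            else:
                pts[i] = c1
        mat = cdist(pts, pts)
        np.fill_diagonal(mat, 0.0)
        missing = np.isnan(pts).any(axis=1)
        mat[missing, :] = np.nan
        mat[:, missing] = np.nan
        for i in np.nonzero(missing)[0]:
            mat[i, i] = np.nan
    elif metric == "min_heavy_atom":
        coords = [res.coords for res in model.residues]
        for i in range(n):
            for j in range(i + 1, n):
                d = cdist(coords[i], coords[j]).min()
                mat[i, j] = mat[j, i] = d
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(keys=model.keys, matrix=mat, metric=metric)


def write_fitness_bfactor(
    model: StructureModel,
    position_fitness: Union[pd.DataFrame, dict[PosKey, float]],
    out_path: Union[str, Path],
    sentinel: float = 0.0,
) -> list[PosKey]:
    """Write per-residue mean fitness into the B-factor column of a PDB.

    ``position_fitness`` is either a mapping (subunit, position) -> value
    or the frame from ``FitnessResults.position_map`` (columns subunit,
    mean_fitness, indexed by position).  Every atom of a residue carries
    the residue value, clamped to the fixed-width PDB field; residues with
    no mapped value get the sentinel and are returned for reporting.
    Coordinates are untouched.
    """
    if isinstance(position_fitness, pd.DataFrame):
        values = {
            (str(row["subunit"]), int(pos)): float(row["mean_fitness"])
            for pos, row in position_fitness.iterrows()
            if np.isfinite(row["mean_fitness"])
        }
    else:
        values = {tuple(k): float(v) for k, v in position_fitness.items()}
    st = model.structure.clone()
    unmapped: list[PosKey] = []
    for chain in st[0]:
        cmap = model.mapping.get(chain.name)
        for res in chain:
            key = None
            if cmap is not None:
                key = (cmap.subunit_id, res.seqid.num + cmap.offset)
            val = values.get(key)
            if val is None:
                if key is not None:
                    unmapped.append(key)
                val = sentinel
            clamped = min(max(val, B_MIN), B_MAX)
            if clamped != val:
                logger.warning("B-factor %s clamped to %s for %s", val, clamped, key)
            for atom in res:
                atom.b_iso = clamped
    st.write_pdb(str(out_path))
    if unmapped:
        logger.info("%d residues had no fitness value; sentinel %.2f used", len(unmapped), sentinel)
    return unmapped
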