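"""Protein structure input and Cβ geometry.

Conformational switch design works on per-residue Cβ reference points taken
from two (or more) structural states of the same protein — e.g. the open and
closed conformations of a hinged two-domain enzyme.  Multi-model PDB files are
treated as frame ensembles standing in for MD snapshots; distances can be
averaged over frames per state label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "StructureError",
    "ResidueSite",
    "ConformationalState",
    "Ensemble",
    "read_structure",
    "load_two_state",
    "cbeta_distance_matrix",
    "mean_distance_matrix",
    "distance_matrix_to_tsv",
    "virtual_cbeta",
]


class StructureError(ValueError):
    """Raised for unusable or inconsistent structural input."""


@dataclass
class ResidueSite:
    """One residue's Cβ reference point.

    ``is_virtual_cbeta`` marks a reconstructed Cβ (glycine, or a residue whose
    CB atom is missing from the coordinate file).
    """

    chain_id: str
    residue_number: int
    residue_name: str
    cbeta: np.ndarray
    is_virtual_cbeta: bool = False

    def __post_init__(self) -> None:
        self.cbeta = np.asarray(self.cbeta, dtype=float)
        if self.cbeta.shape != (3,) or not np.all(np.isfinite(self.cbeta)):
            raise StructureError(
                f"non-finite or malformed Cbeta for {self.key}: {self.cbeta!r}"
            )

    @property
    def key(self) -> tuple[str, int]:
        """(chain, residue number) identity, stable across states."""
        return (self.chain_id, self.residue_number)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_number}"


@dataclass
class ConformationalState:
    """Labeled set of residue sites for one structural state (one frame).

    Besides the Cβ points used for pair geometry, the state optionally carries
    the full heavy-atom set (coordinates, element symbols and a map back to
    the owning site) needed for solvent-accessibility calculations.
    """

    label: str
    sites: list[ResidueSite]
    source: str = ""
    atom_coords: np.ndarray | None = None
    atom_elements: list[str] | None = None
    atom_site_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise StructureError(
                f"state {self.label!r} has {len(self.sites)} usable residues; need >= 2"
            )
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise StructureError(f"duplicate residue identifiers in state {self.label!r}")

    @property
    def site_keys(self) -> list[tuple[str, int]]:
        return [s.key for s in self.sites]

    def cbeta_array(self) -> np.ndarray:
        return np.vstack([s.cbeta for s in self.sites])


@dataclass
class Ensemble:
    """Conformational states grouped by label, with >=1 frame per label."""

    states: dict[str, list[ConformationalState]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.states:
            raise StructureError("ensemble has no states")
        ref = None
        for label, frames in self.states.items():
            if not frames:
                raise StructureError(f"label {label!r} has no frames")
            for st in frames:
                keys = st.site_keys
                if ref is None:
                    ref = keys
                elif keys != ref:
                    raise StructureError(
                        f"state {st.label!r} does not share the residue set/order "
                        "of the other states"
                    )

    @property
    def labels(self) -> list[str]:
        return list(self.states)

    def frames(self, label: str) -> list[ConformationalState]:
        try:
            return self.states[label]
        except KeyError:
            raise KeyError(
                f"no state labeled {label!r}; available: {sorted(self.states)}"
            ) from None

    def frame_count(self, label: str) -> int:
        return len(self.frames(label))

    def representative(self, label: str) -> ConformationalState:
        return self.frames(label)[0]

    @property
    def site_keys(self) -> list[tuple[str, int]]:
        first = next(iter(self.states.values()))[0]
        return first.site_keys

    @classmethod
    def merge(cls, ensembles: Iterable["Ensemble"]) -> "Ensemble":
        states: dict[str, list[ConformationalState]] = {}
        for ens in ensembles:
            for label, frames in ens.states.items():
                if label in states:
                    raise StructureError(f"duplicate state label {label!r} while merging")
                states[label] = frames
        return cls(states)


# Idealized Cbeta placement from backbone N/CA/C (1.52 A bond, tetrahedral
# geometry); coefficients express the ideal position in the local frame
# spanned by (CA-N) x (C-CA), CA-N and C-CA.
_CB_COEF_A = -0.58273431
_CB_COEF_B = 0.56802827
_CB_COEF_C = -0.54067466


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Reconstruct an ideal Cβ position from backbone N, CA and C coordinates."""
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return _CB_COEF_A * a + _CB_COEF_B * b + _CB_COEF_C * cc + ca


def _pick_altloc(atoms) -> dict:
    """Highest-occupancy conformer per atom name; occupancy ties keep the first."""
    best: dict[str, object] = {}
    occ: dict[str, float] = {}
    for atom in atoms:
        name = atom.get_name()
        o = atom.get_occupancy()
        o = 1.0 if o is None else float(o)
        if name not in best or o > occ[name]:
            best[name] = atom
            occ[name] = o
    return best


def _state_from_model(model, label: str, source: str) -> ConformationalState:
    sites: list[ResidueSite] = []
    coords: list[np.ndarray] = []
    elements: list[str] = []
    site_index: list[int] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            if hetflag != " ":
                continue  # waters / heteroatoms are not design sites
            if icode.strip():
                raise StructureError(
                    f"insertion code {icode!r} at {chain.id}:{resseq} is not supported"
                )
            atoms = _pick_altloc(residue.get_unpacked_list())
            cb = atoms.get("CB")
            if cb is not None:
                cbeta = np.asarray(cb.get_coord(), float)
                virtual = False
            elif all(k in atoms for k in ("N", "CA", "C")):
                cbeta = virtual_cbeta(
                    atoms["N"].get_coord(), atoms["CA"].get_coord(), atoms["C"].get_coord()
                )
                virtual = True
            elif "CA" in atoms:
                cbeta = np.asarray(atoms["CA"].get_coord(), float)
                virtual = True
            else:
                logger.warning(
                    "dropping residue %s:%s %s (no CA or CB atom)",
                    chain.id, resseq, residue.get_resname(),
                )
                continue
            idx = len(sites)
            sites.append(
                ResidueSite(
                    chain_id=chain.id,
                    residue_number=int(resseq),
                    residue_name=residue.get_resname(),
                    cbeta=cbeta,
                    is_virtual_cbeta=virtual,
                )
            )
            for name, a in atoms.items():
                elem = (a.element or "").upper()
                if elem in ("H", "D"):
                    continue
                coords.append(np.asarray(a.get_coord(), float))
                elements.append(elem if elem else name[0])
                site_index.append(idx)
    if not sites:
        raise StructureError(f"{source}: no usable residues (empty structure)")
    return ConformationalState(
        label=label,
        sites=sites,
        source=source,
        atom_coords=np.vstack(coords) if coords else None,
        atom_elements=elements or None,
        atom_site_index=np.asarray(site_index, int) if site_index else None,
    )


def read_structure(
    path: str | Path,
    model_selector: int | str | None = "all",
    label: str | None = None,
) -> Ensemble:
    """Read a (possibly multi-model) PDB file into a one-label :class:`Ensemble`.

    Parameters
    ----------
    path:
        PDB file.  MODEL/ENDMDL-delimited models are treated as frames.
    model_selector:
        ``"all"`` (default) keeps every model as a frame; an integer selects a
        single model by 0-based position.
    label:
        State label for all selected frames; defaults to the file stem.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read structure file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # malformed content
        raise IOError(f"failed to parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureError(f"{path}: file contains no models")
    if model_selector is None or model_selector == "all":
        selected = list(enumerate(models))
    else:
        idx = int(model_selector)
        if not 0 <= idx < len(models):
            raise StructureError(
                f"{path}: model index {idx} out of range (file has {len(models)})"
            )
        selected = [(idx, models[idx])]
    lbl = label if label is not None else path.stem
    frames = [
        _state_from_model(model, lbl, f"{path.name}#model{i}") for i, model in selected
    ]
    return Ensemble({lbl: frames})


def load_two_state(
    closed_path: str | Path,
    open_path: str | Path,
    closed_label: str = "closed",
    open_label: str = "open",
) -> Ensemble:
    """Read a closed-state and an open-state PDB file into one ensemble."""
    return Ensemble.merge(
        [
            read_structure(closed_path, label=closed_label),
            read_structure(open_path, label=open_label),
        ]
    )


def cbeta_distance_matrix(state: ConformationalState) -> np.ndarray:
    """Symmetric Cβ–Cβ Euclidean distance matrix (Å) for one state."""
    pts = state.cbeta_array()
    return cdist(pts, pts)


def mean_distance_matrix(ensemble: Ensemble, label: str) -> np.ndarray:
    """Element-wise mean of per-frame Cβ distance matrices for one label."""
    frames = ensemble.frames(label)
    return np.mean([cbeta_distance_matrix(f) for f in frames], axis=0)


def distance_matrix_to_tsv(
    matrix: np.ndarray, sites: Sequence[ResidueSite], path: str | Path
) -> None:
    """Write a distance matrix as TSV with chain:resnum row/column headers."""
    labels = [s.label for s in sites]
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} does not match {n} sites")
    with open(path, "w") as fh:
        fh.write("site\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, matrix):
            fh.write(lab + "\t" + "\t".join(f"{v:.3f}" for v in row) + "\n")
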