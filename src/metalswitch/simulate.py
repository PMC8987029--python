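"""Synthetic inputs for the design and screening pipeline.

Four generators, all seeded and bit-reproducible:

* :func:`make_hinge_toy` — a two-domain pseudo-protein whose domains are rigid
  poly-alanine blobs related by a hinge rotation, with residue pairs planted
  at chosen closed-state Cβ distances.  Stands in for the open/closed states
  of a hinged enzyme; emits a ground-truth table of every pair distance.
* :func:`simulate_plate` — raw + descriptor CSV tables for a screening plate
  whose variants carry planted dose-response phenotypes (Hill-form metal
  occupancy driving inhibition or activation).
* :func:`simulate_saturation` — rate-versus-substrate series from a
  Michaelis–Menten or substrate-inhibition parameter set.
* :func:`simulate_switching` — alternating metal/chelator activity rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder
from scipy.spatial.transform import Rotation

from .kinetics import (
    MMParams,
    RateSeries,
    SIParams,
    SwitchingSeries,
    michaelis_menten,
    substrate_inhibition,
)

__all__ = [
    "HingeToySpec",
    "HingeToyResult",
    "make_hinge_toy",
    "VariantSpec",
    "PlateSimSpec",
    "PlateSim",
    "simulate_plate",
    "simulate_saturation",
    "simulate_switching",
]


# ---------------------------------------------------------------------------
# hinge-motion toy structures
# ---------------------------------------------------------------------------

# pseudo-alanine heavy atoms relative to CB (plausible bond lengths; the toy
# is a geometry fixture, not a stereochemically ideal model)
_RESIDUE_TEMPLATE = {
    "CA": np.array([1.530, 0.000, 0.000]),
    "N": np.array([2.020, 1.373, 0.000]),
    "C": np.array([2.100, -1.400, 0.000]),
    "O": np.array([3.120, -2.100, 0.000]),
    "CB": np.array([0.000, 0.000, 0.000]),
}

_A_BOX = np.array([[-20.0, -2.0], [-11.0, 11.0], [-11.0, 11.0]])
_B_BOX = np.array([[2.0, 20.0], [-11.0, 11.0], [-11.0, 11.0]])
_MIN_SEPARATION = 4.0  # A between CB points within a state


@dataclass
class HingeToySpec:
    """Parameters of the two-domain hinge toy.

    ``planted_pairs`` are (residue in chain A, residue in chain B, target
    closed-state Cβ distance in Å) triples; ``hinge_angle_open`` −
    ``hinge_angle_closed`` (degrees, about an axis parallel to y below the
    domains) controls how far pairs separate on opening.
    """

    residues_per_domain: int = 100
    hinge_angle_closed: float = 0.0
    hinge_angle_open: float = 20.0
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    n_frames: int = 1
    hinge_offset: float = 20.0

    def __post_init__(self) -> None:
        if self.residues_per_domain < 2:
            raise ValueError("residues_per_domain must be >= 2")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for i, j, d in self.planted_pairs:
            if not (1 <= i <= self.residues_per_domain and 1 <= j <= self.residues_per_domain):
                raise ValueError(f"planted pair ({i}, {j}) outside residue range")
            if d <= 0:
                raise ValueError("planted target distance must be positive")


@dataclass
class HingeToyResult:
    closed_path: Path
    open_path: Path
    truth: pd.DataFrame
    spec: HingeToySpec


def _sample_in_box(rng: np.random.Generator, box: np.ndarray) -> np.ndarray:
    return rng.uniform(box[:, 0], box[:, 1])


def _hinge_transform(coords: np.ndarray, angle_deg: float, offset: float) -> np.ndarray:
    """Rotate about the line {x=0, z=-offset} parallel to y."""
    theta = np.deg2rad(angle_deg)
    x = coords[:, 0]
    zh = coords[:, 2] + offset
    out = coords.copy()
    out[:, 0] = x * np.cos(theta) + zh * np.sin(theta)
    out[:, 2] = -x * np.sin(theta) + zh * np.cos(theta) - offset
    return out


def _place_cbetas(spec: HingeToySpec, rng: np.random.Generator):
    n = spec.residues_per_domain
    pos_a = np.full((n, 3), np.nan)
    pos_b = np.full((n, 3), np.nan)

    def placed() -> np.ndarray:
        pts = np.vstack([pos_a, pos_b])
        return pts[np.isfinite(pts[:, 0])]

    def far_enough(p: np.ndarray) -> bool:
        pts = placed()
        return pts.size == 0 or np.min(np.linalg.norm(pts - p, axis=1)) >= _MIN_SEPARATION

    for i, j, target in spec.planted_pairs:
        ok = False
        for _ in range(2000):
            p_i = rng.uniform([-9.0, -8.0, -7.0], [-2.5, 8.0, 7.0])
            g = rng.normal(size=3)
            u = np.array([1.2 + 0.5 * abs(g[0]), 0.35 * g[1], 0.35 * g[2]])
            u /= np.linalg.norm(u)
            p_j = p_i + target * u
            if not np.all((_B_BOX[:, 0] <= p_j) & (p_j <= _B_BOX[:, 1])):
                continue
            if far_enough(p_i) and far_enough(p_j) and np.linalg.norm(p_j - p_i) >= _MIN_SEPARATION:
                pos_a[i - 1] = p_i
                pos_b[j - 1] = p_j
                ok = True
                break
        if not ok:
            raise ValueError(
                f"unachievable geometry for planted pair ({i}, {j}, {target} A)"
            )
    for pos, box in ((pos_a, _A_BOX), (pos_b, _B_BOX)):
        for k in range(n):
            if np.isfinite(pos[k, 0]):
                continue
            for _ in range(5000):
                p = _sample_in_box(rng, box)
                if far_enough(p):
                    pos[k] = p
                    break
            else:
                raise ValueError(
                    "could not place all residues with the minimum separation; "
                    "reduce residues_per_domain"
                )
    return pos_a, pos_b


def _atoms_for_domain(cbetas: np.ndarray, rotations: np.ndarray):
    """Expand CB points into full pseudo-residues with per-residue orientation."""
    names = list(_RESIDUE_TEMPLATE)
    offsets = np.stack([_RESIDUE_TEMPLATE[n] for n in names])
    coords = cbetas[:, None, :] + np.einsum("rij,aj->rai", rotations, offsets)
    return names, coords  # (n_res, n_atoms, 3)


def _write_state_pdb(path: Path, frames, chains=("A", "B")) -> None:
    sb = StructureBuilder()
    sb.init_structure("hinge_toy")
    for m, per_chain in enumerate(frames):
        sb.init_model(m)
        sb.init_seg("    ")
        for chain_id, (names, coords) in zip(chains, per_chain):
            sb.init_chain(chain_id)
            for r in range(coords.shape[0]):
                sb.init_residue("ALA", " ", r + 1, " ")
                for a, name in enumerate(names):
                    sb.init_atom(
                        name, coords[r, a].astype(float), 0.0, 1.0, " ",
                        f" {name:<3s}"[:4], element=name[0],
                    )
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def make_hinge_toy(spec: HingeToySpec, outdir: str | Path) -> HingeToyResult:
    """Generate closed/open PDB files plus a ground-truth pair-distance table.

    Planted pairs are guaranteed (validated, else an error) to sit within
    0.1 Å of their target closed-state distance and not to shrink on opening.
    The truth table covers every residue pair with frame-averaged closed and
    open Cβ distances, computed from the generated coordinates themselves.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    pos_a, pos_b = _place_cbetas(spec, rng)

    n = spec.residues_per_domain
    rot_a = Rotation.random(n, rng=rng).as_matrix()
    rot_b = Rotation.random(n, rng=rng).as_matrix()

    pos_b_closed = _hinge_transform(pos_b, spec.hinge_angle_closed, spec.hinge_offset)
    pos_b_open = _hinge_transform(pos_b, spec.hinge_angle_open, spec.hinge_offset)

    state_frames = {}
    cb_frames = {}
    for label, b_cb in (("closed", pos_b_closed), ("open", pos_b_open)):
        frames = []
        cbs = []
        for _ in range(spec.n_frames):
            names_a, coords_a = _atoms_for_domain(pos_a, rot_a)
            names_b, coords_b = _atoms_for_domain(b_cb, rot_b)
            if spec.noise_sd > 0:
                coords_a = coords_a + rng.normal(0.0, spec.noise_sd, coords_a.shape)
                coords_b = coords_b + rng.normal(0.0, spec.noise_sd, coords_b.shape)
            # PDB coordinates carry 3 decimals; round so truth matches the file
            coords_a = coords_a.round(3)
            coords_b = coords_b.round(3)
            frames.append([(names_a, coords_a), (names_b, coords_b)])
            cb_idx = names_a.index("CB")
            cbs.append(np.vstack([coords_a[:, cb_idx], coords_b[:, cb_idx]]))
        state_frames[label] = frames
        cb_frames[label] = cbs

    def mean_dist(cbs: list[np.ndarray]) -> np.ndarray:
        mats = []
        for pts in cbs:
            diff = pts[:, None, :] - pts[None, :, :]
            mats.append(np.sqrt((diff**2).sum(axis=2)))
        return np.mean(mats, axis=0)

    d_closed = mean_dist(cb_frames["closed"])
    d_open = mean_dist(cb_frames["open"])

    # validate the noise-free construction (frame jitter emulates MD motion
    # and is allowed to wander around these anchors)
    planted_set = {(i, j) for i, j, _ in spec.planted_pairs}
    for i, j, target in spec.planted_pairs:
        dc0 = float(np.linalg.norm(pos_b_closed[j - 1] - pos_a[i - 1]))
        do0 = float(np.linalg.norm(pos_b_open[j - 1] - pos_a[i - 1]))
        if abs(dc0 - target) > 0.1:
            raise ValueError(
                f"planted pair ({i}, {j}): generated closed distance "
                f"{dc0:.3f} misses target {target} by > 0.1 A"
            )
        if do0 < dc0 - 1e-6:
            raise ValueError(
                f"planted pair ({i}, {j}): hinge opening shrinks the distance "
                f"({do0:.3f} < {dc0:.3f}); unachievable geometry"
            )

    labels = [("A", k + 1) for k in range(n)] + [("B", k + 1) for k in range(n)]
    rows = []
    total = 2 * n
    for p in range(total):
        for q in range(p + 1, total):
            ci, ri = labels[p]
            cj, rj = labels[q]
            planted = (ri, rj) in planted_set if (ci, cj) == ("A", "B") else False
            rows.append(
                (ci, ri, cj, rj, d_closed[p, q], d_open[p, q],
                 abs(d_open[p, q] - d_closed[p, q]), planted)
            )
    truth = pd.DataFrame(
        rows,
        columns=["chain_i", "res_i", "chain_j", "res_j",
                 "d_closed", "d_open", "delta", "planted"],
    )

    closed_path = outdir / "hinge_closed.pdb"
    open_path = outdir / "hinge_open.pdb"
    _write_state_pdb(closed_path, state_frames["closed"])
    _write_state_pdb(open_path, state_frames["open"])
    truth.to_csv(outdir / "hinge_truth.tsv", sep="\t", index=False)
    return HingeToyResult(closed_path, open_path, truth, spec)


# ---------------------------------------------------------------------------
# screening plates
# ---------------------------------------------------------------------------

PHENOTYPES = ("inhibited", "activated", "unresponsive", "inactive")


@dataclass
class VariantSpec:
    name: str
    phenotype: str
    reversible: bool = True

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


@dataclass
class PlateSimSpec:
    """Study conditions for a simulated dose-response screening plate.

    Defaults mirror the chromogenic screen: a 0–100 µM metal series read over
    two hours (9 timepoints, 900 s apart), triplicate wells, an apo rate of
    0.02 AU/min against a 0.05 AU baseline, and Hill-form (h = 2, matching
    the 2:1 Bpy:metal stoichiometry) dose-dependent occupancy with EC50 1 µM.
    """

    variants: list[VariantSpec] = field(default_factory=list)
    metal: str = "Ni"
    conc_grid: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0, 100.0)
    ec50: float = 1.0
    hill: float = 2.0
    residual_fraction: float = 0.05
    activation_gain: float = 1.0
    apo_rate: float = 0.02  # AU/min
    baseline: float = 0.05  # AU
    noise_sd: float = 0.005  # AU per timepoint
    replicates: int = 3
    timepoints: int = 9
    interval_s: float = 900.0
    include_edta: bool = False
    n_blanks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("residual_fraction must lie in [0, 1]")
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if 0.0 not in self.conc_grid:
            raise ValueError("conc_grid must include the apo (0) concentration")


@dataclass
class PlateSim:
    raw: pd.DataFrame
    descriptor: pd.DataFrame
    truth: pd.DataFrame
    spec: PlateSimSpec

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        raw_path = outdir / "plate_raw.csv"
        desc_path = outdir / "plate_descriptor.csv"
        self.raw.to_csv(raw_path, index=False)
        self.descriptor.to_csv(desc_path, index=False)
        self.truth.to_csv(outdir / "plate_truth.csv", index=False)
        return raw_path, desc_path


def _well_id_stream():
    import itertools
    import string

    for size in range(1, 3):
        for letters in itertools.product(string.ascii_uppercase, repeat=size):
            row = "".join(letters)
            for col in range(1, 25):
                yield f"{row}{col:02d}"


def _occupancy(conc: float, ec50: float, hill: float) -> float:
    if conc <= 0:
        return 0.0
    return conc**hill / (ec50**hill + conc**hill)


def _true_rate(spec: PlateSimSpec, phenotype: str, conc: float) -> float:
    theta = _occupancy(conc, spec.ec50, spec.hill)
    if phenotype == "inhibited":
        return spec.apo_rate * (1.0 - theta * (1.0 - spec.residual_fraction))
    if phenotype == "activated":
        return spec.apo_rate * (1.0 + theta * spec.activation_gain)
    if phenotype == "unresponsive":
        return spec.apo_rate
    return 0.0  # inactive


def simulate_plate(spec: PlateSimSpec) -> PlateSim:
    """Simulate raw/descriptor plate tables with planted phenotype ground truth.

    Each well's signal is ``baseline + rate·t + Gaussian noise`` with the rate
    set by the variant's phenotype and the Hill-form metal occupancy at the
    well's concentration.  EDTA-rescue wells (optional) revert to the apo rate
    when the variant is reversible and keep the metal-bound rate otherwise.
    """
    if not spec.variants:
        raise ValueError("plate spec lists no variants")
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.timepoints) * spec.interval_s
    ids = _well_id_stream()
    max_conc = max(spec.conc_grid)

    desc_rows = []
    truth_rows = []
    signals = {}

    def add_well(variant, metal, conc, edta, rep, blank, rate_au_min):
        wid = next(ids)
        desc_rows.append(
            dict(well=wid, variant=variant, metal=metal, conc_uM=conc,
                 edta=int(edta), replicate=rep, blank=int(blank))
        )
        truth_rows.append(
            dict(well=wid, variant=variant, conc_uM=conc, edta=int(edta),
                 true_rate_au_min=rate_au_min)
        )
        signal = spec.baseline + (rate_au_min / 60.0) * times
        if spec.noise_sd > 0:
            signal = signal + rng.normal(0.0, spec.noise_sd, times.shape)
        signals[wid] = signal

    for v in spec.variants:
        for conc in spec.conc_grid:
            rate = _true_rate(spec, v.phenotype, conc)
            for rep in range(1, spec.replicates + 1):
                add_well(v.name, spec.metal, conc, False, rep, False, rate)
        if spec.include_edta:
            rate = (
                _true_rate(spec, v.phenotype, 0.0)
                if v.reversible
                else _true_rate(spec, v.phenotype, max_conc)
            )
            for rep in range(1, spec.replicates + 1):
                add_well(v.name, spec.metal, max_conc, True, rep, False, rate)
    for rep in range(1, spec.n_blanks + 1):
        add_well("blank", None, 0.0, False, rep, True, 0.0)

    raw = pd.DataFrame({"time_s": times} | signals)
    return PlateSim(raw, pd.DataFrame(desc_rows), pd.DataFrame(truth_rows), spec)


# ---------------------------------------------------------------------------
# saturation curves and switching series
# ---------------------------------------------------------------------------

def simulate_saturation(
    params: MMParams | SIParams,
    conc_grid,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> RateSeries:
    """Rates from a saturation model on a concentration grid, plus seeded noise."""
    conc = np.asarray(conc_grid, float)
    if isinstance(params, SIParams):
        true = substrate_inhibition(conc, params.V_max, params.K_M, params.K_i)
    elif isinstance(params, MMParams):
        true = michaelis_menten(conc, params.V_max, params.K_M)
    else:
        raise TypeError(f"params must be MMParams or SIParams, got {type(params)}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    reps = true[None, :] + (
        rng.normal(0.0, noise_sd, (replicates, conc.size)) if noise_sd > 0 else 0.0
    )
    reps = np.atleast_2d(reps)
    rate = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if replicates > 1 else None
    return RateSeries(conc, rate, sd)


def simulate_switching(
    n_rounds: int = 24,
    on_rate: float = 1.0,
    off_rate: float = 0.05,
    drift_per_round: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    start_state: str = "off",
) -> SwitchingSeries:
    """Alternating on/off activity rounds with optional multiplicative drift.

    The first round defaults to "off" (metal added first, chelator next), as
    in the 24-round alternating metal/EDTA cycling assay.
    """
    if n_rounds < 2:
        raise ValueError("need at least 2 rounds")
    if start_state not in ("on", "off"):
        raise ValueError("start_state must be 'on' or 'off'")
    rng = np.random.default_rng(seed)
    rounds = np.arange(1, n_rounds + 1)
    states = [
        start_state if r % 2 == 1 else ("on" if start_state == "off" else "off")
        for r in rounds
    ]
    base = np.where(np.asarray(states) == "on", on_rate, off_rate).astype(float)
    base *= (1.0 + drift_per_round) ** (rounds - 1)
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, base.shape)
    return SwitchingSeries(rounds, states, base)
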