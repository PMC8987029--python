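"""Residue-pair selection for linker-group (BpyAla) incorporation.

A metal-chelating side-chain pair can cross-link two domains only when, in the
conformation to be trapped (the "closed" state), the two Cβ atoms sit at the
spacing dictated by the bis-bidentate metal complex — about 10.5 Å for
M(Bpy)₂ — while in the other state the spacing is different enough that the
cross-link cannot form.  Candidate pairs must therefore

1. have a closed-state Cβ–Cβ distance inside the configured window,
2. be solvent exposed (relative SASA at or above a threshold),
3. change Cβ–Cβ distance between states by at least a minimum amount, and
4. sit on opposite domains of the enzyme,

and are ranked by descending distance change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .sasa import relative_sasa, shrake_rupley_sasa
from .structures import Ensemble, ResidueSite, mean_distance_matrix

__all__ = [
    "ConfigError",
    "DesignConfig",
    "DomainDefinition",
    "PairCandidate",
    "assign_domains",
    "select_pairs",
    "count_double_variants",
    "pairs_to_tsv",
    "load_design_config",
]


class ConfigError(ValueError):
    """Invalid design configuration or domain definition."""


@dataclass
class DesignConfig:
    """Thresholds for the four selection predicates.

    ``distance_center``/``distance_halfwidth`` default to the 10.5 ± 0.5 Å
    geometric constraint of the Zn(Bpy)₂ complex; ``paper_window()`` widens the
    halfwidth to 1.0 Å, giving the 9.5–11.5 Å screening window.
    """

    closed_label: str = "closed"
    open_label: str = "open"
    distance_center: float = 10.5
    distance_halfwidth: float = 0.5
    min_delta_distance: float = 2.0
    min_relative_sasa: float = 0.20
    sasa_probe_radius: float = 1.4
    sasa_points: int = 960
    require_exposure_both_states: bool = False

    def __post_init__(self) -> None:
        if self.distance_halfwidth <= 0:
            raise ConfigError("distance_halfwidth must be > 0")
        if not 0.0 <= self.min_relative_sasa <= 1.0:
            raise ConfigError("min_relative_sasa must lie in [0, 1]")
        if self.sasa_points < 92:
            raise ConfigError("sasa_points must be >= 92")
        if self.min_delta_distance < 0:
            raise ConfigError("min_delta_distance must be >= 0")

    @property
    def window(self) -> tuple[float, float]:
        return (
            self.distance_center - self.distance_halfwidth,
            self.distance_center + self.distance_halfwidth,
        )

    @classmethod
    def paper_window(cls, **kwargs) -> "DesignConfig":
        """Config using the 9.5–11.5 Å screening window (10.5 ± 1.0 Å)."""
        kwargs.setdefault("distance_center", 10.5)
        kwargs.setdefault("distance_halfwidth", 1.0)
        return cls(**kwargs)


@dataclass
class DomainDefinition:
    """A named domain as inclusive (chain, start, end) residue ranges."""

    name: str
    ranges: list[tuple[str, int, int]] = field(default_factory=list)

    def contains(self, chain_id: str, residue_number: int) -> bool:
        return any(
            chain_id == c and start <= residue_number <= end
            for c, start, end in self.ranges
        )


@dataclass
class PairCandidate:
    """A residue pair passing all four predicates, with its rank."""

    site_i: ResidueSite
    site_j: ResidueSite
    d_closed: float
    d_open: float
    delta_distance: float
    signed_delta: float
    rel_sasa_i: float
    rel_sasa_j: float
    domain_i: str
    domain_j: str
    rank: int = 0


def assign_domains(
    sites: Sequence[ResidueSite], domains: Sequence[DomainDefinition]
) -> list[str]:
    """Map each site to exactly one domain; anything else is a config error."""
    names: list[str] = []
    for site in sites:
        hits = [d.name for d in domains if d.contains(site.chain_id, site.residue_number)]
        if len(hits) == 0:
            raise ConfigError(f"residue {site.label} is not covered by any domain")
        if len(hits) > 1:
            raise ConfigError(
                f"residue {site.label} falls in overlapping domains {hits}"
            )
        names.append(hits[0])
    return names


def _mean_relative_sasa(ensemble: Ensemble, label: str, config: DesignConfig) -> np.ndarray:
    frames = ensemble.frames(label)
    rel = np.zeros(len(frames[0].sites))
    for frame in frames:
        abs_sasa = shrake_rupley_sasa(
            frame, probe_radius=config.sasa_probe_radius, n_points=config.sasa_points
        )
        rel += np.array(
            [relative_sasa(a, s.residue_name) for a, s in zip(abs_sasa, frame.sites)]
        )
    return rel / len(frames)


def select_pairs(
    ensemble: Ensemble,
    domains: Sequence[DomainDefinition],
    config: DesignConfig | None = None,
) -> list[PairCandidate]:
    """Filter and rank residue pairs for linker-group incorporation.

    Distances are per-label means over frames (a single representative
    structure per state is the one-frame special case).  Exposure is assessed
    in the closed state unless ``require_exposure_both_states`` is set.
    Output is sorted by descending distance change; ties break on ascending
    (chain, residue number) identifiers, and ranks run 1..k.
    """
    config = config or DesignConfig()
    for label in (config.closed_label, config.open_label):
        if label not in ensemble.states:
            raise ConfigError(
                f"ensemble lacks required state label {label!r}; has {ensemble.labels}"
            )
    sites = ensemble.representative(config.closed_label).sites
    domain_of = assign_domains(sites, domains)

    d_closed = mean_distance_matrix(ensemble, config.closed_label)
    d_open = mean_distance_matrix(ensemble, config.open_label)
    rel = _mean_relative_sasa(ensemble, config.closed_label, config)
    if config.require_exposure_both_states:
        rel = np.minimum(
            rel, _mean_relative_sasa(ensemble, config.open_label, config)
        )

    lo, hi = config.window
    exposed = rel >= config.min_relative_sasa
    candidates: list[PairCandidate] = []
    n = len(sites)
    for i in range(n):
        for j in range(i + 1, n):
            dc = d_closed[i, j]
            if not lo <= dc <= hi:
                continue
            if not (exposed[i] and exposed[j]):
                continue
            signed = d_open[i, j] - dc
            if abs(signed) < config.min_delta_distance:
                continue
            if domain_of[i] == domain_of[j]:
                continue
            a, b = i, j
            if sites[b].key < sites[a].key:
                a, b = b, a
            candidates.append(
                PairCandidate(
                    site_i=sites[a],
                    site_j=sites[b],
                    d_closed=float(dc),
                    d_open=float(d_open[i, j]),
                    delta_distance=float(abs(signed)),
                    signed_delta=float(signed),
                    rel_sasa_i=float(rel[a]),
                    rel_sasa_j=float(rel[b]),
                    domain_i=domain_of[a],
                    domain_j=domain_of[b],
                )
            )
    candidates.sort(key=lambda p: (-p.delta_distance, p.site_i.key, p.site_j.key))
    for rank, cand in enumerate(candidates, start=1):
        cand.rank = rank
    return candidates


def count_double_variants(n_residues: int) -> int:
    """Number of distinct residue pairs, C(n, 2) — e.g. 616 sites → 189,420."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues to form a pair")
    return n_residues * (n_residues - 1) // 2


def pairs_to_tsv(pairs: Sequence[PairCandidate], path: str | Path) -> None:
    cols = (
        "res_i\tres_j\td_closed\td_open\tdelta\tsigned_delta\t"
        "rel_sasa_i\trel_sasa_j\tdomain_i\tdomain_j\trank\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for p in pairs:
            fh.write(
                f"{p.site_i.label}\t{p.site_j.label}\t{p.d_closed:.3f}\t{p.d_open:.3f}\t"
                f"{p.delta_distance:.3f}\t{p.signed_delta:.3f}\t{p.rel_sasa_i:.3f}\t"
                f"{p.rel_sasa_j:.3f}\t{p.domain_i}\t{p.domain_j}\t{p.rank}\n"
            )


def load_design_config(path: str | Path) -> tuple[DesignConfig, list[DomainDefinition]]:
    """Load a DesignConfig plus domain definitions from one YAML/JSON file.

    Layout::

        design: {distance_center: 10.5, distance_halfwidth: 1.0, ...}
        domains:
          - {name: propeller, ranges: [[A, 1, 100]]}
          - {name: peptidase, ranges: [[B, 1, 100]]}
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = set(DesignConfig.__dataclass_fields__)
    design_raw = raw.get("design", {}) or {}
    unknown = set(design_raw) - known
    if unknown:
        raise ConfigError(f"unknown design config keys: {sorted(unknown)}")
    config = DesignConfig(**design_raw)
    domains = []
    for d in raw.get("domains", []):
        extra = set(d) - {"name", "ranges"}
        if extra:
            raise ConfigError(f"unknown domain keys: {sorted(extra)}")
        domains.append(
            DomainDefinition(
                name=str(d["name"]),
                ranges=[(str(c), int(s), int(e)) for c, s, e in d["ranges"]],
            )
        )
    if not domains:
        raise ConfigError(f"config file {path} defines no domains")
    return config, domains
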