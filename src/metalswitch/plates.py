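"""Plate-reader kinetic screening analysis.

Reproduces the high-throughput analysis used for 384-well chromogenic screens:
two CSV inputs (a raw time × wells table and a per-well descriptor table) are
joined into kinetic traces; the rate of each well is the maximum
ordinary-least-squares slope over a sliding window of five timepoints;
replicates are averaged; and each variant × metal series is classified as
inhibited (<50% of apo activity at the highest metal concentration), activated
(>50% increase), unresponsive, or inactive (apo rate below an activity floor).
EDTA-rescue wells quantify reversibility as the fractional recovery of apo
activity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WellDescriptor",
    "KineticTrace",
    "RateResult",
    "DoseResponseResult",
    "RecoveryResult",
    "read_plate_csvs",
    "sliding_window_max_slope",
    "trace_max_slopes",
    "aggregate_condition",
    "aggregate_rates",
    "classify_dose_response",
    "classify_plate",
    "reversibility_recovery",
    "reversibility_table",
]

DESCRIPTOR_COLUMNS = ["well", "variant", "metal", "conc_uM", "edta", "replicate", "blank"]
TIME_COLUMN = "time_s"

#: absorbance above which plate-reader response is treated as saturated (AU)
DEFAULT_SATURATION_CEILING = 3.5


@dataclass(frozen=True)
class WellDescriptor:
    well_id: str
    variant: str
    metal: str | None
    metal_conc: float
    edta: bool
    replicate: int
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.metal_conc < 0:
            raise ValueError(f"well {self.well_id}: metal_conc must be >= 0")


@dataclass
class KineticTrace:
    """One well's signal-versus-time series (times in seconds, strictly increasing)."""

    well: WellDescriptor
    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.signal = np.asarray(self.signal, float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError(f"well {self.well.well_id}: times/signal shape mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"well {self.well.well_id}: times must be strictly increasing")


@dataclass
class RateResult:
    """Replicate-aggregated maximum slope for one reaction condition."""

    variant: str
    metal: str | None
    metal_conc: float
    edta: bool
    mean_max_slope: float
    sd: float
    n_replicates: int
    window_start_time: float

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class DoseResponseResult:
    variant: str
    metal: str | None
    concentrations: np.ndarray
    normalized_rates: np.ndarray
    classification: str  # inhibited | activated | unresponsive | inactive
    fold_change_low_high: float
    apo_rate: float


@dataclass
class RecoveryResult:
    recovery: float
    after_over_apo: float
    defined: bool


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes", "y")
    return bool(int(value))


def read_plate_csvs(raw_path: str | Path, descriptor_path: str | Path) -> list[KineticTrace]:
    """Join the raw time × wells table with the per-well descriptor table.

    The raw CSV's first column is ``time_s``; each remaining column is a well.
    Wells present in the raw table but missing from the descriptor are skipped
    with a warning; a descriptor row naming a missing well is an error, as is
    a duplicated well id.
    """
    raw = pd.read_csv(raw_path)
    if raw.columns[0] != TIME_COLUMN:
        raise ValueError(
            f"raw CSV must have '{TIME_COLUMN}' as its first column, got {raw.columns[0]!r}"
        )
    desc = pd.read_csv(descriptor_path)
    missing_cols = [c for c in DESCRIPTOR_COLUMNS if c not in desc.columns]
    if missing_cols:
        raise ValueError(f"descriptor CSV lacks columns: {missing_cols}")
    if desc["well"].duplicated().any():
        dups = sorted(desc.loc[desc["well"].duplicated(), "well"].unique())
        raise ValueError(f"duplicate well ids in descriptor: {dups}")

    raw_wells = set(raw.columns[1:])
    times = raw[TIME_COLUMN].to_numpy(float)
    traces: list[KineticTrace] = []
    for row in desc.itertuples(index=False):
        well_id = str(row.well)
        if well_id not in raw_wells:
            raise ValueError(f"descriptor references well {well_id!r} absent from raw CSV")
        metal = None if pd.isna(row.metal) or str(row.metal).strip() == "" else str(row.metal)
        wd = WellDescriptor(
            well_id=well_id,
            variant=str(row.variant),
            metal=metal,
            metal_conc=float(row.conc_uM),
            edta=_parse_bool(row.edta),
            replicate=int(row.replicate),
            is_blank=_parse_bool(row.blank),
        )
        traces.append(KineticTrace(wd, times.copy(), raw[well_id].to_numpy(float)))
    undescribed = raw_wells - {t.well.well_id for t in traces}
    if undescribed:
        logger.warning("skipping %d undescribed wells: %s", len(undescribed), sorted(undescribed))
    return traces


def _clean(times: np.ndarray, signal: np.ndarray, saturation_ceiling: float | None):
    keep = np.isfinite(times) & np.isfinite(signal)
    if saturation_ceiling is not None:
        keep &= signal < saturation_ceiling
    return times[keep], signal[keep]


def sliding_window_max_slope(
    trace: KineticTrace,
    window_size: int = 5,
    saturation_ceiling: float | None = DEFAULT_SATURATION_CEILING,
) -> tuple[float, float]:
    """Maximum OLS slope over all contiguous windows of ``window_size`` points.

    Returns ``(max_slope, window_start_time)`` with the slope in signal units
    per second (the unit of the stored times).  Non-finite points and points at
    or above the saturation ceiling are dropped before windowing.  Ties go to
    the earliest window, which on concave initial-rate traces makes this the
    classic initial-rate estimate.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    t, y = _clean(trace.times, trace.signal, saturation_ceiling)
    if t.size < window_size:
        raise ValueError(
            f"well {trace.well.well_id}: {t.size} usable points < window of {window_size}"
        )
    tw = np.lib.stride_tricks.sliding_window_view(t, window_size)
    yw = np.lib.stride_tricks.sliding_window_view(y, window_size)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    slopes = (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)
    best = int(np.argmax(slopes))  # first occurrence on ties
    return float(slopes[best]), float(tw[best, 0])


def trace_max_slopes(
    traces: Sequence[KineticTrace],
    window_size: int = 5,
    per_minute: bool = True,
    saturation_ceiling: float | None = DEFAULT_SATURATION_CEILING,
    blank_correct: bool = False,
) -> pd.DataFrame:
    """Per-well maximum slopes with descriptor metadata.

    Slopes are reported per minute by default (times are stored in seconds).
    With ``blank_correct`` the mean slope of blank wells is subtracted from
    every well.
    """
    rows = []
    for tr in traces:
        slope, t0 = sliding_window_max_slope(tr, window_size, saturation_ceiling)
        w = tr.well
        rows.append(
            dict(
                well=w.well_id, variant=w.variant, metal=w.metal,
                conc_uM=w.metal_conc, edta=w.edta, replicate=w.replicate,
                blank=w.is_blank, rate=slope * (60.0 if per_minute else 1.0),
                window_start_s=t0,
            )
        )
    df = pd.DataFrame(rows)
    if blank_correct and df["blank"].any():
        df["rate"] -= df.loc[df["blank"], "rate"].mean()
    return df


def aggregate_condition(rates: Sequence[float]) -> tuple[float, float, int]:
    """Mean, sample standard deviation (n−1; 0 when n = 1) and n of replicates."""
    arr = np.asarray(list(rates), float)
    if arr.size == 0:
        raise ValueError("empty replicate group")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def aggregate_rates(well_rates: pd.DataFrame) -> list[RateResult]:
    """Collapse per-well rates into per-condition :class:`RateResult` rows."""
    results = []
    grouped = well_rates.groupby(["variant", "metal", "conc_uM", "edta"], dropna=False)
    for (variant, metal, conc, edta), grp in grouped:
        mean, sd, n = aggregate_condition(grp["rate"])
        results.append(
            RateResult(
                variant=str(variant),
                metal=None if pd.isna(metal) else str(metal),
                metal_conc=float(conc),
                edta=bool(edta),
                mean_max_slope=mean,
                sd=sd,
                n_replicates=n,
                window_start_time=float(grp["window_start_s"].mean()),
            )
        )
    return results


def classify_dose_response(
    rates: Sequence[RateResult],
    activity_floor: float = 0.0,
    inhibition_ratio: float = 0.5,
    activation_ratio: float = 1.5,
) -> DoseResponseResult:
    """Classify one variant × metal concentration series.

    ``activity_floor`` is an absolute rate below which the variant counts as
    inactive; callers typically pass a fraction (default 5%) of a wild-type
    reference rate.  Otherwise the ratio of the rate at the highest metal
    concentration to the apo (0 metal) rate decides: < ``inhibition_ratio``
    (0.5, i.e. less than 50% apo activity) → inhibited; > ``activation_ratio``
    (1.5, i.e. a >50% increase) → activated; else unresponsive.
    """
    series = sorted((r for r in rates if not r.edta), key=lambda r: r.metal_conc)
    if len(series) < 2:
        raise ValueError("need rates at >= 2 concentrations (including apo)")
    if series[0].metal_conc != 0.0:
        raise ValueError("missing apo (0 metal) condition")
    variants = {r.variant for r in series}
    if len(variants) != 1:
        raise ValueError(f"mixed variants in one dose-response series: {sorted(variants)}")
    concs = np.array([r.metal_conc for r in series])
    vals = np.array([r.mean_max_slope for r in series])
    apo = vals[0]
    high = vals[-1]
    normalized = vals / apo if apo > 0 else np.full_like(vals, np.nan)
    if apo < activity_floor:
        cls = "inactive"
    else:
        ratio = high / apo if apo > 0 else math.inf
        if ratio < inhibition_ratio:
            cls = "inhibited"
        elif ratio > activation_ratio:
            cls = "activated"
        else:
            cls = "unresponsive"
    fold = apo / high if high > 0 else math.inf
    return DoseResponseResult(
        variant=series[0].variant,
        metal=series[0].metal,
        concentrations=concs,
        normalized_rates=normalized,
        classification=cls,
        fold_change_low_high=float(fold),
        apo_rate=float(apo),
    )


def classify_plate(
    rate_results: Sequence[RateResult],
    wt_variant: str | None = None,
    floor_fraction: float = 0.05,
    absolute_floor: float = 0.0,
    inhibition_ratio: float = 0.5,
    activation_ratio: float = 1.5,
) -> list[DoseResponseResult]:
    """Classify every (variant, metal) series on a plate.

    When ``wt_variant`` is given, the inactive floor is ``floor_fraction``
    (default 5%) of the wild-type apo rate; otherwise ``absolute_floor``.
    Blank wells and EDTA-rescue wells are excluded from dose-response series.
    """
    floor = absolute_floor
    if wt_variant is not None:
        wt_apo = [
            r for r in rate_results
            if r.variant == wt_variant and r.metal_conc == 0.0 and not r.edta
        ]
        if not wt_apo:
            raise ValueError(f"no apo condition found for WT reference {wt_variant!r}")
        floor = floor_fraction * wt_apo[0].mean_max_slope
    out = []
    keys = sorted(
        {
            (r.variant, r.metal)
            for r in rate_results
            if not r.edta and r.variant != "blank" and r.metal is not None
        }
    )
    for variant, metal in keys:
        series = [
            r for r in rate_results
            if r.variant == variant and r.metal == metal and not r.edta
        ]
        # the apo point may be recorded with metal=None; fold it in
        if not any(r.metal_conc == 0.0 for r in series):
            series += [
                r for r in rate_results
                if r.variant == variant and r.metal is None
                and r.metal_conc == 0.0 and not r.edta
            ]
        out.append(
            classify_dose_response(
                series,
                activity_floor=floor,
                inhibition_ratio=inhibition_ratio,
                activation_ratio=activation_ratio,
            )
        )
    return out


def reversibility_recovery(
    rate_metal: float,
    rate_metal_then_edta: float,
    rate_apo: float,
    rel_tol: float = 0.05,
) -> RecoveryResult:
    """Fractional recovery of apo activity after chelator rescue.

    ``recovery = (after_EDTA − with_metal) / (apo − with_metal)``: 1 for full
    reversal, 0 when chelation does not restore activity.  When the metal rate
    is within ``rel_tol`` of the apo rate (a non-responder) the fraction is
    undefined and flagged.
    """
    denom = rate_apo - rate_metal
    scale = max(abs(rate_apo), abs(rate_metal), 1e-300)
    after_over_apo = rate_metal_then_edta / rate_apo if rate_apo != 0 else math.inf
    if abs(denom) <= rel_tol * scale:
        return RecoveryResult(math.nan, after_over_apo, defined=False)
    return RecoveryResult((rate_metal_then_edta - rate_metal) / denom, after_over_apo, True)


def reversibility_table(rate_results: Sequence[RateResult]) -> pd.DataFrame:
    """Recovery fractions for every (variant, metal) with EDTA-rescue wells."""
    rows = []
    edta_conditions = {
        (r.variant, r.metal): r for r in rate_results if r.edta and r.variant != "blank"
    }
    for (variant, metal), after in edta_conditions.items():
        same = [r for r in rate_results if r.variant == variant and not r.edta]
        apo = [r for r in same if r.metal_conc == 0.0]
        with_metal = [r for r in same if r.metal == metal and r.metal_conc > 0]
        if not apo or not with_metal:
            continue
        metal_rate = max(with_metal, key=lambda r: r.metal_conc).mean_max_slope
        rec = reversibility_recovery(metal_rate, after.mean_max_slope, apo[0].mean_max_slope)
        rows.append(
            dict(
                variant=variant, metal=metal, rate_metal=metal_rate,
                rate_after_edta=after.mean_max_slope, rate_apo=apo[0].mean_max_slope,
                recovery=rec.recovery, after_over_apo=rec.after_over_apo,
                defined=rec.defined,
            )
        )
    return pd.DataFrame(rows)
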