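"""Normalisation formulas for functional-assay readouts and viral titration.

Every operation here is an exactly reproducible arithmetic transform of
plate-reader or qPCR data: baseline fold change, vehicle-control
normalisation, dual-luciferase ratios, the consecutive dCq/ddCq/fold-change
chain for RT-qPCR (sign convention: dCq = geometric mean of the reference
genes' Cq minus the target Cq, so fold change = 2^ddCq with no negation),
and transforming-units-per-ml lentiviral titer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError


@dataclass
class PlateTrace:
    """One well's time-resolved luminescence with its condition labels."""

    well: str
    times: np.ndarray  # minutes, strictly increasing
    values: np.ndarray  # arbitrary luminescence units
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError(f"well {self.well}: times/values length mismatch")
        if self.times.size == 0:
            raise ValidationError(f"well {self.well}: empty trace")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"well {self.well}: times not strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"well {self.well}: non-finite luminescence")


def baseline_fold_change(
    trace: PlateTrace, baseline_window: tuple[float, float]
) -> PlateTrace:
    """Divide every value by the mean over the baseline time window."""
    lo, hi = baseline_window
    mask = (trace.times >= lo) & (trace.times <= hi)
    if not mask.any():
        raise ValidationError(
            f"well {trace.well}: baseline window [{lo}, {hi}] contains no time point"
        )
    baseline = trace.values[mask].mean()
    if baseline == 0:
        raise ValidationError(f"well {trace.well}: zero baseline mean")
    return PlateTrace(
        well=trace.well,
        times=trace.times.copy(),
        values=trace.values / baseline,
        condition=dict(trace.condition),
    )


def vehicle_normalize(
    traces: list[PlateTrace], vehicle_group: str, condition_key: str = "treatment"
) -> list[PlateTrace]:
    """Divide each trace, per time point, by the vehicle-group mean.

    Vehicle wells (``condition[condition_key] == vehicle_group``) must cover
    every time point present in the treated wells.
    """
    vehicle = [t for t in traces if t.condition.get(condition_key) == vehicle_group]
    if not vehicle:
        raise ConfigError(f"no wells labelled {condition_key}={vehicle_group!r}")
    ref_times = vehicle[0].times
    for v in vehicle[1:]:
        if not np.array_equal(v.times, ref_times):
            raise ValidationError("vehicle wells sample different time points")
    vehicle_mean = np.mean([v.values for v in vehicle], axis=0)

    out = []
    for t in traces:
        if not np.array_equal(t.times, ref_times):
            raise ValidationError(
                f"well {t.well}: time points not aligned with vehicle control"
            )
        out.append(
            PlateTrace(
                well=t.well,
                times=t.times.copy(),
                values=t.values / vehicle_mean,
                condition=dict(t.condition),
            )
        )
    return out


def dual_reporter_fold(
    firefly: np.ndarray | float,
    renilla: np.ndarray | float,
    vehicle_mean_ratio: float,
) -> np.ndarray | float:
    """(firefly / renilla) / vehicle mean ratio.

    The renilla channel controls for transfection efficiency and cell number;
    dividing by the vehicle triplicate's mean ratio yields the fold change.
    """
    firefly = np.asarray(firefly, dtype=float)
    renilla = np.asarray(renilla, dtype=float)
    if np.any(renilla <= 0):
        raise ValidationError("renilla luminescence must be positive")
    if vehicle_mean_ratio <= 0:
        raise ValidationError("vehicle mean ratio must be positive")
    result = (firefly / renilla) / vehicle_mean_ratio
    return float(result) if result.ndim == 0 else result


@dataclass
class CqTable:
    """Sample × gene mean quantification cycles with reference-gene set."""

    cq: pd.DataFrame  # rows = samples, columns = genes
    reference_genes: list[str]
    control_sample: str

    def __post_init__(self) -> None:
        if not self.reference_genes:
            raise ValidationError("reference gene set must be non-empty")
        missing = set(self.reference_genes) - set(self.cq.columns)
        if missing:
            raise ValidationError(f"reference gene(s) absent: {sorted(missing)}")
        if self.control_sample not in self.cq.index:
            raise ConfigError(f"control sample {self.control_sample!r} absent")
        if not np.all(np.isfinite(self.cq.to_numpy(dtype=float))):
            raise ValidationError("Cq table contains non-finite values")


def ddcq_fold_change(cq: CqTable) -> pd.DataFrame:
    """Per-sample per-gene fold change via dCq → ddCq → 2^ddCq.

    dCq = geometric mean of reference-gene Cq − target Cq;
    ddCq = dCq − dCq of the control sample; fold change = 2^ddCq.
    """
    ref = cq.cq[cq.reference_genes].to_numpy(dtype=float)
    if np.any(ref <= 0):
        raise ValidationError("reference Cq values must be positive for geometric mean")
    geo = np.exp(np.log(ref).mean(axis=1))  # per sample
    dcq = geo[:, None] - cq.cq.to_numpy(dtype=float)
    dcq = pd.DataFrame(dcq, index=cq.cq.index, columns=cq.cq.columns)
    ddcq = dcq - dcq.loc[cq.control_sample]
    return 2.0 ** ddcq


def lentiviral_titer(
    cells_transduced: float,
    pct_egfp: float,
    dilution_factor: float,
    volume_ml: float,
) -> float:
    """Transforming units per ml: cells × %EGFP × dilution / (volume × 100)."""
    for name, val in (
        ("cells_transduced", cells_transduced),
        ("pct_egfp", pct_egfp),
        ("dilution_factor", dilution_factor),
        ("volume_ml", volume_ml),
    ):
        if val <= 0:
            raise ValidationError(f"{name} must be > 0, got {val}")
    if pct_egfp > 100:
        raise ValidationError(f"pct_egfp is a 0-100 percentage, got {pct_egfp}")
    return (cells_transduced * pct_egfp * dilution_factor) / (volume_ml * 100.0)
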