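"""Simulated genome-scale ER-expansion screen tables with known ground truth.

Each row is one imaged field of one well: mutant id, cell count, mean cell
area, mean ER-marker intensity, and the three mid-section ER metrics.  Values
are built additively:

    value = global mean + plate offset + smooth covariate trends
            + planted mutant effect + well-level noise + field-level noise

so every downstream normalization step has a known quantity to remove.  The
well/field split of the residual reflects that the two fields of view of a
well image the same culture: most residual variation is shared between them
(field fraction 0.2 of the residual SD by default).  Metric residuals are
correlated across the three metrics as the underlying cell population links
them (more peripheral ER also means larger profiles and fewer gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CovariateEffects", "ScreenSimSpec", "simulate_screen_table", "METRICS"]

METRICS = ("peripheral_er_size", "er_profile_size", "er_gaps_per_um")

#: global means and residual SDs of the three metrics plus marker intensity,
#: in their natural units (fractions, gaps/um, arbitrary intensity units)
_BASE_MEAN = {
    "peripheral_er_size": 0.45,
    "er_profile_size": 0.08,
    "er_gaps_per_um": 0.35,
    "intensity": 1000.0,
}
_BASE_SD = {
    "peripheral_er_size": 0.04,
    "er_profile_size": 0.012,
    "er_gaps_per_um": 0.08,
    "intensity": 60.0,
}

#: residual correlation among the three metrics (well level)
_METRIC_CORR = np.array(
    [
        [1.0, 0.4, -0.3],
        [0.4, 1.0, -0.2],
        [-0.3, -0.2, 1.0],
    ]
)


@dataclass(frozen=True)
class CovariateEffects:
    """Amplitudes (in units of each metric's residual SD) of the smooth trends
    tied to mean cell area, per-field cell count, and well imaging order."""

    cell_area: float = 0.2
    cell_count: float = 0.15
    well_order: float = 0.15


@dataclass(frozen=True)
class ScreenSimSpec:
    n_plates: int = 16
    wells_per_plate: int = 300
    fields_per_well: int = 2
    n_controls_per_plate: int = 2
    plate_offset_sd: float = 0.5  # in residual-SD units, applied per metric
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    residual_sd: float = 1.0  # scalar multiplier on the per-metric base SDs
    field_sd_fraction: float = 0.2  # share of residual SD that is field-level
    planted_hits: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_plates, self.wells_per_plate, self.fields_per_well) < 1:
            raise ValueError("plate/well/field counts must be >= 1")
        if self.plate_offset_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be >= 0")
        if not 0.0 <= self.field_sd_fraction <= 1.0:
            raise ValueError("field_sd_fraction must lie in [0, 1]")
        for mid, effects in self.planted_hits.items():
            for metric in effects:
                if metric not in METRICS:
                    raise ValueError(f"unknown metric {metric!r} for hit {mid!r}")


def _trend_params(spec: "ScreenSimSpec") -> dict[str, tuple[float, float]]:
    """Phase/slope of the smooth covariate trends, fixed once per spec seed."""
    trng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([spec.seed, 977]))
    )
    return {
        name: (float(trng.uniform(0, 2 * np.pi)), float(trng.uniform(0.2, 0.6)))
        for name in ("cell_area", "cell_count", "well_order")
    }


def _trend_value(x: float, params: tuple[float, float]) -> float:
    phase, slope = params
    return float(np.sin(1.3 * x + phase) + slope * x)


def simulate_screen_table(spec: ScreenSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a screen table; returns (table, truth).

    ``table`` has one row per (plate, well, field) with the ScreenTable
    columns; ``truth`` has one row per mutant with its planted per-metric
    effects (in residual-SD units) and an ``is_true_hit`` flag.
    """
    spec.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    ce = spec.covariate_effects
    sd = {k: v * spec.residual_sd for k, v in _BASE_SD.items()}
    f_frac = spec.field_sd_fraction
    well_frac = float(np.sqrt(max(1.0 - f_frac**2, 0.0)))
    chol = np.linalg.cholesky(_METRIC_CORR)

    # mutants that must exist for planted hits
    planted = dict(spec.planted_hits)
    rows = []
    truth_rows = []
    mutant_counter = 0
    planted_ids = list(planted)
    # spread planted mutant ids over wells deterministically: they replace the
    # first wells of successive plates (after controls)
    planted_assignment: dict[tuple[int, int], str] = {}
    for k, mid in enumerate(planted_ids):
        plate = k % spec.n_plates
        slot = spec.n_controls_per_plate + k // spec.n_plates
        if slot >= spec.wells_per_plate:
            raise ValueError("more planted hits than available wells")
        planted_assignment[(plate, slot)] = mid

    trends_p = _trend_params(spec)
    for p in range(spec.n_plates):
        plate_id = f"plate{p:02d}"
        plate_offset = {
            m: rng.normal(0.0, spec.plate_offset_sd * sd[m])
            for m in (*METRICS, "intensity")
        }
        order = np.arange(spec.wells_per_plate)
        for w in range(spec.wells_per_plate):
            well_id = f"{p:02d}-{w:03d}"
            is_control = w < spec.n_controls_per_plate
            mid = planted_assignment.get((p, w))
            if is_control:
                mutant = "WT"
            elif mid is not None:
                mutant = mid
            else:
                mutant = f"mut{mutant_counter:05d}"
                mutant_counter += 1
            effects = planted.get(mutant, {})
            if not is_control and mutant not in ("WT",):
                truth_rows.append(
                    {
                        "mutant": mutant,
                        "is_true_hit": mutant in planted,
                        **{f"effect_{m}": effects.get(m, 0.0) for m in METRICS},
                    }
                )
            area = rng.normal(1400.0, 120.0)
            # correlated well-level residuals for the three metrics
            well_noise = chol @ rng.normal(0.0, 1.0, 3) * well_frac
            int_well = rng.normal(0.0, 1.0) * well_frac
            for f in range(spec.fields_per_well):
                count = max(int(rng.normal(180.0, 45.0)), 5)
                x_area = (area - 1400.0) / 120.0
                x_count = (count - 180.0) / 45.0
                x_order = (w - order.mean()) / max(order.std(), 1.0)
                row = {
                    "plate": plate_id,
                    "well": well_id,
                    "well_order": w,
                    "field": f,
                    "mutant": mutant,
                    "is_control": is_control,
                    "cell_count": count,
                    "mean_cell_area": area,
                }
                trends = {
                    "cell_area": _trend_value(x_area, trends_p["cell_area"]),
                    "cell_count": _trend_value(x_count, trends_p["cell_count"]),
                    "well_order": _trend_value(x_order, trends_p["well_order"]),
                }
                intensity = (
                    _BASE_MEAN["intensity"]
                    + plate_offset["intensity"]
                    + ce.cell_area * sd["intensity"] * trends["cell_area"]
                    + ce.cell_count * sd["intensity"] * trends["cell_count"]
                    + sd["intensity"]
                    * (int_well + f_frac * rng.normal(0.0, 1.0))
                )
                row["mean_marker_intensity"] = intensity
                field_noise = chol @ rng.normal(0.0, 1.0, 3) * f_frac
                for j, m in enumerate(METRICS):
                    row[m] = (
                        _BASE_MEAN[m]
                        + plate_offset[m]
                        + ce.cell_area * sd[m] * trends["cell_area"]
                        + ce.cell_count * sd[m] * trends["cell_count"]
                        + ce.well_order * sd[m] * trends["well_order"]
                        + effects.get(m, 0.0) * sd[m]
                        + sd[m] * (well_noise[j] + field_noise[j])
                    )
                rows.append(row)
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["mutant", "is_true_hit", *(f"effect_{m}" for m in METRICS)],
    )
    return table, truth
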