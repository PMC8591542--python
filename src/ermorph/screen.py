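"""Genome-scale ER-expansion screen scoring.

Mutants on the same imaging plate serve as a plate-specific background
population (BP).  The scoring procedure is:

1. normalize marker intensities (subtract plate means, then local-regression
   corrections against mean cell area and cell count);
2. define the BP per plate as the rows within 1.5 SD of the plate's mean
   corrected intensity — excluding extreme outliers from the reference;
3. per ER metric, Z = (sample - BP mean) / BP SD, removing plate effects;
4. correct Z for well imaging order, then for cell count, by local
   regression (LOWESS: tricube-weighted local linear fit, span 0.3,
   2 robustness iterations);
5. aggregate the per-field Z per sample by keeping the field value of
   maximal absolute value with its sign (so underexpansion hits are not
   masked by the sign convention);
6. call hits: Z < -2 flags peripheral ER size and ER profile size, Z > 2
   flags ER gaps; a strain is a hit when at least two of the three metrics
   are flagged.

The module is organised as a statsmodels-style model/results pair:
``ERExpansionScreen(table).fit()`` returns :class:`ScreenResults` carrying
the per-field Z table, per-sample aggregates, hit calls and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "METRICS",
    "HIT_DIRECTION",
    "ScreenParams",
    "BackgroundPopulation",
    "ERExpansionScreen",
    "ScreenResults",
    "loess_correct",
    "normalize_intensity",
    "define_background_population",
    "compute_zscores",
    "aggregate_per_sample",
    "call_hits",
]

METRICS = ("peripheral_er_size", "er_profile_size", "er_gaps_per_um")
#: hit direction per metric: -1 flags Z < -threshold, +1 flags Z > +threshold
HIT_DIRECTION = {
    "peripheral_er_size": -1,
    "er_profile_size": -1,
    "er_gaps_per_um": +1,
}
_ZCOL = {m: f"z_{m}" for m in METRICS}


@dataclass(frozen=True)
class ScreenParams:
    loess_span: float = 0.3
    loess_iterations: int = 2
    bp_intensity_sd: float = 1.5
    hit_threshold: float = 2.0
    min_metrics_for_hit: int = 2
    min_cell_count: int = 25
    min_loess_points: int = 10


@dataclass
class BackgroundPopulation:
    """Per-plate reference population and its per-metric moments."""

    plate: str
    member_index: pd.Index
    bp_mean: dict[str, float]
    bp_sd: dict[str, float]


def loess_correct(
    values: np.ndarray,
    covariate: np.ndarray,
    span: float = 0.3,
    iterations: int = 2,
    min_points: int = 10,
) -> np.ndarray:
    """Residuals of a locally weighted linear regression of values on a covariate.

    Returns ``values - fit``; with fewer than ``min_points`` points the values
    are returned unchanged with a warning.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.shape != covariate.shape:
        raise ValueError("values and covariate must have the same length")
    if not np.all(np.isfinite(covariate)):
        raise ValueError("covariate must be finite")
    if len(values) < min_points:
        warnings.warn("too few points for local regression; values returned as-is")
        return values.copy()
    span_px = np.ptp(covariate)

    def fit(y):
        return lowess(
            y,
            covariate,
            frac=span,
            it=iterations,
            delta=0.01 * span_px,
            return_sorted=False,
        )

    # two passes ("twicing"): refitting the residuals removes most of the
    # attenuation bias a single local-linear smooth leaves on curved trends
    residual = values - fit(values)
    return residual - fit(residual)


def normalize_intensity(
    table: pd.DataFrame, params: ScreenParams | None = None
) -> pd.DataFrame:
    """Add an ``intensity_corrected`` column: plate-mean centering, then
    local-regression corrections against mean cell area and cell count."""
    params = params or ScreenParams()
    out = table.copy()
    centered = out.groupby("plate")["mean_marker_intensity"].transform(
        lambda s: s - s.mean()
    )
    corrected = centered.to_numpy(dtype=float)
    for covariate in ("mean_cell_area", "cell_count"):
        corrected = loess_correct(
            corrected,
            out[covariate].to_numpy(dtype=float),
            span=params.loess_span,
            iterations=params.loess_iterations,
            min_points=params.min_loess_points,
        )
    out["intensity_corrected"] = corrected
    return out


def define_background_population(
    table: pd.DataFrame, plate: str, params: ScreenParams | None = None
) -> BackgroundPopulation:
    """The plate's background population: rows whose corrected marker
    intensity lies within 1.5 SD of the plate mean; per-metric mean/SD over
    those members."""
    params = params or ScreenParams()
    sub = table.loc[table["plate"] == plate]
    if "intensity_corrected" not in sub.columns:
        raise ValueError("run normalize_intensity first")
    vals = sub["intensity_corrected"].to_numpy(dtype=float)
    mean, sd = vals.mean(), vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        members = sub
    else:
        members = sub.loc[np.abs(vals - mean) <= params.bp_intensity_sd * sd]
    if len(members) < 3:
        raise ValueError(f"plate {plate!r}: fewer than 3 background members")
    bp_mean, bp_sd = {}, {}
    for m in METRICS:
        mv = members[m].to_numpy(dtype=float)
        bp_mean[m] = float(mv.mean())
        bp_sd[m] = float(mv.std(ddof=1))
        if bp_sd[m] == 0:
            raise ValueError(f"plate {plate!r}: zero background SD for {m}")
    return BackgroundPopulation(
        plate=plate, member_index=members.index, bp_mean=bp_mean, bp_sd=bp_sd
    )


def compute_zscores(
    table: pd.DataFrame,
    bps: dict[str, BackgroundPopulation],
    params: ScreenParams | None = None,
) -> pd.DataFrame:
    """Per-field Z scores per metric from each plate's background population,
    then local-regression corrections against well order and cell count."""
    params = params or ScreenParams()
    out = table.copy()
    for m in METRICS:
        z = np.full(len(out), np.nan)
        plates = out["plate"].to_numpy()
        vals = out[m].to_numpy(dtype=float)
        for plate, bp in bps.items():
            sel = plates == plate
            z[sel] = (vals[sel] - bp.bp_mean[m]) / bp.bp_sd[m]
        out[_ZCOL[m]] = z
    for covariate in ("well_order", "cell_count"):
        cov = out[covariate].to_numpy(dtype=float)
        for m in METRICS:
            out[_ZCOL[m]] = loess_correct(
                out[_ZCOL[m]].to_numpy(dtype=float),
                cov,
                span=params.loess_span,
                iterations=params.loess_iterations,
                min_points=params.min_loess_points,
            )
    return out


def _signed_max_abs(values: pd.Series) -> float:
    arr = values.to_numpy(dtype=float)
    return float(arr[np.argmax(np.abs(arr))])


def aggregate_per_sample(zscored: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-field Z to one row per sample (plate, well, mutant):
    per metric, the field value of maximal absolute value, sign retained."""
    agg = (
        zscored.groupby(["plate", "well", "mutant"], sort=False)
        .agg(
            {_ZCOL[m]: _signed_max_abs for m in METRICS}
            | {"cell_count": "mean", "is_control": "first"}
        )
        .reset_index()
    )
    return agg.rename(columns={_ZCOL[m]: f"z_{s}" for m, s in zip(METRICS, ("peripheral", "profile", "gaps"))})


_AGG_Z = {"peripheral_er_size": "z_peripheral", "er_profile_size": "z_profile",
          "er_gaps_per_um": "z_gaps"}


def call_hits(records: pd.DataFrame, params: ScreenParams | None = None) -> pd.DataFrame:
    """Flag metrics passing their directional threshold (strict inequality)
    and call a hit when at least two of the three metrics are flagged."""
    params = params or ScreenParams()
    out = records.copy()
    n_flags = np.zeros(len(out), dtype=int)
    for m in METRICS:
        col = _AGG_Z[m]
        z = out[col].to_numpy(dtype=float)
        if HIT_DIRECTION[m] < 0:
            flag = z < -params.hit_threshold
        else:
            flag = z > params.hit_threshold
        out[f"hit_{col}"] = flag
        n_flags += flag.astype(int)
    out["n_flags"] = n_flags
    out["is_hit"] = n_flags >= params.min_metrics_for_hit
    return out


class ERExpansionScreen:
    """Screen-scoring model over a per-field measurement table.

    Parameters
    ----------
    table : DataFrame
        One row per (plate, well, field) with columns ``plate``, ``well``,
        ``well_order``, ``field``, ``mutant``, ``is_control``, ``cell_count``,
        ``mean_cell_area``, ``mean_marker_intensity`` and the three metrics.
    params : ScreenParams, optional
    """

    REQUIRED = (
        "plate",
        "well",
        "well_order",
        "field",
        "mutant",
        "cell_count",
        "mean_cell_area",
        "mean_marker_intensity",
        *METRICS,
    )

    def __init__(self, table: pd.DataFrame, params: ScreenParams | None = None):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks required columns: {missing}")
        if table.duplicated(subset=["plate", "well", "field"]).any():
            raise ValueError("(plate, well, field) rows must be unique")
        self.table = table.copy()
        if "is_control" not in self.table.columns:
            self.table["is_control"] = False
        self.params = params or ScreenParams()

    @classmethod
    def from_csv(cls, path, params: ScreenParams | None = None) -> "ERExpansionScreen":
        return cls(pd.read_csv(path), params=params)

    def fit(self) -> "ScreenResults":
        p = self.params
        work = self.table.loc[self.table["cell_count"] >= p.min_cell_count]
        n_dropped = len(self.table) - len(work)
        work = normalize_intensity(work, p)
        bps = {
            plate: define_background_population(work, plate, p)
            for plate in work["plate"].unique()
        }
        zscored = compute_zscores(work, bps, p)
        aggregated = aggregate_per_sample(zscored)
        hits = call_hits(aggregated, p)
        return ScreenResults(
            model=self,
            zscored=zscored,
            records=hits,
            background_populations=bps,
            n_low_count_dropped=n_dropped,
        )


@dataclass
class ScreenResults:
    """Fitted screen scores: per-field Z table, per-sample records, hits."""

    model: ERExpansionScreen
    zscored: pd.DataFrame
    records: pd.DataFrame
    background_populations: dict[str, BackgroundPopulation] = field(repr=False)
    n_low_count_dropped: int = 0

    @property
    def hits(self) -> pd.DataFrame:
        return self.records.loc[self.records["is_hit"]]

    @property
    def hit_rate(self) -> float:
        mutants = self.records.loc[~self.records["is_control"].astype(bool)]
        return float(mutants["is_hit"].mean()) if len(mutants) else float("nan")

    def summary(self) -> str:
        rec = self.records
        lines = [
            "ER expansion screen scoring",
            "=" * 44,
            f"plates:            {rec['plate'].nunique()}",
            f"samples scored:    {len(rec)}",
            f"fields scored:     {len(self.zscored)}",
            f"low-count dropped: {self.n_low_count_dropped}",
            f"hits called:       {int(rec['is_hit'].sum())} "
            f"({100 * self.hit_rate:.2f}% of mutants)",
            "",
            "aggregated Z per metric (mean / SD):",
        ]
        for col in ("z_peripheral", "z_profile", "z_gaps"):
            z = rec[col].to_numpy(dtype=float)
            lines.append(f"  {col:<13} {z.mean():+7.3f} / {z.std(ddof=1):.3f}")
        return "\n".join(lines)
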