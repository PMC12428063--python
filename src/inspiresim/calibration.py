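"""Lethal-threshold calibration and the study's group statistics.

The lethal electric-field threshold of a measured ablation is the field
level whose simulated volume-above-field equals the measured volume: the
volume-vs-E_set curve (200-2000 V/cm in 10 V/cm steps by default) is
strictly monotone, so matching is a 1-D inversion, done either by
monotone linear interpolation (default) or by nearest grid point
(mirroring the raw 10 V/cm grid resolution).

Also here: Welch's unequal-variance t-test (raw samples or summary
statistics), ordinary least squares for the treatment-time trend, and
per-group summaries.  The test statistics are computed from the textbook
formulas directly; the test suite cross-checks them against scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
import scipy.stats

from . import _integrate
from .electro import FieldSolution, field_volume_curve

__all__ = ["VolumeFieldCurve", "ThresholdMatch", "AblationMeasurement",
           "calibrate_threshold", "predict_ablation", "TestResult",
           "welch_t_test", "welch_t_test_from_stats", "linear_trend",
           "group_summary", "DEFAULT_E_GRID"]

#: Field-level grid for volume-vs-field curves: 200-2000 V/cm, 10 V/cm steps.
DEFAULT_E_GRID = np.arange(200.0, 2000.0 + 1e-9, 10.0)


@dataclass
class VolumeFieldCurve:
    """Simulated tissue volume above each field level for one geometry.

    ``e_grid`` (V/cm) is strictly increasing; ``volumes`` (cm^3) are
    non-increasing along it.  ``provenance`` records geometry, voltage and
    conductivity mode for traceability.
    """

    e_grid: np.ndarray
    volumes: np.ndarray
    provenance: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.e_grid = np.asarray(self.e_grid, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.e_grid.ndim != 1 or self.e_grid.shape != self.volumes.shape:
            raise ValueError("e_grid and volumes must be matching 1-D arrays")
        if not (np.diff(self.e_grid) > 0).all():
            raise ValueError("e_grid must be strictly increasing")
        if (np.diff(self.volumes) > 1e-9).any():
            raise ValueError("volumes must be non-increasing along the grid")

    @classmethod
    def from_field(cls, field: FieldSolution,
                   e_grid: np.ndarray | None = None,
                   method: str = "interpolated") -> "VolumeFieldCurve":
        grid = DEFAULT_E_GRID if e_grid is None else np.asarray(e_grid, float)
        vols = field_volume_curve(field, grid, method=method)
        vols = np.minimum.accumulate(vols)  # clip interpolation noise
        prov = {"applied_voltage": field.applied_voltage, "method": method,
                "n_triangles": field.mesh.n_triangles}
        if field.mesh.geometry is not None:
            prov["exposure_cm"] = field.mesh.geometry.applicator.exposure_length
        return cls(grid, vols, prov)

    def volume_at(self, e_set: float) -> float:
        return float(np.interp(e_set, self.e_grid, self.volumes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"e_set_V_per_cm": self.e_grid,
                             "volume_cm3": self.volumes})


@dataclass(frozen=True)
class ThresholdMatch:
    """A calibrated lethal threshold (V/cm) with an out-of-range flag.

    When the measured volume lies outside the curve's range the nearest
    grid endpoint is reported and ``out_of_range`` is set.
    """

    threshold: float
    out_of_range: bool = False
    mode: str = "interpolated"

    def __float__(self) -> float:
        return float(self.threshold)


def calibrate_threshold(curve: VolumeFieldCurve, measured_volume: float,
                        mode: str = "interpolated") -> ThresholdMatch:
    """Field level whose simulated volume equals the measured volume."""
    if not measured_volume > 0:
        raise ValueError("measured_volume > 0")
    v = curve.volumes
    e = curve.e_grid
    if measured_volume > v[0]:
        return ThresholdMatch(float(e[0]), True, mode)
    if measured_volume < v[-1]:
        return ThresholdMatch(float(e[-1]), True, mode)
    if mode == "interpolated":
        # volumes are non-increasing; np.interp needs ascending x
        thr = float(np.interp(-measured_volume, -v, e))
    elif mode == "grid-nearest":
        thr = float(e[np.argmin(np.abs(v - measured_volume))])
    else:
        raise ValueError("mode must be 'interpolated' or 'grid-nearest'")
    return ThresholdMatch(thr, False, mode)


@dataclass(frozen=True)
class AblationMeasurement:
    """Volume and axial/transverse extents of one ablation zone (cm, cm^3).

    ``length`` is the axial extent, ``width``/``width2`` the transverse
    diameters; length/width is the elongation (1 = spherical).
    """

    volume_cm3: float
    length_cm: float
    width_cm: float
    width2_cm: float | None = None
    group: float | str | None = None
    replicate: int | None = None
    empty: bool = False

    @property
    def length_width_ratio(self) -> float:
        return self.length_cm / self.width_cm if self.width_cm else np.nan


def predict_ablation(field: FieldSolution, threshold: float,
                     group=None) -> AblationMeasurement:
    """Predicted ablation zone: the iso-region where |E| >= threshold."""
    if not threshold > 0:
        raise ValueError("threshold > 0")
    m = field.mesh
    nodal = field.nodal_e_magnitude
    ext = _integrate.superlevel_extent(m.points, m.edges, nodal, threshold)
    if ext is None:
        return AblationMeasurement(0.0, 0.0, 0.0, 0.0, group=group, empty=True)
    zmin, zmax, rmax = ext
    vol = float(_integrate.superlevel_volumes(
        m.points, m.triangles, nodal, [threshold])[0])
    return AblationMeasurement(volume_cm3=vol, length_cm=zmax - zmin,
                               width_cm=2.0 * rmax, width2_cm=2.0 * rmax,
                               group=group)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    """Statistic container for Welch tests (t, df, p) and OLS trends
    (slope, intercept, r_squared)."""

    statistic: float | None = None
    df: float | None = None
    p_value: float | None = None
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    undefined: bool = False


def welch_t_test_from_stats(mean1: float, sd1: float, n1: int,
                            mean2: float, sd2: float, n2: int) -> TestResult:
    """Two-tailed Welch t-test from summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite
    degrees of freedom; p from the t distribution.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    if v1 + v2 == 0:
        return TestResult(undefined=True)
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(p))


def welch_t_test(group_a, group_b) -> TestResult:
    """Two-tailed Welch t-test on raw samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    return welch_t_test_from_stats(a.mean(), a.std(ddof=1), len(a),
                                   b.mean(), b.std(ddof=1), len(b))


def linear_trend(x, y) -> TestResult:
    """OLS fit y = slope * x + intercept with the coefficient of
    determination R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("n >= 3 required for a trend")
    if np.allclose(x, x[0]):
        return TestResult(undefined=True)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = ((y - slope * x - intercept) ** 2).sum()
    ss_tot = ((y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TestResult(slope=float(slope), intercept=float(intercept),
                      r_squared=float(r2))


def group_summary(measurements: pd.DataFrame,
                  group_col: str = "group_cm",
                  value_cols: tuple[str, ...] = ("volume_cm3", "time_s")
                  ) -> pd.DataFrame:
    """Per-group n, mean and sample SD for each value column."""
    if measurements.empty:
        raise ValueError("empty measurement table")
    g = measurements.groupby(group_col)
    out = {"n": g.size()}
    for col in value_cols:
        if col in measurements:
            out[f"{col}_mean"] = g[col].mean()
            out[f"{col}_sd"] = g[col].std(ddof=1).fillna(0.0)
    return pd.DataFrame(out).reset_index()
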