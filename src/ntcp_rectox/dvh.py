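"""Dose-volume histogram construction, EQD2 correction and dosimetric indices.

Rectal dose distributions are represented either as per-voxel dose samples
(:class:`DoseSample`) or as cumulative dose-volume histograms
(:class:`DVHCurve`, volume fraction receiving at least each dose level).
Physical doses are converted to the equivalent dose in 2-Gy fractions
(EQD2) under the linear-quadratic model before any NTCP modeling, using a
voxel-by-voxel correction; the conventional bin-by-bin DVH correction is
available as :func:`eqd2_convert_dvh`.

Dosimetric indices follow the standard planning conventions:

* ``D_X%`` — the lowest dose received by the hottest X% of the organ volume;
* ``V_DGy`` — the fraction of organ volume receiving at least D Gy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DVHParseError",
    "DoseSample",
    "DVHCurve",
    "FractionationScheme",
    "DoseIndexSpec",
    "eqd2_convert",
    "eqd2_convert_dvh",
    "build_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "dose_index",
    "read_dvh_csv",
    "write_dvh_csv",
]


class ConfigurationError(ValueError):
    """Invalid configuration value; the message names the offending field."""


class DVHParseError(ValueError):
    """A DVH CSV file violates the format or the curve invariants."""


@dataclass(frozen=True)
class DoseSample:
    """Per-voxel physical (or EQD2-corrected) doses for one patient's rectum.

    Voxel volumes are relative; if omitted, voxels are uniform.  Volumes are
    normalized to sum to one.
    """

    patient_id: str
    voxel_doses: np.ndarray
    voxel_volumes: np.ndarray | None = None

    def __post_init__(self) -> None:
        doses = np.asarray(self.voxel_doses, dtype=float)
        if doses.ndim != 1 or doses.size == 0:
            raise ConfigurationError("voxel_doses: must be a nonempty 1-D array")
        if np.any(doses < 0) or not np.all(np.isfinite(doses)):
            raise ConfigurationError("voxel_doses: doses must be finite and >= 0")
        object.__setattr__(self, "voxel_doses", doses)
        if self.voxel_volumes is None:
            vols = np.full(doses.size, 1.0 / doses.size)
        else:
            vols = np.asarray(self.voxel_volumes, dtype=float)
            if vols.shape != doses.shape:
                raise ConfigurationError("voxel_volumes: shape mismatch with voxel_doses")
            if np.any(vols < 0) or vols.sum() <= 0:
                raise ConfigurationError("voxel_volumes: must be >= 0 with positive total")
            vols = vols / vols.sum()
        object.__setattr__(self, "voxel_volumes", vols)

    @property
    def mean_dose(self) -> float:
        return float(np.dot(self.voxel_volumes, self.voxel_doses))

    @property
    def max_dose(self) -> float:
        return float(self.voxel_doses.max())


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: fraction of volume receiving >= each grid dose."""

    patient_id: str
    dose_grid: np.ndarray
    cum_volume: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.dose_grid, dtype=float)
        cum = np.asarray(self.cum_volume, dtype=float)
        if grid.ndim != 1 or grid.size == 0 or grid.shape != cum.shape:
            raise DVHParseError("dose_grid and cum_volume must be matching nonempty 1-D arrays")
        if np.any(np.diff(grid) <= 0):
            raise DVHParseError("dose_grid must be strictly increasing")
        if np.any(grid < 0):
            raise DVHParseError("dose_grid must be non-negative")
        if np.any(np.diff(cum) > 1e-12):
            raise DVHParseError("cum_volume must be monotone non-increasing")
        if abs(cum[0] - 1.0) > 1e-9 or np.any(cum < -1e-12) or np.any(cum > 1 + 1e-12):
            raise DVHParseError("cum_volume must start at 1 and lie in [0, 1]")
        object.__setattr__(self, "dose_grid", grid)
        object.__setattr__(self, "cum_volume", np.clip(cum, 0.0, 1.0))


@dataclass(frozen=True)
class FractionationScheme:
    """Fractionation for EQD2 conversion.

    Study defaults: total dose delivered in 43 fractions, rectal
    alpha/beta = 3 Gy.
    """

    n_fractions: int = 43
    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ConfigurationError("n_fractions: must be >= 1")
        if not self.alpha_beta > 0:
            raise ConfigurationError("alpha_beta: must be > 0")


_INDEX_RE = re.compile(r"^(?:D(?P<x>\d+(?:\.\d+)?)%|V(?P<d>\d+(?:\.\d+)?)Gy)$", re.IGNORECASE)


@dataclass(frozen=True)
class DoseIndexSpec:
    """A dosimetric index: ``D_at_volume`` (D_X%) or ``V_at_dose`` (V_DGy)."""

    kind: str
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in ("D_at_volume", "V_at_dose"):
            raise ConfigurationError(f"kind: unknown index kind {self.kind!r}")
        if self.kind == "D_at_volume" and not (0 < self.threshold < 100):
            raise ConfigurationError("threshold: X% must be in (0, 100)")
        if self.kind == "V_at_dose" and self.threshold < 0:
            raise ConfigurationError("threshold: dose must be >= 0")

    @classmethod
    def parse(cls, name: str) -> "DoseIndexSpec":
        """Parse ``'D25%'`` or ``'V50Gy'`` style names."""
        m = _INDEX_RE.match(name.strip())
        if m is None:
            raise ConfigurationError(f"index: cannot parse dosimetric index {name!r}")
        if m.group("x") is not None:
            return cls("D_at_volume", float(m.group("x")))
        return cls("V_at_dose", float(m.group("d")))

    @property
    def name(self) -> str:
        t = self.threshold
        s = f"{t:g}"
        return f"D{s}%" if self.kind == "D_at_volume" else f"V{s}Gy"


# ---------------------------------------------------------------------------
# EQD2 conversion
# ---------------------------------------------------------------------------

def eqd2_factorless(total_dose: np.ndarray, scheme: FractionationScheme) -> np.ndarray:
    """EQD2 of a total dose delivered in ``scheme.n_fractions`` fractions.

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta) with d = D / n_fractions.
    """
    d = np.asarray(total_dose, dtype=float)
    per_fraction = d / scheme.n_fractions
    return d * (per_fraction + scheme.alpha_beta) / (2.0 + scheme.alpha_beta)


def eqd2_convert(doses: DoseSample, scheme: FractionationScheme) -> DoseSample:
    """Voxel-by-voxel EQD2 correction; voxel order and volumes preserved."""
    return replace(doses, voxel_doses=eqd2_factorless(doses.voxel_doses, scheme))


def eqd2_convert_dvh(dvh: DVHCurve, scheme: FractionationScheme) -> DVHCurve:
    """Bin-by-bin EQD2 correction: maps the dose grid of an existing curve.

    The EQD2 map is strictly increasing in dose, so the corrected grid stays
    strictly increasing and the cumulative volumes are unchanged.
    """
    return replace(dvh, dose_grid=eqd2_factorless(dvh.dose_grid, scheme))


# ---------------------------------------------------------------------------
# DVH construction and index extraction
# ---------------------------------------------------------------------------

def build_dvh(doses: DoseSample, bin_width: float = 0.1) -> DVHCurve:
    """Build a cumulative DVH on a uniform grid from 0 to max dose + one bin.

    ``cum_volume(d)`` is the volume fraction of voxels with dose >= d,
    evaluated exactly at each grid point.
    """
    if not bin_width > 0:
        raise ConfigurationError("bin_width: must be > 0")
    dmax = doses.voxel_doses.max()
    n_bins = int(np.ceil(dmax / bin_width)) + 1
    grid = np.arange(n_bins + 1) * bin_width
    order = np.argsort(doses.voxel_doses)
    sorted_doses = doses.voxel_doses[order]
    below = np.cumsum(doses.voxel_volumes[order])
    # volume strictly below d, via searchsorted on sorted voxel doses
    idx = np.searchsorted(sorted_doses, grid, side="left")
    vol_below = np.concatenate([[0.0], below])[idx]
    cum = 1.0 - vol_below
    cum[0] = 1.0
    return DVHCurve(doses.patient_id, grid, cum)


def dose_at_volume(dvh: DVHCurve, x_percent: float) -> float:
    """D_X%: the lowest dose received by the hottest ``x_percent`` of volume.

    Linear interpolation on the cumulative curve; on flat segments the
    highest dose attaining the volume fraction is returned.
    """
    if not (0 < x_percent < 100):
        raise ConfigurationError("x_percent: must be in (0, 100)")
    target = x_percent / 100.0
    grid, cum = dvh.dose_grid, dvh.cum_volume
    # rightmost index with cum >= target (cum non-increasing, cum[0] = 1)
    ge = np.nonzero(cum >= target)[0]
    i = ge[-1]
    if i == grid.size - 1 or cum[i] == target:
        return float(grid[i])
    # interpolate on the strictly decreasing segment [i, i+1]
    c0, c1 = cum[i], cum[i + 1]
    frac = (c0 - target) / (c0 - c1)
    return float(grid[i] + frac * (grid[i + 1] - grid[i]))


def volume_at_dose(dvh: DVHCurve, d_gy: float) -> float:
    """V_D: interpolated volume fraction receiving at least ``d_gy``."""
    if d_gy < 0:
        raise ConfigurationError("d_gy: must be >= 0")
    if d_gy >= dvh.dose_grid[-1]:
        return float(dvh.cum_volume[-1]) if d_gy == dvh.dose_grid[-1] else 0.0
    return float(np.interp(d_gy, dvh.dose_grid, dvh.cum_volume))


def _dose_at_volume_raw(doses: DoseSample, x_percent: float) -> float:
    # order statistic: smallest dose within the hottest x% of volume
    order = np.argsort(doses.voxel_doses)[::-1]
    hot_vol = np.cumsum(doses.voxel_volumes[order])
    k = int(np.searchsorted(hot_vol, x_percent / 100.0 - 1e-12, side="left"))
    k = min(k, doses.voxel_doses.size - 1)
    return float(doses.voxel_doses[order][k])


def _volume_at_dose_raw(doses: DoseSample, d_gy: float) -> float:
    return float(doses.voxel_volumes[doses.voxel_doses >= d_gy].sum())


def dose_index(data: DoseSample | DVHCurve, spec: DoseIndexSpec) -> float:
    """Evaluate a dosimetric index on voxel samples (exact order statistic)
    or on a DVH curve (interpolated)."""
    if isinstance(data, DoseSample):
        if spec.kind == "D_at_volume":
            return _dose_at_volume_raw(data, spec.threshold)
        return _volume_at_dose_raw(data, spec.threshold)
    if spec.kind == "D_at_volume":
        return dose_at_volume(data, spec.threshold)
    return volume_at_dose(data, spec.threshold)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_DVH_COLUMNS = ["dose_gy", "cum_volume_fraction"]


def write_dvh_csv(dvh: DVHCurve, path) -> None:
    pd.DataFrame(
        {"dose_gy": dvh.dose_grid, "cum_volume_fraction": dvh.cum_volume}
    ).to_csv(path, index=False, float_format="%.10g")


def read_dvh_csv(path, patient_id: str | None = None) -> DVHCurve:
    """Read a cumulative DVH from CSV with header ``dose_gy,cum_volume_fraction``.

    Invariant violations are rejected with the offending data row number
    (1-based, excluding the header).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DVHParseError("no data rows") from None
    if list(df.columns) != _DVH_COLUMNS:
        raise DVHParseError(
            f"expected header {','.join(_DVH_COLUMNS)!r}, got {','.join(map(str, df.columns))!r}"
        )
    if len(df) == 0:
        raise DVHParseError("no data rows")
    dose = df["dose_gy"].to_numpy(float)
    cum = df["cum_volume_fraction"].to_numpy(float)
    for row in range(len(df)):
        if not np.isfinite(dose[row]) or dose[row] < 0:
            raise DVHParseError(f"row {row + 1}: negative or invalid dose")
        if row > 0 and dose[row] <= dose[row - 1]:
            raise DVHParseError(f"row {row + 1}: dose_gy not strictly increasing")
        if row > 0 and cum[row] > cum[row - 1] + 1e-12:
            raise DVHParseError(f"row {row + 1}: cum_volume_fraction increases")
    pid = patient_id if patient_id is not None else str(path)
    try:
        return DVHCurve(pid, dose, cum)
    except DVHParseError as exc:
        raise DVHParseError(str(exc)) from None
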