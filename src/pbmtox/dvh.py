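"""Dose-volume histogram containers, conversions, V-metrics and CSV I/O.

A differential DVH stores, per structure, the fraction of structure volume
``v_i`` falling in each 0.1 Gy dose bin ``d_i`` (bins labelled by their
representative dose, uniform 0.1 Gy width).  The cumulative form stores the
fraction of volume receiving at least each dose.  V-metrics (V5..V25, the
percent volume receiving >= 5..25 Gy) are the cohort-comparison quantities
for pelvic bone marrow and its sub-structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: uniform dose-bin width in Gy
BIN_WIDTH = 0.1

#: structure labels for pelvic bone marrow and its sub-structures
STRUCTURES = ("whole_pelvis", "iliac", "lumbosacral", "lower_pelvis")

#: default V-metric threshold levels in Gy
DEFAULT_LEVELS = (5.0, 10.0, 15.0, 20.0, 25.0)

_SUM_TOL = 1e-6


class DVHParseError(ValueError):
    """Raised for malformed DVH CSV input; message includes file line numbers."""


def _snap_index(dose: float, bin_width: float = BIN_WIDTH) -> int:
    return int(round(float(dose) / bin_width))


@dataclass(frozen=True, eq=False)
class DVH:
    """Differential dose-volume histogram on a uniform 0.1 Gy bin grid.

    Parameters
    ----------
    bin_doses : array-like
        Ascending, uniformly spaced (0.1 Gy) bin doses in Gy.
    volume_fraction : array-like
        Fraction of structure volume in each bin; non-negative, summing to 1
        (within 1e-6) for a complete structure.
    total_volume_ccm : float
        Absolute structure volume in cm^3 (metadata; relative volumes are
        primary).
    structure : str
        Structure label; one of :data:`STRUCTURES` or ``"other"``.
    """

    bin_doses: np.ndarray
    volume_fraction: np.ndarray
    total_volume_ccm: float = 1.0
    structure: str = "other"

    def __post_init__(self) -> None:
        bd = np.atleast_1d(np.asarray(self.bin_doses, dtype=float))
        vf = np.atleast_1d(np.asarray(self.volume_fraction, dtype=float))
        object.__setattr__(self, "bin_doses", bd)
        object.__setattr__(self, "volume_fraction", vf)
        if bd.ndim != 1 or bd.shape != vf.shape or bd.size == 0:
            raise ValueError("bin_doses and volume_fraction must be equal-length 1-D arrays")
        if bd.size > 1 and not np.allclose(np.diff(bd), BIN_WIDTH, atol=1e-9):
            raise ValueError(f"bin grid must be uniform with width {BIN_WIDTH} Gy")
        if np.any(bd < -1e-12):
            raise ValueError("bin doses must be non-negative")
        if np.any(vf < -1e-12):
            raise ValueError("volume fractions must be non-negative")
        if abs(vf.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"volume fractions must sum to 1 for a complete structure (got {vf.sum():.8f})"
            )
        if not self.total_volume_ccm > 0:
            raise ValueError("total_volume_ccm must be positive")

    @classmethod
    def from_points(
        cls,
        points: Mapping[float, float],
        total_volume_ccm: float = 1.0,
        structure: str = "other",
    ) -> "DVH":
        """Build a dense-grid DVH from ``{dose: fraction}`` point masses.

        Doses are snapped to the 0.1 Gy grid (mass-preserving reassignment);
        fractions at coinciding bins are aggregated.
        """
        doses = np.asarray(list(points.keys()), dtype=float)
        fracs = np.asarray(list(points.values()), dtype=float)
        return cls._from_mass(doses, fracs, total_volume_ccm, structure)

    @classmethod
    def _from_mass(cls, doses, fracs, total_volume_ccm=1.0, structure="other") -> "DVH":
        doses = np.asarray(doses, dtype=float)
        fracs = np.asarray(fracs, dtype=float)
        idx = np.round(doses / BIN_WIDTH).astype(int)
        if np.any(idx < 0):
            raise ValueError("doses must be non-negative")
        lo, hi = int(idx.min()), int(idx.max())
        grid = np.round(np.arange(lo, hi + 1) * BIN_WIDTH, 10)
        vf = np.zeros(hi - lo + 1)
        np.add.at(vf, idx - lo, fracs)
        return cls(grid, vf, total_volume_ccm, structure)

    @property
    def mean_dose(self) -> float:
        """Volume-weighted mean dose in Gy."""
        return float(np.dot(self.bin_doses, self.volume_fraction))

    def scale_doses(self, factor: float) -> "DVH":
        """Return the DVH with all bin doses scaled by ``factor`` (> 0), re-snapped
        to the 0.1 Gy grid mass-preservingly (used to split a plan into phases)."""
        if not factor > 0:
            raise ValueError("factor must be positive")
        return DVH._from_mass(
            self.bin_doses * factor, self.volume_fraction, self.total_volume_ccm, self.structure
        )

    def allclose(self, other: "DVH", atol: float = 1e-9) -> bool:
        """Grid-aware comparison: equal mass per 0.1 Gy bin within ``atol``."""
        lo = min(_snap_index(self.bin_doses[0]), _snap_index(other.bin_doses[0]))
        hi = max(_snap_index(self.bin_doses[-1]), _snap_index(other.bin_doses[-1]))

        def dense(d: "DVH") -> np.ndarray:
            out = np.zeros(hi - lo + 1)
            i0 = _snap_index(d.bin_doses[0])
            out[i0 - lo : i0 - lo + d.volume_fraction.size] = d.volume_fraction
            return out

        return bool(np.allclose(dense(self), dense(other), atol=atol))


@dataclass(frozen=True, eq=False)
class CumulativeDVH:
    """Cumulative DVH: fraction of volume receiving at least each grid dose.

    The grid need not be uniform; values are non-increasing in dose and lie
    in [0, 1].
    """

    dose_grid: np.ndarray
    fraction_at_or_above: np.ndarray

    def __post_init__(self) -> None:
        dg = np.atleast_1d(np.asarray(self.dose_grid, dtype=float))
        fr = np.atleast_1d(np.asarray(self.fraction_at_or_above, dtype=float))
        object.__setattr__(self, "dose_grid", dg)
        object.__setattr__(self, "fraction_at_or_above", fr)
        if dg.shape != fr.shape or dg.ndim != 1 or dg.size == 0:
            raise ValueError("dose_grid and fraction_at_or_above must be equal-length 1-D arrays")
        if dg.size > 1 and np.any(np.diff(dg) <= 0):
            raise ValueError("dose_grid must be strictly ascending")
        if np.any(np.diff(fr) > 1e-9):
            raise ValueError("fraction_at_or_above must be non-increasing")
        if np.any(fr < -1e-12) or np.any(fr > 1 + 1e-9):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class DoseMetrics:
    """V5..V25 in percent volume, plus absolute structure volume in cm^3."""

    v5: float
    v10: float
    v15: float
    v20: float
    v25: float
    volume_ccm: float

    def __post_init__(self) -> None:
        vals = [self.v5, self.v10, self.v15, self.v20, self.v25]
        if any(not (-1e-9 <= v <= 100 + 1e-9) for v in vals):
            raise ValueError("V-metrics must lie in [0, 100]")
        if np.any(np.diff(vals) > 1e-9):
            raise ValueError("V-metrics must be non-increasing in threshold")

    def as_dict(self) -> dict:
        return {
            "v5": self.v5,
            "v10": self.v10,
            "v15": self.v15,
            "v20": self.v20,
            "v25": self.v25,
            "volume_ccm": self.volume_ccm,
        }


def cumulative_from_differential(d: DVH) -> CumulativeDVH:
    """Reverse cumulative sum of the differential form (same grid)."""
    fr = d.volume_fraction[::-1].cumsum()[::-1]
    return CumulativeDVH(d.bin_doses, np.minimum(fr, 1.0))


def differential_from_cumulative(
    c: CumulativeDVH,
    bin_width: float = BIN_WIDTH,
    total_volume_ccm: float = 1.0,
    structure: str = "other",
) -> DVH:
    """Adjacent differences of the cumulative form, snapped to the uniform grid.

    The mass dropped between grid doses ``d_k`` and ``d_{k+1}`` is assigned to
    ``d_k`` (counts-at-or-above convention); the residual at the last grid
    point stays there.  Fractions sum to the cumulative form's first value.
    """
    if abs(bin_width - BIN_WIDTH) > 1e-12:
        raise ValueError(f"only the canonical bin width {BIN_WIDTH} Gy is supported")
    fr = c.fraction_at_or_above
    if abs(fr[0] - 1.0) > _SUM_TOL:
        raise ValueError(
            f"cumulative DVH is incomplete (first value {fr[0]:.6f}, expected 1)"
        )
    mass = np.empty_like(fr)
    mass[:-1] = fr[:-1] - fr[1:]
    mass[-1] = fr[-1]
    d = DVH._from_mass(c.dose_grid, mass, total_volume_ccm, structure)
    if abs(d.volume_fraction.sum() - fr[0]) > _SUM_TOL:
        raise ValueError("mass not conserved during rebinning")
    return d


def v_at(d: DVH, threshold: float) -> float:
    """Percent of volume receiving at least ``threshold`` Gy.

    Counts whole bins whose representative dose is >= threshold (inclusive);
    at 0.1 Gy resolution this differs from interpolated evaluation by at most
    one bin.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    sel = d.bin_doses >= threshold - 1e-9
    return float(np.clip(100.0 * d.volume_fraction[sel].sum(), 0.0, 100.0))


def dose_metrics(d: DVH, levels=DEFAULT_LEVELS) -> DoseMetrics:
    """V-metrics at the standard 5..25 Gy levels plus absolute volume."""
    vals = [v_at(d, t) for t in levels]
    return DoseMetrics(*vals, volume_ccm=d.total_volume_ccm)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Long format, UTF-8, comma-separated, header required:
#   [patient_id,] structure, kind, dose_gy, volume_fraction [or volume_ccm]
# kind is "differential" or "cumulative"; one file may hold many patients and
# structures.  Cumulative inputs are converted on read.
# ---------------------------------------------------------------------------

_REQUIRED_COLS = {"structure", "kind", "dose_gy"}


def read_dvh_csv(path) -> dict:
    """Read a DVH CSV file.

    Returns ``{patient_id: {structure: DVH}}`` when a ``patient_id`` column is
    present, else ``{structure: DVH}``.
    """
    try:
        df = pd.read_csv(path, dtype={"structure": str, "kind": str})
    except Exception as exc:  # noqa: BLE001 - surface a parse error with the path
        raise DVHParseError(f"{path}: cannot read CSV ({exc})") from exc
    missing = _REQUIRED_COLS - set(df.columns)
    if missing:
        raise DVHParseError(f"{path}: missing required columns {sorted(missing)}")
    has_frac = "volume_fraction" in df.columns
    has_ccm = "volume_ccm" in df.columns
    if not (has_frac or has_ccm):
        raise DVHParseError(f"{path}: need a volume_fraction or volume_ccm column")
    vol_col = "volume_fraction" if has_frac else "volume_ccm"

    for col in ("dose_gy", vol_col):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise DVHParseError(
                f"{path}: non-numeric value in column '{col}' at line {bad[0] + 2}"
            )
        df[col] = numeric
    if df[vol_col].isna().any():
        line = int(df.index[df[vol_col].isna()][0]) + 2
        raise DVHParseError(f"{path}: empty volume cell at line {line}")

    has_pid = "patient_id" in df.columns
    keys = ["patient_id", "structure"] if has_pid else "structure"
    out: dict = {}
    for key, sub in df.groupby(keys, sort=False):
        kinds = sub["kind"].unique()
        if len(kinds) != 1 or kinds[0] not in ("differential", "cumulative"):
            raise DVHParseError(
                f"{path}: structure group {key} must have a single kind "
                "'differential' or 'cumulative'"
            )
        sub = sub.sort_values("dose_gy")
        doses = sub["dose_gy"].to_numpy(dtype=float)
        vols = sub[vol_col].to_numpy(dtype=float)
        structure = key[-1] if has_pid else key
        if has_ccm and not has_frac:
            total = vols[0] if kinds[0] == "cumulative" else vols.sum()
            if not total > 0:
                raise DVHParseError(f"{path}: structure group {key} has zero volume")
            fracs = vols / total
        else:
            total = (
                float(sub["total_volume_ccm"].iloc[0])
                if "total_volume_ccm" in sub.columns
                else 1.0
            )
            fracs = vols
        try:
            if kinds[0] == "cumulative":
                dvh = differential_from_cumulative(
                    CumulativeDVH(doses, fracs), total_volume_ccm=total, structure=structure
                )
            else:
                dvh = DVH._from_mass(doses, fracs, total, structure)
        except ValueError as exc:
            first_line = int(sub.index[0]) + 2
            raise DVHParseError(
                f"{path}: invalid DVH for group {key} (starting line {first_line}): {exc}"
            ) from exc
        if has_pid:
            out.setdefault(str(key[0]), {})[structure] = dvh
        else:
            out[structure] = dvh
    return out


def write_dvh_csv(path, dvhs: Mapping) -> None:
    """Write DVHs in differential long format (inverse of :func:`read_dvh_csv`).

    ``dvhs`` is either ``{structure: DVH}`` or ``{patient_id: {structure: DVH}}``.
    """
    nested = any(isinstance(v, Mapping) for v in dvhs.values())
    items = (
        [(pid, s, d) for pid, sub in dvhs.items() for s, d in sub.items()]
        if nested
        else [(None, s, d) for s, d in dvhs.items()]
    )
    frames = []
    for pid, structure, d in items:
        frame = pd.DataFrame(
            {
                "structure": structure,
                "kind": "differential",
                "dose_gy": np.round(d.bin_doses, 6),
                "volume_fraction": d.volume_fraction,
                "total_volume_ccm": d.total_volume_ccm,
            }
        )
        if nested:
            frame.insert(0, "patient_id", pid)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
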