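"""Core isotope arithmetic for 13C pulse-chase tracing.

A pulse of ``13CO2`` fed to source leaves raises their ``13C/12C`` ratio
far above the natural background.  Sampling every organ over the chase
lets one follow the labeled photosynthate into sink organs (branches,
fruit peels, seed kernels).  The chain of quantities is:

measured ratio ``R_s``  ->  ``delta13C`` (per mil vs. the VPDB standard
ratio ``R_c = 0.0112372``)  ->  atom percent 13C  ->  excess-13C mass
(atom percent above the unlabeled background ``F_n``, times the organ's
carbon pool)  ->  allocation percentage ``P_i`` and transport rate
``V_i``.

All scalar functions accept NumPy arrays and broadcast elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VPDB_RATIO",
    "IsotopeConstants",
    "IsotopeReading",
    "OrganPool",
    "AllocationResult",
    "delta_from_ratio",
    "ratio_from_delta",
    "atom_percent",
    "delta_from_atom_percent",
    "total_carbon",
    "excess_13c_mass",
    "allocation_ratios",
    "transport_rate",
    "allocation_table",
]

#: 13C/12C ratio of the VPDB carbonate standard.
VPDB_RATIO = 0.0112372


@dataclass(frozen=True)
class IsotopeConstants:
    """Physical constants of the delta-13C scale.

    Parameters
    ----------
    Rc : float
        13C/12C ratio of the reference standard (VPDB).  Must be > 0.
    """

    Rc: float = VPDB_RATIO

    def __post_init__(self) -> None:
        if not self.Rc > 0:
            raise ValueError(f"Rc must be positive, got {self.Rc}")


@dataclass(frozen=True)
class IsotopeReading:
    """One organ x time x month isotope measurement.

    Exactly one of ``Rs`` (raw 13C/12C ratio) or ``delta13C`` (per mil)
    must be provided; the other is derived on demand.
    """

    organ: str
    month: str
    time_h: float
    Rs: float | None = None
    delta13C: float | None = None

    def __post_init__(self) -> None:
        if (self.Rs is None) == (self.delta13C is None):
            raise ValueError(
                f"reading {self.organ}/{self.month}: exactly one of Rs and "
                "delta13C must be given"
            )
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")
        if self.Rs is not None and self.Rs < 0:
            raise ValueError(f"Rs must be >= 0, got {self.Rs}")
        if self.delta13C is not None and self.delta13C <= -1000:
            raise ValueError(f"delta13C must be > -1000 per mil, got {self.delta13C}")

    def delta(self, constants: IsotopeConstants = IsotopeConstants()) -> float:
        """delta-13C in per mil, converting from ``Rs`` if necessary."""
        if self.delta13C is not None:
            return float(self.delta13C)
        return float(delta_from_ratio(self.Rs, constants))


@dataclass(frozen=True)
class OrganPool:
    """Carbon pool of one organ in one month.

    ``biomass_g`` is organ dry mass ``W_i`` in grams, ``carbon_fraction``
    the proportion of that mass that is carbon (``C%``, 0-1), and
    ``Fn_atom_percent`` the 13C atom percent measured in unlabeled
    control plants (the natural background ``F_n``).
    """

    organ: str
    month: str
    biomass_g: float
    carbon_fraction: float
    Fn_atom_percent: float

    def __post_init__(self) -> None:
        if self.biomass_g < 0:
            raise ValueError(f"biomass_g must be >= 0, got {self.biomass_g}")
        if not 0.0 <= self.carbon_fraction <= 1.0:
            raise ValueError(
                f"carbon_fraction must be in [0, 1], got {self.carbon_fraction}"
            )
        if not 0.0 <= self.Fn_atom_percent < 100.0:
            raise ValueError(
                f"Fn_atom_percent must be in [0, 100), got {self.Fn_atom_percent}"
            )


@dataclass(frozen=True)
class AllocationResult:
    """Derived quantities for one organ in one month."""

    organ: str
    month: str
    Ci_g: float
    atom_percent: float
    excess13C_mg: float
    allocation_percent: float
    transport_rate: float  # ug g^-1 h^-1
    total13C_mg: float
    negative_excess: bool = field(default=False)


def delta_from_ratio(Rs, constants: IsotopeConstants = IsotopeConstants()):
    """Convert a raw 13C/12C ratio to delta-13C in per mil.

    ``delta13C = (Rs - Rc) / Rc * 1000``.  Strictly increasing in ``Rs``;
    equals 0 at the standard ratio and -1000 at ``Rs = 0``.
    """
    Rs = np.asarray(Rs, dtype=float)
    if np.any(Rs < 0):
        raise ValueError("Rs must be >= 0")
    out = (Rs - constants.Rc) / constants.Rc * 1000.0
    return out if out.ndim else float(out)


def ratio_from_delta(delta13C, constants: IsotopeConstants = IsotopeConstants()):
    """Invert :func:`delta_from_ratio`: ``Rs = Rc * (1 + delta/1000)``."""
    delta13C = np.asarray(delta13C, dtype=float)
    if np.any(delta13C <= -1000.0):
        raise ValueError("delta13C must be > -1000 per mil")
    out = constants.Rc * (1.0 + delta13C / 1000.0)
    return out if out.ndim else float(out)


def atom_percent(delta13C, constants: IsotopeConstants = IsotopeConstants()):
    """13C atom percent from delta-13C.

    ``Atom% = (delta + 1000) * Rc / ((delta + 1000) * Rc + 1000) * 100``

    which is the fraction of carbon atoms that are 13C, as a percentage.
    Maps ``(-1000, inf)`` monotonically into ``(0, 100)``.
    """
    delta13C = np.asarray(delta13C, dtype=float)
    if np.any(delta13C <= -1000.0):
        raise ValueError("delta13C must be > -1000 per mil")
    x = (delta13C + 1000.0) * constants.Rc
    out = x / (x + 1000.0) * 100.0
    return out if out.ndim else float(out)


def delta_from_atom_percent(ap, constants: IsotopeConstants = IsotopeConstants()):
    """Invert :func:`atom_percent` (used by the simulator).

    For atom percent ``A`` in (0, 100):
    ``delta = 1000 * A / (100 - A) / Rc - 1000``.
    """
    ap = np.asarray(ap, dtype=float)
    if np.any(ap <= 0.0) or np.any(ap >= 100.0):
        raise ValueError("atom percent must be in (0, 100)")
    x = 1000.0 * ap / (100.0 - ap)  # (delta + 1000) * Rc
    out = x / constants.Rc - 1000.0
    return out if out.ndim else float(out)


def total_carbon(pool: OrganPool) -> float:
    """Total carbon ``C_i`` of an organ in grams: ``carbon_fraction * W_i``."""
    return pool.carbon_fraction * pool.biomass_g


def excess_13c_mass(Ci_g, atom_pct, Fn):
    """Excess (above-background) 13C mass in mg.

    ``13C_i = C_i * (Atom% - F_n) / 100 * 1000`` with ``C_i`` in grams,
    so the result is in milligrams.  Negative values (atom percent below
    background, as happens late in the season when labeled carbon has
    been exported or respired) are preserved, not clamped; callers flag
    them downstream.
    """
    Ci_g = np.asarray(Ci_g, dtype=float)
    if np.any(Ci_g < 0):
        raise ValueError("Ci_g must be >= 0")
    out = Ci_g * (np.asarray(atom_pct, dtype=float) - np.asarray(Fn, dtype=float)) / 100.0 * 1000.0
    return out if out.ndim else float(out)


def allocation_ratios(excess_by_organ: Mapping[str, float]) -> dict[str, float]:
    """Allocation percentage ``P_i = 13C_i / sum_j 13C_j * 100`` per organ.

    Scale-invariant; the returned values sum to exactly 100 (up to
    floating rounding).  Raises if the month's total excess is <= 0,
    in which case no meaningful partition of the label exists.
    """
    if not excess_by_organ:
        raise ValueError("need at least one organ")
    total = float(sum(excess_by_organ.values()))
    if total <= 0:
        raise ValueError(
            "no net labeled carbon in month (total excess 13C "
            f"= {total:.6g} mg <= 0)"
        )
    return {organ: m / total * 100.0 for organ, m in excess_by_organ.items()}


def transport_rate(excess13C_mg, biomass_g, hours_since_label):
    """Transport rate ``V_i`` in ug per gram dry biomass per hour.

    ``V_i = (13C_i [ug] / W_i [g]) / H [h]``.  The per-gram convention
    honors the unit the rate is reported in; see the methods note for
    the reasoning.
    """
    biomass_g = np.asarray(biomass_g, dtype=float)
    hours = np.asarray(hours_since_label, dtype=float)
    if np.any(hours <= 0):
        raise ValueError("hours_since_label must be > 0")
    if np.any(biomass_g <= 0):
        raise ValueError("biomass_g must be > 0")
    out = np.asarray(excess13C_mg, dtype=float) * 1000.0 / biomass_g / hours
    return out if out.ndim else float(out)


def _coerce_readings(readings) -> list[IsotopeReading]:
    if isinstance(readings, pd.DataFrame):
        out = []
        for row in readings.itertuples(index=False):
            rs = getattr(row, "rs", None)
            delta = getattr(row, "delta13c", None)
            rs = None if rs is None or (isinstance(rs, float) and np.isnan(rs)) else float(rs)
            delta = None if delta is None or (isinstance(delta, float) and np.isnan(delta)) else float(delta)
            if rs is not None and delta is not None:
                # documented precedence: delta wins when both are present
                rs = None
            out.append(
                IsotopeReading(
                    organ=str(row.organ),
                    month=str(row.month),
                    time_h=float(row.time_h),
                    Rs=rs,
                    delta13C=delta,
                )
            )
        return out
    return list(readings)


def _coerce_pools(pools) -> list[OrganPool]:
    if isinstance(pools, pd.DataFrame):
        return [
            OrganPool(
                organ=str(r.organ),
                month=str(r.month),
                biomass_g=float(r.biomass_g),
                carbon_fraction=float(r.carbon_fraction),
                Fn_atom_percent=float(r.fn_atom_percent),
            )
            for r in pools.itertuples(index=False)
        ]
    return list(pools)


def allocation_table(
    readings: Iterable[IsotopeReading] | pd.DataFrame,
    pools: Iterable[OrganPool] | pd.DataFrame,
    constants: IsotopeConstants = IsotopeConstants(),
) -> pd.DataFrame:
    """Full per-organ, per-month allocation table.

    Composes the scalar operations: each reading is converted to
    delta-13C and atom percent, matched with its organ x month carbon
    pool, and turned into excess-13C mass; within each month the excess
    masses are normalized to allocation percentages and divided by the
    chase time to give transport rates.

    When an organ x month pair carries several timepoints, the latest
    one (end of the chase) is used for the monthly balance.

    Parameters
    ----------
    readings
        Sequence of :class:`IsotopeReading` or a DataFrame with columns
        ``organ, month, time_h`` and one of ``rs`` / ``delta13c``.
    pools
        Sequence of :class:`OrganPool` or a DataFrame with columns
        ``organ, month, biomass_g, carbon_fraction, fn_atom_percent``.

    Returns
    -------
    pandas.DataFrame
        One row per organ x month with columns ``organ, month, time_h,
        delta13c, atom_percent, ci_g, excess13c_mg, allocation_percent,
        transport_rate_ug_g_h, total13c_mg, negative_excess``.
        ``allocation_percent`` is NaN for months whose total excess is
        not positive (no net labeled carbon to partition).
    """
    readings = _coerce_readings(readings)
    pools = _coerce_pools(pools)
    if not readings:
        raise ValueError("no readings supplied")
    pool_map = {(p.organ, p.month): p for p in pools}

    # keep the latest timepoint per organ x month
    latest: dict[tuple[str, str], IsotopeReading] = {}
    for r in readings:
        key = (r.organ, r.month)
        if key not in latest or r.time_h > latest[key].time_h:
            latest[key] = r

    rows = []
    for (organ, month), r in latest.items():
        pool = pool_map.get((organ, month))
        if pool is None:
            raise KeyError(
                f"no organ pool for organ={organ!r}, month={month!r}"
            )
        delta = r.delta(constants)
        ap = atom_percent(delta, constants)
        ci = total_carbon(pool)
        excess = excess_13c_mass(ci, ap, pool.Fn_atom_percent)
        rows.append(
            dict(
                organ=organ,
                month=month,
                time_h=r.time_h,
                delta13c=delta,
                atom_percent=ap,
                ci_g=ci,
                excess13c_mg=excess,
                biomass_g=pool.biomass_g,
            )
        )
    df = pd.DataFrame(rows)

    df["allocation_percent"] = np.nan
    df["total13c_mg"] = np.nan
    for month, sub in df.groupby("month", sort=False):
        total = sub["excess13c_mg"].sum()
        df.loc[sub.index, "total13c_mg"] = total
        if total > 0:
            df.loc[sub.index, "allocation_percent"] = (
                sub["excess13c_mg"] / total * 100.0
            )
    df["transport_rate_ug_g_h"] = np.where(
        (df["time_h"] > 0) & (df["biomass_g"] > 0),
        df["excess13c_mg"] * 1000.0 / df["biomass_g"] / df["time_h"].where(df["time_h"] > 0),
        np.nan,
    )
    df["negative_excess"] = df["excess13c_mg"] < 0
    df = df.drop(columns=["biomass_g"])
    return df.sort_values(["month", "organ"], kind="stable").reset_index(drop=True)
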