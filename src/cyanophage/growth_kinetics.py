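"""One-step growth-curve estimators: latent period, burst size, packaged fraction.

The experimental design assumed here is a synchronized single-round
infection: phage added at high MOI to a dilute host culture, free phage in
the filtrate quantified by qPCR every few hours, each sample split into an
undigested aliquot (total phage DNA copies) and a DNase-digested aliquot
(encapsidated, DNase-protected copies only). Host cells are tracked in the
infected culture and a phage-free control.

Estimators:

* latent period — last sampling time before the first *sustained* rise of
  free phage: two consecutive points each above rise_factor × the
  post-adsorption baseline (the series minimum after the adsorption
  window).
* burst size — (mean of the plateau points − post-adsorption residual)
  divided by the number of infected cells. At MOI ≈ 2 essentially every
  host is infected (Poisson P(≥1) ≈ 0.86), so the divisor defaults to the
  initial host count.
* packaged fraction — per-time digested/undigested ratio clipped to [0, 1],
  averaged over time points whose undigested signal clears a floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, FormatError, NoBurstError, UndefinedValueError

ADSORPTION_END_H = 6.0
RISE_FACTOR = 2.0
RATIO_FLOOR = 10.0  # copies/mL below which a ratio is meaningless (0/0 guard)
PLATEAU_POINTS = 3


@dataclass(frozen=True)
class InfectionTimeSeries:
    """Aligned host and free-phage series over the course of an infection."""

    times: np.ndarray          # hours
    host_treated: np.ndarray   # cells/mL, infected culture
    host_control: np.ndarray   # cells/mL, phage-free control
    free_undigested: np.ndarray  # genome copies/mL
    free_digested: np.ndarray | None = None  # copies/mL after DNase digestion

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise ArgumentError("times must be strictly increasing, length >= 2")
        for name in ("host_treated", "host_control", "free_undigested", "free_digested"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != times.shape:
                raise ArgumentError(f"{name} is not aligned with times")
            if np.any(arr < 0) or np.any(~np.isfinite(arr)):
                raise ArgumentError(f"{name} must be finite and non-negative")

    def series(self, which: str) -> np.ndarray:
        if which == "undigested":
            return self.free_undigested
        if which == "digested":
            if self.free_digested is None:
                raise ArgumentError("series has no DNase-digested measurements")
            return self.free_digested
        raise ArgumentError("which must be 'undigested' or 'digested'")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_h": self.times,
            "host_treated": self.host_treated,
            "host_control": self.host_control,
            "free_undigested": self.free_undigested,
        }
        if self.free_digested is not None:
            data["free_digested"] = self.free_digested
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "InfectionTimeSeries":
        df = pd.read_csv(path, sep="\t")
        required = ["time_h", "host_treated", "host_control", "free_undigested"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"time-series TSV missing column(s) {missing}")
        if df.empty:
            raise FormatError("time-series TSV has no data rows")
        bad = df.index[df[required].isna().any(axis=1)].tolist()
        if bad:
            raise FormatError(f"time-series TSV has missing values in row(s) {bad}")
        return cls(
            times=df["time_h"].to_numpy(),
            host_treated=df["host_treated"].to_numpy(),
            host_control=df["host_control"].to_numpy(),
            free_undigested=df["free_undigested"].to_numpy(),
            free_digested=df["free_digested"].to_numpy()
            if "free_digested" in df.columns else None,
        )


@dataclass(frozen=True)
class GrowthEstimates:
    """Bundle of one-step growth outcomes plus the thresholds that produced them."""

    latent_h: float
    burst_undigested: float
    burst_digested: float | None
    packaged_fraction_mean: float | None
    n_infected: float
    burst_provisional: bool
    thresholds: dict

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(d.pop("thresholds"))
        return d


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------

def call_lysis(host_treated_final: float, host_control_final: float,
               threshold: float = 0.5) -> bool:
    """True iff the treated culture declined by strictly more than the
    threshold fraction relative to the control."""
    if host_control_final <= 0:
        raise ArgumentError("control count must be positive")
    return host_treated_final / host_control_final < (1.0 - threshold)


def call_infectivity_od(od_treated: float, od_control: float,
                        threshold: float = 0.5) -> bool:
    """Infectivity by optical density: same strict >50%-decline rule."""
    return call_lysis(od_treated, od_control, threshold)


# ---------------------------------------------------------------------------
# Kinetic estimators
# ---------------------------------------------------------------------------

def _post_adsorption(series: InfectionTimeSeries, adsorption_end_h: float):
    mask = series.times >= adsorption_end_h
    if not mask.any():
        raise ArgumentError("no samples after the adsorption window")
    return mask


def estimate_latent(
    series: InfectionTimeSeries,
    which: str = "undigested",
    adsorption_end_h: float = ADSORPTION_END_H,
    rise_factor: float = RISE_FACTOR,
) -> float:
    """Latent period: last sampling time before the first sustained rise.

    A sustained rise is two consecutive post-adsorption points each above
    rise_factor × baseline, where baseline is the post-adsorption minimum
    of the series. Raises NoBurstError when no such rise exists.
    """
    if series.times.size < 6:
        raise ArgumentError("latent-period estimation needs >= 6 time points")
    y = series.series(which)
    mask = _post_adsorption(series, adsorption_end_h)
    idx = np.nonzero(mask)[0]
    baseline = float(y[idx].min())
    threshold = rise_factor * baseline
    for j, i in enumerate(idx[:-1]):
        if y[i] > threshold and y[idx[j + 1]] > threshold:
            if j == 0:
                # rising already at the first post-adsorption sample: the
                # latent period is bounded only by the adsorption window
                return float(adsorption_end_h)
            return float(series.times[i - 1])
    raise NoBurstError(
        f"no sustained rise above {rise_factor} x baseline ({baseline:g}) detected"
    )


def estimate_burst(
    series: InfectionTimeSeries,
    which: str = "undigested",
    n_infected: float | None = None,
    adsorption_end_h: float = ADSORPTION_END_H,
    plateau_points: int = PLATEAU_POINTS,
) -> float:
    """Burst size: (mean plateau − post-adsorption residual) / infected cells.

    The plateau is the final `plateau_points` samples; the residual is the
    post-adsorption minimum (unadsorbed inoculum). If the series is still
    rising across the plateau a warning flags the estimate as provisional.
    """
    y = series.series(which)
    if n_infected is None:
        n_infected = float(series.host_treated[0])
    if n_infected <= 0:
        raise ArgumentError("n_infected must be positive")
    if plateau_points < 1 or plateau_points > y.size:
        raise ArgumentError("invalid plateau_points")
    mask = _post_adsorption(series, adsorption_end_h)
    residual = float(y[mask].min())
    plateau = y[-plateau_points:]
    plateau_mean = float(plateau.mean())
    if plateau_mean <= residual:
        raise NoBurstError("no rise above the post-adsorption residual")
    if plateau[-1] > 1.3 * plateau[0]:
        warnings.warn(
            "series still rising over the plateau window; burst estimate is provisional",
            stacklevel=2,
        )
    return (plateau_mean - residual) / n_infected


def packaged_fraction(
    series: InfectionTimeSeries,
    floor: float = RATIO_FLOOR,
) -> tuple[pd.DataFrame, float]:
    """Per-time digested/undigested ratios (clipped to [0, 1]) and their mean.

    Only time points with undigested signal above `floor` enter the mean;
    raises UndefinedValueError when none qualify.
    """
    if series.free_digested is None:
        raise ArgumentError("packaged_fraction requires the DNase-digested series")
    und = series.free_undigested
    dig = series.free_digested
    valid = und >= floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.clip(np.where(und > 0, dig / np.where(und > 0, und, 1.0), np.nan), 0.0, 1.0)
    ratio = np.where(valid, ratio, np.nan)
    if not valid.any():
        raise UndefinedValueError(
            f"no time point with undigested signal above the floor ({floor:g})"
        )
    table = pd.DataFrame(
        {"time_h": series.times, "packaged_ratio": ratio, "included": valid}
    )
    return table, float(np.nanmean(ratio))


def estimate_growth(
    series: InfectionTimeSeries,
    n_infected: float | None = None,
    adsorption_end_h: float = ADSORPTION_END_H,
    rise_factor: float = RISE_FACTOR,
    ratio_floor: float = RATIO_FLOOR,
    plateau_points: int = PLATEAU_POINTS,
) -> GrowthEstimates:
    """Run every estimator on one experiment and report all thresholds used."""
    if n_infected is None:
        n_infected = float(series.host_treated[0])
    latent = estimate_latent(series, "undigested", adsorption_end_h, rise_factor)
    provisional = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        burst_u = estimate_burst(series, "undigested", n_infected,
                                 adsorption_end_h, plateau_points)
        provisional = any("provisional" in str(w.message) for w in caught)
    burst_d = None
    pf_mean = None
    if series.free_digested is not None:
        burst_d = estimate_burst(series, "digested", n_infected,
                                 adsorption_end_h, plateau_points)
        _, pf_mean = packaged_fraction(series, ratio_floor)
    return GrowthEstimates(
        latent_h=latent,
        burst_undigested=burst_u,
        burst_digested=burst_d,
        packaged_fraction_mean=pf_mean,
        n_infected=n_infected,
        burst_provisional=provisional,
        thresholds={
            "adsorption_end_h": adsorption_end_h,
            "rise_factor": rise_factor,
            "ratio_floor": ratio_floor,
            "plateau_points": plateau_points,
        },
    )
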