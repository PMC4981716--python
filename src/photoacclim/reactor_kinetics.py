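"""Steady-state rate and yield calculations for turbidostat bioreactors.

A turbidostat holds optical density constant, so at steady state the dilution
rate D equals the specific growth rate mu imposed by the environment (here,
incident irradiance).  The net specific rate of oxygenic photosynthesis qO2
follows from an O2 mass balance over the liquid control volume:

    qO2 * x = D * ([O2] - [O2_in]) + kLa * ([O2] - kH * pO2_in)

with dissolved O2 in uM, dilution rate and the lumped gas-liquid transfer
coefficient kLa in h^-1, Henry's-law coefficient kH in mM atm^-1, in-gas O2
partial pressure pO2_in in atm, and biomass concentration x in g AFDW L^-1.
The right-hand side sums the net convective export and the net stripping flux;
qO2 is positive when the culture is a net O2 producer.

Canonical internal units: h^-1, uM, g L^-1, mmol h^-1 g^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: grams of ash-free dry biomass per carbon-mole, used to put biomass
#: production on a C-mol basis.
BIOMASS_G_PER_CMOL = 24.59

#: steady-state continuity criterion: max relative variation between
#: consecutive measurements (inclusive).
STEADY_STATE_MAX_VARIATION = 0.03

#: minimum residence times elapsed before a culture is called steady.
STEADY_STATE_MIN_RESIDENCE_TIMES = 5.0


@dataclass(frozen=True)
class GasLiquidParams:
    """Gas-liquid exchange parameters of the sparged reactor.

    Parameters
    ----------
    kla : float
        Lumped volumetric mass-transfer coefficient. Interpreted according
        to ``kla_unit`` and stored internally in h^-1.
    kH : float
        Henry's-law partitioning coefficient for O2, mM atm^-1.
    pO2_in : float
        O2 partial pressure of the in-gas, atm.
    O2_in : float
        Dissolved O2 of the inflowing medium, uM. Defaults to 0 (medium
        equilibrated with O2-free sparge gas).
    kla_unit : str
        ``"per_hour"`` or ``"per_minute"``; a per-minute value is converted
        to h^-1 on construction.
    """

    kla: float
    kH: float = 1.08
    pO2_in: float = 0.0
    O2_in: float = 0.0
    kla_unit: str = "per_hour"

    def __post_init__(self) -> None:
        if self.kla_unit not in ("per_hour", "per_minute"):
            raise ValueError(f"unknown kla unit {self.kla_unit!r}")
        if self.kla_unit == "per_minute":
            object.__setattr__(self, "kla", self.kla * 60.0)
            object.__setattr__(self, "kla_unit", "per_hour")
        if self.kla <= 0:
            raise ValueError("kla must be positive")
        if self.kH <= 0:
            raise ValueError("kH must be positive")
        if not 0.0 <= self.pO2_in <= 1.0:
            raise ValueError("pO2_in must lie in [0, 1] atm")
        if self.O2_in < 0:
            raise ValueError("O2_in must be non-negative")


@dataclass(frozen=True)
class SteadyStateRecord:
    """One irradiance-controlled steady state: environment plus responses."""

    Ii: float  # incident irradiance, umol photons m^-2 s^-1
    D: float  # dilution rate, h^-1
    mu: float  # specific growth rate, h^-1
    OD730: float
    x: float  # biomass concentration, g AFDW L^-1
    O2: float  # dissolved O2, uM
    pH: float = 7.5
    organism: str = ""

    def __post_init__(self) -> None:
        for name in ("Ii", "D", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class RateEstimates:
    """Specific rates at one steady state (production-positive convention)."""

    qO2: float  # mmol O2 h^-1 g^-1
    qX: float  # Cmmol h^-1 g^-1
    Q: float | None = None  # Cmmol biomass per mmol O2


def equilibrium_O2(gas: GasLiquidParams, pO2: float) -> float:
    """Dissolved O2 (uM) in equilibrium with a gas phase at ``pO2`` atm."""
    if pO2 < 0:
        raise ValueError("pO2 must be non-negative")
    return gas.kH * 1000.0 * pO2  # mM atm^-1 * atm -> mM -> uM


def compute_qO2(record: SteadyStateRecord, gas: GasLiquidParams) -> float:
    """Net specific O2 production rate from the steady-state mass balance.

    Returns qO2 in mmol O2 h^-1 g_AFDW^-1; negative values indicate net
    consumption and are returned as-is.
    """
    if record.x <= 0:
        raise ValueError("biomass concentration x must be positive to "
                         "compute a specific rate")
    o2_star = equilibrium_O2(gas, gas.pO2_in)  # uM
    flux_uM_per_h = (record.D * (record.O2 - gas.O2_in)
                     + gas.kla * (record.O2 - o2_star))
    # uM h^-1 == umol L^-1 h^-1; divide by g L^-1, convert umol -> mmol
    return flux_uM_per_h / record.x / 1000.0


def compute_qX(mu: float) -> float:
    """Net specific biomass production rate, Cmmol h^-1 g_AFDW^-1."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    return mu * 1000.0 / BIOMASS_G_PER_CMOL


@dataclass(frozen=True)
class QuotientFit:
    """Per-regime photosynthetic quotient: OLS slope of qX on qO2."""

    regime: str
    Q: float | None
    stderr: float | None
    intercept: float | None
    n: int
    ok: bool
    message: str = ""


def photosynthetic_quotient(
    qO2: np.ndarray,
    qX: np.ndarray,
    regime_labels,
    fit_intercept: bool = True,
) -> dict[str, QuotientFit]:
    """Photosynthetic quotient Q per growth regime.

    Q is the ratio of net carbon fixed into biomass (Cmmol) to net O2
    evolved (mmol), estimated as the OLS slope of qX on qO2 within each
    regime.  Regimes with fewer than two points or zero qO2 variance are
    flagged rather than fitted.
    """
    qO2 = np.asarray(qO2, dtype=float)
    qX = np.asarray(qX, dtype=float)
    labels = np.asarray(regime_labels)
    if not (len(qO2) == len(qX) == len(labels)):
        raise ValueError("qO2, qX and regime_labels must be equal length")
    out: dict[str, QuotientFit] = {}
    for regime in dict.fromkeys(labels.tolist()):  # preserve order
        m = labels == regime
        x, y = qO2[m], qX[m]
        n = int(m.sum())
        if n < 2:
            out[regime] = QuotientFit(regime, None, None, None, n, False,
                                      "fewer than 2 points")
            continue
        if np.ptp(x) == 0:
            out[regime] = QuotientFit(regime, None, None, None, n, False,
                                      "zero qO2 variance")
            continue
        if fit_intercept:
            res = stats.linregress(x, y)
            out[regime] = QuotientFit(regime, float(res.slope),
                                      float(res.stderr),
                                      float(res.intercept), n, True)
        else:
            slope = float(np.dot(x, y) / np.dot(x, x))
            resid = y - slope * x
            dof = max(n - 1, 1)
            se = float(np.sqrt(resid @ resid / dof / np.dot(x, x)))
            out[regime] = QuotientFit(regime, slope, se, 0.0, n, True)
    return out


@dataclass(frozen=True)
class SteadyStateVerdict:
    steady: bool
    residence_times_elapsed: float
    channel_verdicts: dict[str, bool | None] = field(default_factory=dict)
    max_variation: dict[str, float | None] = field(default_factory=dict)


def detect_steady_state(
    channels: dict[str, np.ndarray],
    residence_times_elapsed: float,
    max_variation: float = STEADY_STATE_MAX_VARIATION,
    min_residence_times: float = STEADY_STATE_MIN_RESIDENCE_TIMES,
) -> SteadyStateVerdict:
    """Physiological steady-state check from growth readout continuity.

    A culture is steady when every monitored channel (typically OD730, pH,
    dissolved O2) varies by at most ``max_variation`` (inclusive) between
    consecutive measurements — relative variation |delta| / pair mean — and
    at least ``min_residence_times`` reactor residence times have elapsed.
    Channels with fewer than two measurements are indeterminate (None) and
    make the overall verdict False.
    """
    verdicts: dict[str, bool | None] = {}
    variations: dict[str, float | None] = {}
    for name, series in channels.items():
        v = np.asarray(series, dtype=float)
        if v.size < 2:
            verdicts[name] = None
            variations[name] = None
            continue
        pair_mean = (v[1:] + v[:-1]) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(np.diff(v)) / np.abs(pair_mean)
        rel = np.where(np.abs(np.diff(v)) == 0, 0.0, rel)
        worst = float(np.max(rel))
        variations[name] = worst
        verdicts[name] = bool(worst <= max_variation)
    all_ok = all(v is True for v in verdicts.values()) and len(verdicts) > 0
    steady = all_ok and residence_times_elapsed >= min_residence_times
    return SteadyStateVerdict(steady, residence_times_elapsed, verdicts,
                              variations)


def rates_table(records, gas: GasLiquidParams):
    """Compute qO2 and qX for a sequence of records; returns a DataFrame."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append({
            "organism": r.organism,
            "Ii": r.Ii,
            "mu": r.mu,
            "qO2": compute_qO2(r, gas),
            "qX": compute_qX(r.mu),
        })
    return pd.DataFrame(rows)


def doubling_time(mu: float) -> float:
    """Doubling time (h) of exponential growth at specific rate mu (h^-1)."""
    if mu <= 0:
        return math.inf
    return math.log(2.0) / mu
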