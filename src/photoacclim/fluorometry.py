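"""PAM chlorophyll-fluorescence statistics.

Pulse-amplitude-modulated (PAM) fluorometry probes photosystem II: the
relative electron transport rate is rETR = PAR * dF/Fm' with dF = Fm' - F,
a rapid light curve traces rETR against stepped PAR and is summarised by its
asymptote rETR_max and initial slope alpha_r, the maximal quantum yield is
Fv/Fm = (Fm - Fo)/Fm, and the post-illumination fluorescence rise in darkness
is used as a proxy for cyclic electron flow around photosystem I (rCEF):
reductant accumulated in the light re-reduces the plastoquinone pool after
the actinic light goes off, raising F at a rate proportional to that flux.

The measurement protocol applies, after fluorescence induction under actinic
light: (i) a 200-ms saturating pulse, (ii) 5 s of far-red light, (iii) 15 s
of actinic light, (iv) 30 s of darkness.  rCEF is the least-squares slope of
F over the initial window of the dark phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import photoresponse

PHASES = ("saturating_pulse", "far_red", "actinic", "dark")

#: nominal phase durations (s) of the four-step protocol
PHASE_DURATIONS = {"saturating_pulse": 0.2, "far_red": 5.0,
                   "actinic": 15.0, "dark": 30.0}

#: default initial window of the dark phase used for the rCEF slope (s)
DEFAULT_RCEF_WINDOW_S = 10.0


@dataclass
class FluorescenceTrace:
    """A PAM time trace: time (s), fluorescence, and a phase label per sample."""

    time: np.ndarray
    F: np.ndarray
    phase: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time) == len(self.F) == len(self.phase)):
            raise ValueError("time, F and phase must be equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        unknown = set(self.phase) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "F": self.F,
                             "phase": self.phase})


@dataclass
class RapidLightCurve:
    """Stepped-PAR fluorescence table from which rETR(PAR) is computed."""

    PAR: np.ndarray
    F: np.ndarray
    Fm_prime: np.ndarray
    step_duration_s: float = 60.0

    def __post_init__(self) -> None:
        self.PAR = np.asarray(self.PAR, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.Fm_prime = np.asarray(self.Fm_prime, dtype=float)
        if not (len(self.PAR) == len(self.F) == len(self.Fm_prime)):
            raise ValueError("PAR, F and Fm_prime must be equal length")
        if np.any(self.PAR < 0) or np.any(np.diff(self.PAR) <= 0):
            raise ValueError("PAR must be non-negative and strictly increasing")
        if np.any(self.Fm_prime <= 0) or np.any(self.F <= 0):
            raise ValueError("fluorescence values must be positive")

    @property
    def rETR(self) -> np.ndarray:
        return compute_rETR(self.PAR, self.F, self.Fm_prime)


@dataclass
class PhotoPhysStats:
    """Photophysiology summary for one sample."""

    rETRmax: float | None = None
    rETRmax_observed: float | None = None
    alpha_r: float | None = None
    rCEF: float | None = None
    FvFm: float | None = None
    flags: list = field(default_factory=list)


def compute_rETR(PAR, F, Fm_prime):
    """Relative electron transport rate, rETR = PAR * (Fm' - F) / Fm'.

    F above Fm' yields a negative rate; the anomaly is preserved (and can be
    flagged by the caller) rather than clamped.
    """
    PAR = np.asarray(PAR, dtype=float)
    F = np.asarray(F, dtype=float)
    Fm_prime = np.asarray(Fm_prime, dtype=float)
    if np.any(Fm_prime <= 0):
        raise ValueError("Fm_prime must be positive")
    if np.any(PAR < 0):
        raise ValueError("PAR must be non-negative")
    out = PAR * (Fm_prime - F) / Fm_prime
    return out if out.ndim else float(out)


def fit_rapid_light_curve(rlc: RapidLightCurve):
    """Fit the saturating light-response curve to (PAR, rETR) points.

    Returns ``(rETRmax, alpha_r, fit)`` where rETRmax is the fitted
    asymptote and alpha_r = Rmax/Ik its initial slope.  An all-zero rETR
    series is degenerate and returns ``(None, None, None)``.
    """
    retr = rlc.rETR
    par = rlc.PAR
    keep = par > 0
    if keep.sum() < 3:
        raise ValueError("need at least 3 positive-PAR steps")
    if np.allclose(retr[keep], 0.0):
        warnings.warn("degenerate rapid light curve: all rETR values are zero")
        return None, None, None
    fit = photoresponse.fit_light_response(par[keep], retr[keep],
                                           model="saturating")
    return fit.Rmax, fit.alpha, fit


def estimate_rCEF(trace: FluorescenceTrace,
                  window_s: float = DEFAULT_RCEF_WINDOW_S) -> float:
    """Post-illumination fluorescence rise rate (fluorescence units s^-1).

    The ordinary-least-squares slope of F against time over the first
    ``window_s`` seconds of the dark phase.  The rise reflects plastoquinone
    reduction by accumulated reductant and serves as a cyclic-electron-flow
    proxy.
    """
    dark = trace.phase == "dark"
    if not np.any(dark):
        raise ValueError("trace contains no dark phase")
    t = trace.time[dark]
    f = trace.F[dark]
    t0 = t[0]
    if window_s > t[-1] - t0:
        warnings.warn("rCEF window longer than dark phase; truncated")
    sel = t - t0 <= window_s
    t, f = t[sel], f[sel]
    if len(t) < 3:
        raise ValueError("need at least 3 dark-phase samples in the window")
    if np.ptp(f) == 0:
        return 0.0
    return float(stats.linregress(t, f).slope)


def optimal_quantum_yield(Fo: float, Fm: float) -> float:
    """Maximal PS II quantum yield Fv/Fm = (Fm - Fo)/Fm."""
    if Fm <= 0:
        raise ValueError("Fm must be positive")
    y = (Fm - Fo) / Fm
    if y < 0:
        warnings.warn("Fo exceeds Fm: negative quantum yield")
    return y


def summarize(trace: FluorescenceTrace | None = None,
              rlc: RapidLightCurve | None = None,
              Fo: float | None = None,
              Fm: float | None = None,
              rcef_window_s: float = DEFAULT_RCEF_WINDOW_S) -> PhotoPhysStats:
    """Bundle the PAM statistics available from the supplied inputs."""
    out = PhotoPhysStats()
    if rlc is not None:
        retrmax, alpha_r, _ = fit_rapid_light_curve(rlc)
        if retrmax is None:
            out.flags.append("degenerate rapid light curve")
        out.rETRmax = retrmax
        out.alpha_r = alpha_r
        out.rETRmax_observed = float(np.max(rlc.rETR))
    if trace is not None:
        out.rCEF = estimate_rCEF(trace, window_s=rcef_window_s)
    if Fo is not None and Fm is not None:
        out.FvFm = optimal_quantum_yield(Fo, Fm)
        if out.FvFm < 0:
            out.flags.append("negative Fv/Fm")
    return out
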