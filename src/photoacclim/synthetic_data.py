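"""Synthetic generators for every pipeline input, with known ground truth.

These generators stand in for the bioreactor, fluorometer, sequencer and
microscope: steady states lie on a Platt-type growth-irradiance curve with
dissolved O2 solving the reactor mass balance exactly for the simulated qO2;
fluorescence traces follow the four-phase PAM protocol with a linear
post-illumination rise; expression matrices are built from four eigengene
archetypes (monotone up, monotone down, minimum and maximum at the
light-limited-to-saturated transition) plus gene-level noise; annotation
maps carry planted enriched categories.

Measurement noise is multiplicative mean-one log-normal (rates are positive
and their reported spread scales with the mean).  Every generator is
deterministic given its seed, and ground truth travels in clearly separated
``truth_*`` columns/fields that no estimator reads.

Default parameter values are those of the turbidostat study conditions the
generators emulate: mu_max = 0.20 h^-1, Ik = 164 umol photons m^-2 s^-1, no
growth photoinhibition, irradiances spanning 33-760, OD730 setpoint 0.082
(36 mg AFDW L^-1), kLa = 0.83 min^-1, kH = 1.08 mM atm^-1, photosynthetic
quotients 1.3 (light-limited) and 0.6 (light-saturated).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import photoresponse
from .fluorometry import FluorescenceTrace, RapidLightCurve, PHASE_DURATIONS
from .reactor_kinetics import GasLiquidParams, compute_qX

#: irradiance grid of the emulated steady states, umol photons m^-2 s^-1
DEFAULT_IRRADIANCES = (33.0, 65.0, 98.0, 164.0, 264.0, 395.0, 580.0, 760.0)

TRUTH_COLUMNS = ("truth_mu", "truth_qO2", "truth_regime")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of
    variation ``cv`` (exactly 1 when cv == 0)."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


@dataclass
class TurbidostatSimConfig:
    """Ground-truth parameters of the simulated turbidostat steady states."""

    Rmax_mu: float = 0.20  # h^-1
    Ik: float = 164.0  # umol photons m^-2 s^-1
    beta: float = math.inf  # inhibition threshold; inf = no photoinhibition
    irradiance_grid: tuple = DEFAULT_IRRADIANCES
    q_per_regime: dict = field(default_factory=lambda: {
        photoresponse.REGIME_LIMITED: 1.3,
        photoresponse.REGIME_SATURATED: 0.6,
    })
    gas: GasLiquidParams = field(default_factory=lambda: GasLiquidParams(
        kla=0.83, kla_unit="per_minute", kH=1.08, pO2_in=0.0, O2_in=0.0))
    setpoint_OD: float = 0.082
    od_to_biomass: float = 0.439  # g AFDW L^-1 per OD730 unit
    noise_cv: float = 0.05
    pH: float = 7.5
    organism: str = "Synechococcus 7002"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Rmax_mu <= 0 or self.Ik <= 0 or self.beta <= 0:
            raise ValueError("Rmax_mu, Ik and beta must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if any(ii <= 0 for ii in self.irradiance_grid):
            raise ValueError("irradiances must be strictly positive")


def _qO2_from_qX(qX: np.ndarray, cfg: TurbidostatSimConfig) -> np.ndarray:
    """Continuous piecewise-linear map from biomass rate to O2 rate.

    Below the Ik transition the photosynthetic quotient (slope of qX on qO2)
    is Q_lim; above it, Q_sat, with the two line segments joined at the
    rate realised at Ii = Ik.
    """
    q_lim = cfg.q_per_regime[photoresponse.REGIME_LIMITED]
    q_sat = cfg.q_per_regime[photoresponse.REGIME_SATURATED]
    mu_k = photoresponse.eval_light_response(cfg.Ik, cfg.Rmax_mu, cfg.Ik,
                                             cfg.beta)
    qx_k = compute_qX(mu_k)
    qo_k = qx_k / q_lim
    return np.where(qX <= qx_k,
                    qX / q_lim,
                    qo_k + (qX - qx_k) / q_sat)


def simulate_steady_states(config: TurbidostatSimConfig) -> pd.DataFrame:
    """Simulate one steady-state record per grid irradiance.

    The observable columns are organism, Ii, D, mu, OD730, x, O2_uM, pH;
    ground truth travels in ``truth_mu``, ``truth_qO2``, ``truth_regime``.
    Dissolved O2 is the exact solution of the reactor O2 balance for the
    simulated qO2, so rate estimators can recover the truth.
    """
    rng = np.random.default_rng(config.seed)
    ii = np.asarray(config.irradiance_grid, dtype=float)
    n = len(ii)
    mu_true = photoresponse.eval_light_response(ii, config.Rmax_mu, config.Ik,
                                                config.beta)
    mu = mu_true * _lognormal_factor(rng, config.noise_cv, n)
    od = config.setpoint_OD * _lognormal_factor(rng, config.noise_cv, n)
    x = od * config.od_to_biomass
    qx = np.array([compute_qX(m) for m in mu])
    qo2 = _qO2_from_qX(qx, config) * _lognormal_factor(rng, config.noise_cv, n)
    gas = config.gas
    # invert the steady-state O2 balance for the dissolved concentration
    flux = qo2 * 1000.0 * x  # uM h^-1
    o2_star = gas.kH * 1000.0 * gas.pO2_in
    o2 = (flux + mu * gas.O2_in + gas.kla * o2_star) / (mu + gas.kla)
    bad = o2 < 0
    if np.any(bad):
        offenders = ii[bad].tolist()
        raise ValueError("non-physical configuration: negative dissolved O2 "
                         f"at irradiance(s) {offenders}")
    regimes = photoresponse.classify_regimes(ii, config.Ik)
    return pd.DataFrame({
        "organism": config.organism,
        "Ii": ii,
        "D": mu,  # turbidostat steady state: dilution rate equals growth rate
        "mu": mu,
        "OD730": od,
        "x": x,
        "O2_uM": o2,
        "pH": config.pH,
        "truth_mu": mu_true,
        "truth_qO2": qo2,
        "truth_regime": regimes,
    })


@dataclass
class ExpressionSimConfig:
    """Planted-archetype expression matrix generator settings."""

    n_genes: tuple = (809, 724, 648, 551)  # per archetype
    n_conditions: int = 8
    transition_index: int = 3  # condition nearest the Ik transition
    gene_noise_sd: float = 0.3  # standardized units
    rpkm_scale: float = 100.0
    #: category -> (archetype number 1..4, fraction of that cluster's genes)
    planted_categories: dict = field(default_factory=lambda: {
        "translation": (1, 0.15),
        "photosystem antenna": (2, 0.15),
        "photodamage and repair": (3, 0.12),
        "polysaccharide biosynthesis": (4, 0.12),
    })
    n_background_categories: int = 8
    background_fraction: float = 0.05
    condition_labels: tuple | None = None  # defaults to the irradiance grid
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_genes):
            raise ValueError("each archetype needs at least one gene")
        if self.gene_noise_sd < 0:
            raise ValueError("gene_noise_sd must be non-negative")
        if self.rpkm_scale <= 0:
            raise ValueError("rpkm_scale must be positive")
        if self.n_conditions < 4:
            raise ValueError("need at least 4 conditions to distinguish the "
                             "four archetypes")
        if not 0 < self.transition_index < self.n_conditions - 1:
            raise ValueError("transition_index must be interior")


def archetype_profiles(n_conditions: int, transition_index: int) -> np.ndarray:
    """The four standardized eigengene archetypes (rows), piecewise-linear
    in condition index: monotone up, monotone down, minimum at the
    transition, maximum at the transition.

    The monotone shapes saturate/accelerate at breakpoints offset from the
    transition and the two extremum shapes have asymmetric arms, so the four
    standardized profiles are mutually linearly independent once there are
    enough conditions (>= 6) to resolve the distinct breakpoints.
    """
    t = np.arange(n_conditions, dtype=float)
    tr = float(transition_index)
    up = np.minimum(t, min(tr + 2.0, n_conditions - 1.0))  # rises, plateaus
    down = -np.minimum(t, min(tr + 1.0, n_conditions - 1.0))
    vee = np.maximum(tr - t, 0) + 0.8 * np.maximum(t - tr, 0)  # min at tr
    hat = -(0.8 * np.maximum(tr - t, 0) + np.maximum(t - tr, 0))  # max at tr
    profiles = np.vstack([up, down, vee, hat])
    mean = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    return (profiles - mean) / sd


@dataclass
class SimulatedExpression:
    """Bundle of simulated expression data with its ground truth."""

    rpkm: pd.DataFrame  # genes x conditions, positive
    true_labels: pd.Series  # gene -> archetype number (1..4)
    annotations: pd.DataFrame  # long-format (gene, level, category)
    archetypes: np.ndarray  # 4 x n_conditions standardized profiles
    planted: dict  # category -> (cluster, fraction)


def simulate_expression(config: ExpressionSimConfig) -> SimulatedExpression:
    """Genes = archetype profile + Gaussian noise, mapped to positive RPKM
    via RPKM = rpkm_scale * 2**profile (so the log2/z-score transform of the
    analysis recovers the planted structure)."""
    rng = np.random.default_rng(config.seed)
    profiles = archetype_profiles(config.n_conditions, config.transition_index)
    n_total = int(sum(config.n_genes))
    width = len(str(n_total))
    rows, labels, gene_ids = [], [], []
    g = 0
    for arch, n in enumerate(config.n_genes, start=1):
        noise = rng.normal(0.0, config.gene_noise_sd,
                           size=(n, config.n_conditions))
        rows.append(profiles[arch - 1] + noise)
        labels.extend([arch] * n)
        gene_ids.extend(f"g{g + i:0{width}d}" for i in range(n))
        g += n
    z = np.vstack(rows)
    rpkm = config.rpkm_scale * np.exp2(z)
    if config.condition_labels is not None:
        cond = list(config.condition_labels)
        if len(cond) != config.n_conditions:
            raise ValueError("condition_labels length mismatch")
    else:
        grid = list(DEFAULT_IRRADIANCES)
        cond = ([f"Ii_{int(v)}" for v in grid[:config.n_conditions]]
                if config.n_conditions <= len(grid)
                else [f"cond_{i}" for i in range(config.n_conditions)])
    rpkm_df = pd.DataFrame(rpkm, index=pd.Index(gene_ids, name="gene"),
                           columns=cond)
    true_labels = pd.Series(labels, index=rpkm_df.index, name="cluster")

    ann_records = []
    for cat, (cluster, fraction) in config.planted_categories.items():
        members = true_labels.index[true_labels == cluster]
        n_pick = max(1, math.floor(fraction * len(members)))
        picked = rng.choice(members, size=n_pick, replace=False)
        for gene in sorted(picked):
            ann_records.append({"gene": gene, "level": "main_role",
                                "category": cat})
    for i in range(config.n_background_categories):
        level = "subrole" if i % 2 else "main_role"
        n_pick = max(1, math.floor(config.background_fraction * n_total))
        picked = rng.choice(rpkm_df.index, size=n_pick, replace=False)
        for gene in sorted(picked):
            ann_records.append({"gene": gene, "level": level,
                                "category": f"background_{i:02d}"})
    annotations = pd.DataFrame(ann_records,
                               columns=["gene", "level", "category"])
    return SimulatedExpression(rpkm=rpkm_df, true_labels=true_labels,
                               annotations=annotations, archetypes=profiles,
                               planted=dict(config.planted_categories))


def simulate_fluorescence_trace(rcef_slope: float, noise_sd: float = 0.0,
                                seed: int = 0, dt: float = 0.1,
                                levels: dict | None = None
                                ) -> FluorescenceTrace:
    """Four-phase PAM trace with a linear dark-phase rise of the given slope.

    Phases follow the printed protocol: 200-ms saturating pulse, 5 s
    far-red, 15 s actinic, 30 s dark.  Dark-phase fluorescence is
    ``F_dark0 + rcef_slope * (t - t_dark_start)`` plus Gaussian noise.
    """
    if not math.isfinite(rcef_slope):
        raise ValueError("rcef_slope must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    levels = levels or {"saturating_pulse": 2.5, "far_red": 0.8,
                        "actinic": 1.5, "dark": 1.0}
    rng = np.random.default_rng(seed)
    times, values, phases = [], [], []
    t0 = 0.0
    for phase in ("saturating_pulse", "far_red", "actinic", "dark"):
        dur = PHASE_DURATIONS[phase]
        step = min(dt, dur / 2.0)
        t = np.arange(0.0, dur, step)
        if phase == "dark":
            f = levels[phase] + rcef_slope * t
        else:
            f = np.full_like(t, levels[phase])
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=len(t))
        times.append(t + t0)
        values.append(f)
        phases.extend([phase] * len(t))
        t0 += dur
    return FluorescenceTrace(np.concatenate(times), np.concatenate(values),
                             np.asarray(phases, dtype=object),
                             metadata={"rcef_slope_truth": rcef_slope,
                                       "noise_sd": noise_sd, "seed": seed})


def simulate_rapid_light_curve(Rmax: float = 60.0, Ik: float = 120.0,
                               par_steps=None, Fm_prime: float = 1.0,
                               noise_sd: float = 0.0, seed: int = 0
                               ) -> RapidLightCurve:
    """Rapid light curve whose rETR follows the saturating light-response
    model; F is back-computed from the target photochemical yield.

    ``noise_sd`` is the relative (multiplicative) noise on the rETR values,
    applied before the fluorescence back-computation — measurement scatter
    in rapid light curves scales with the electron transport rate.
    """
    if par_steps is None:
        par_steps = np.array([25., 50., 100., 150., 250., 400., 600., 800.])
    par = np.asarray(par_steps, dtype=float)
    rng = np.random.default_rng(seed)
    retr = photoresponse.eval_light_response(par, Rmax, Ik)
    if noise_sd > 0:
        retr = retr * (1.0 + rng.normal(0.0, noise_sd, size=len(retr)))
        retr = np.clip(retr, 0.0, None)
    yield_ = retr / np.where(par > 0, par, 1.0)
    if np.any(yield_ >= 1.0):
        raise ValueError("Rmax/Ik too high: photochemical yield would "
                         "exceed 1")
    f = np.clip(Fm_prime * (1.0 - yield_), 1e-6, None)
    return RapidLightCurve(PAR=par, F=f,
                           Fm_prime=np.full_like(par, Fm_prime))


#: per-condition (mean volume um^3, n cells) of the emulated morphometrics;
#: the flanking conditions follow the printed means and counts, the middle
#: one is an interpolated transitional state.
DEFAULT_VOLUME_CONDITIONS = {98.0: (4.84, 104), 164.0: (6.9, 107),
                             395.0: (9.69, 65)}


def simulate_cell_measurements(conditions: dict | None = None,
                               aspect_ratio: float = 1.7,
                               axis_cv: float = 0.05,
                               seed: int = 0) -> pd.DataFrame:
    """Cell axis-measurement table (cell id, a_um, b_um, condition).

    Cells are prolate spheroids with a fixed mean aspect ratio; axis
    diameters get independent mean-one log-normal noise, with the minor
    axis scaled so the expected volume matches the requested mean.
    """
    conditions = conditions or DEFAULT_VOLUME_CONDITIONS
    rng = np.random.default_rng(seed)
    rows = []
    cell = 0
    for condition, (mean_v, n) in conditions.items():
        # E[a^2 b] = a0^2 b0 (1+cv^2) for independent mean-one factors
        target = mean_v / (1.0 + axis_cv ** 2)
        a0 = (6.0 * target / (math.pi * aspect_ratio)) ** (1.0 / 3.0)
        b0 = aspect_ratio * a0
        a = a0 * _lognormal_factor(rng, axis_cv, n)
        b = b0 * _lognormal_factor(rng, axis_cv, n)
        b = np.maximum(b, a)  # keep major >= minor
        for i in range(n):
            rows.append({"cell_id": f"c{cell + i:05d}", "a_um": a[i],
                         "b_um": b[i], "condition": condition})
        cell += n
    return pd.DataFrame(rows)


def write_bundle(outdir, seed: int = 0,
                 turbidostat: TurbidostatSimConfig | None = None,
                 expression: ExpressionSimConfig | None = None,
                 rcef_slope: float = 0.5, trace_noise_sd: float = 0.02
                 ) -> dict:
    """Write a complete synthetic input bundle (TSVs + JSON sidecar).

    Returns the manifest dict that is also written to ``manifest.json``.
    """
    from .io import write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    turbidostat = turbidostat or TurbidostatSimConfig(seed=seed)
    expression = expression or ExpressionSimConfig(seed=seed + 1)

    states = simulate_steady_states(turbidostat)
    write_table(states, outdir / "steady_states.tsv", units={
        "Ii": "umol_photons_m-2_s-1", "D": "h-1", "mu": "h-1",
        "x": "g_AFDW_L-1", "O2_uM": "uM"})

    sim = simulate_expression(expression)
    rpkm = sim.rpkm.reset_index()
    write_table(rpkm, outdir / "expression_rpkm.tsv", units={})
    write_table(sim.annotations, outdir / "annotations.tsv", units={})
    write_table(sim.true_labels.rename("truth_cluster").reset_index(),
                outdir / "truth_expression_labels.tsv", units={})

    trace = simulate_fluorescence_trace(rcef_slope, trace_noise_sd, seed=seed)
    write_table(trace.to_frame(), outdir / "pam_trace.tsv",
                units={"time_s": "s", "F": "fluorescence_units"})
    rlc = simulate_rapid_light_curve(seed=seed)
    write_table(pd.DataFrame({"PAR": rlc.PAR, "F": rlc.F,
                              "Fm_prime": rlc.Fm_prime}),
                outdir / "rapid_light_curve.tsv",
                units={"PAR": "umol_photons_m-2_s-1"})

    cells = simulate_cell_measurements(seed=seed)
    write_table(cells, outdir / "cell_measurements.tsv",
                units={"a_um": "um", "b_um": "um"})

    gas = turbidostat.gas
    turbo_cfg = asdict(turbidostat)
    turbo_cfg["beta"] = (None if math.isinf(turbidostat.beta)
                         else turbidostat.beta)
    manifest = {
        "seed": seed,
        "turbidostat_config": turbo_cfg,
        "expression_config": asdict(expression),
        "gas_params": {"kla": gas.kla, "kla_unit": "per_hour", "kH": gas.kH,
                       "pO2_in": gas.pO2_in, "O2_in": gas.O2_in},
        "rcef_slope": rcef_slope,
        "files": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
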