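"""In-silico culture experiments with known ground truth.

Generates everything the analysis chain consumes — growth curves, residual
Pb(II) depletion, circuit-parameter trajectories and noisy impedance sweeps —
for a batch-reactor experiment: three replicate reactors, sampled hourly over
10 Hz–1 MHz sweeps, run with and without an initial 80 mg/L Pb(II) dose.

Two growth profiles are provided.  ``rise_plateau`` emulates a facultative
organism that keeps growing slowly after its fast phase (K. pneumoniae-like):
log-CFU follows dL/dt = r·(1 − L/K), a saturating curve whose early slope is
the growth rate r.  ``rise_decline`` emulates an organism that peaks and then
declines after substrate depletion (P. bifermentans-like): the same curve up
to the peak time, then a linear decline.

Circuit parameters are linked to growth through affine maps from log-CFU to
the negated coefficients (−a0 … −d0), with multiplicative offsets applied in
the Pb condition to reproduce the orders-of-magnitude separation of |b0| and
|c0| between exposed and unexposed cultures.  Every generator is a pure
function of its configuration and seed.

The module also carries the two small solution-chemistry helpers (stock
concentration from dissolved salt mass; nominal reactor concentration after
spiking) used to define the 10,000 mg/L stock and 80 mg/L working dose.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .circuit import CircuitParams
from .growth import GrowthSeries, PbSeries
from .spectra import FrequencyGrid, ImpedanceSpectrum, write_spectra

__all__ = [
    "GrowthModelSpec",
    "Affine",
    "LinkageModel",
    "NoiseSpec",
    "PbDepletionSpec",
    "ExperimentConfig",
    "simulate_growth",
    "simulate_pb",
    "params_from_growth",
    "simulate_spectrum",
    "simulate_experiment",
    "stock_concentration",
    "dilution_concentration",
    "PB_MASS_FRACTION_IN_NITRATE",
    "GROWTH_PRESETS",
    "LINKAGE_PRESETS",
]

# Atomic masses (u) for the Pb(NO3)2 stoichiometry.
_M_PB = 207.2
_M_N = 14.007
_M_O = 15.999
_M_PB_NITRATE = _M_PB + 2 * (_M_N + 3 * _M_O)

#: Mass fraction of Pb in lead(II) nitrate, 207.2 / 331.2 ≈ 0.6256.
PB_MASS_FRACTION_IN_NITRATE = _M_PB / _M_PB_NITRATE

#: Series resistance filling the real channel of synthetic sweeps (Ω).
#: Only the reactance is modelled; this keeps Nyquist plots drawable.
DEFAULT_R_SERIES_OHM = 100.0


@dataclass(frozen=True)
class GrowthModelSpec:
    """Shape of a simulated log-CFU trajectory."""

    profile: Literal["rise_plateau", "rise_decline"]
    initial_log_cfu: float = 6.0
    growth_rate: float = 0.55  # d(log10 CFU)/dt at the start of growth, 1/h
    capacity: float = 9.5  # plateau log10(CFU/mL)
    peak_time_h: float = 9.0  # rise_decline only
    decline_rate: float = 0.15  # 1/h, rise_decline only

    def __post_init__(self) -> None:
        if self.growth_rate < 0 or self.decline_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.profile not in ("rise_plateau", "rise_decline"):
            raise ValueError(f"unknown growth profile {self.profile!r}")


@dataclass(frozen=True)
class Affine:
    """y = intercept + slope·x."""

    intercept: float
    slope: float = 0.0

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class LinkageModel:
    """Affine maps from log-CFU to the negated circuit coefficients.

    The maps produce (−a0, −b0, −c0, −d0); Pb-exposed reactors additionally
    multiply each negated coefficient by its entry in ``with_pb_scale``.
    A negative ``neg_b0.slope`` makes −b0 decrease as the culture grows,
    the configuration under which −b0 is a usable CFU proxy.
    """

    neg_a0: Affine
    neg_b0: Affine
    neg_c0: Affine
    neg_d0: Affine
    with_pb_scale: dict[str, float] = field(
        default_factory=lambda: {"a0": 1.0, "b0": 1.0, "c0": 1.0, "d0": 1.0}
    )

    def params_at(self, log_cfu: float, condition: str) -> CircuitParams:
        scale = self.with_pb_scale if condition == "with_pb" else None
        vals = {}
        for name, aff in (("a0", self.neg_a0), ("b0", self.neg_b0),
                          ("c0", self.neg_c0), ("d0", self.neg_d0)):
            v = float(aff(log_cfu))
            if scale is not None:
                v *= scale[name]
            vals[name] = -v  # maps are on the negated scale
        return CircuitParams(**vals)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian reactance noise: absolute σ (Ω) plus relative σ."""

    sigma_abs: float = 0.0
    sigma_rel: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_abs < 0 or self.sigma_rel < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass(frozen=True)
class PbDepletionSpec:
    """First-order-like Pb(II) uptake with a concentration floor."""

    initial_mg_per_l: float = 80.0
    uptake_rate: float = 0.9  # mg/L removed per hour per unit log-CFU
    floor_mg_per_l: float = 5.0

    def __post_init__(self) -> None:
        if self.floor_mg_per_l > self.initial_mg_per_l:
            raise ValueError("floor concentration cannot exceed the initial concentration")
        if min(self.initial_mg_per_l, self.uptake_rate, self.floor_mg_per_l) < 0:
            raise ValueError("concentrations and rates must be non-negative")


GROWTH_PRESETS: dict[str, GrowthModelSpec] = {
    # fast rise then continued slow growth to the end of the run
    "kpneumoniae_like": GrowthModelSpec(profile="rise_plateau"),
    # rise to a peak near 9 h, then decline
    "pbifermentans_like": GrowthModelSpec(profile="rise_decline", capacity=9.0),
}

# Plausible-scale trajectories: d0 near 1e-5 H (wiring inductance), |b0| and
# |c0| separated by orders of magnitude between Pb conditions.  Magnitudes
# are illustrative, not measured values.
LINKAGE_PRESETS: dict[str, LinkageModel] = {
    "kpneumoniae_like": LinkageModel(
        neg_a0=Affine(-8.0, 0.5),
        neg_b0=Affine(400.0, -30.0),
        neg_c0=Affine(40.0, -2.5),
        neg_d0=Affine(-2.0e-5, 0.0),
        with_pb_scale={"a0": 2.0, "b0": 100.0, "c0": 20.0, "d0": 1.5},
    ),
    "pbifermentans_like": LinkageModel(
        neg_a0=Affine(-7.0, 0.4),
        neg_b0=Affine(350.0, -25.0),
        neg_c0=Affine(35.0, -2.0),
        neg_d0=Affine(-2.0e-5, 0.0),
        with_pb_scale={"a0": 1.5, "b0": 15.0, "c0": 8.0, "d0": 1.1},
    ),
}


def simulate_growth(spec: GrowthModelSpec, times: np.ndarray | Sequence[float],
                    reactor_id: str = "r1", condition: str = "without_pb") -> GrowthSeries:
    """Deterministic log-CFU trajectory for one reactor.

    ``rise_plateau`` integrates dL/dt = r·(1 − L/K) in closed form,
    L(t) = K − (K − L0)·exp(−r·t/K), so the early-time slope is r and the
    series saturates at the capacity K.  ``rise_decline`` follows the same
    curve up to the peak time, then declines linearly.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly ascending")
    spec_l0, K, r = spec.initial_log_cfu, spec.capacity, spec.growth_rate

    def saturating(tt: np.ndarray) -> np.ndarray:
        if r == 0:
            return np.full_like(tt, spec_l0)
        return K - (K - spec_l0) * np.exp(-r * tt / K)

    if spec.profile == "rise_plateau":
        log_cfu = saturating(t)
    else:
        peak_val = float(saturating(np.array([spec.peak_time_h]))[0])
        log_cfu = np.where(
            t <= spec.peak_time_h,
            saturating(t),
            peak_val - spec.decline_rate * (t - spec.peak_time_h),
        )
    return GrowthSeries(t, log_cfu, reactor_id=reactor_id, condition=condition)


def simulate_pb(spec: PbDepletionSpec, growth: GrowthSeries, reactor_id: str | None = None) -> PbSeries:
    """Residual Pb(II) under growth-proportional uptake with a floor.

    Explicit stepping: C(t+Δ) = max(floor, C(t) − uptake·log_cfu(t)·Δ).
    The series is non-increasing and never drops below the floor.
    """
    t = growth.time_h
    c = np.empty_like(t)
    c[0] = spec.initial_mg_per_l
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        c[i] = max(spec.floor_mg_per_l, c[i - 1] - spec.uptake_rate * growth.log_cfu[i - 1] * dt)
    return PbSeries(t, c, reactor_id=reactor_id or growth.reactor_id)


def params_from_growth(linkage: LinkageModel, growth: GrowthSeries,
                       condition: str | None = None) -> list[CircuitParams]:
    """Ground-truth circuit parameters at each sampling time of a culture."""
    cond = condition or growth.condition
    return [linkage.params_at(float(l), cond) for l in growth.log_cfu]


def simulate_spectrum(
    params: CircuitParams,
    grid: FrequencyGrid,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
    r_series_ohm: float = DEFAULT_R_SERIES_OHM,
    reactor_id: str = "r1",
    time_h: float = 0.0,
    condition: str = "without_pb",
) -> ImpedanceSpectrum:
    """One noisy sweep from ground-truth parameters.

    Observed reactance is X_model(ω) + ε_abs + ε_rel·|X_model(ω)| with
    independent Gaussian draws from the seeded stream.  The real channel is a
    constant series resistance (the model describes only the reactance).
    """
    from .circuit import canonical_model_reactance

    x = canonical_model_reactance(params, grid)
    noise = noise or NoiseSpec(0.0, 0.0)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if noise.sigma_abs > 0 or noise.sigma_rel > 0:
        eps = noise.sigma_abs * rng.standard_normal(x.size)
        eps = eps + noise.sigma_rel * np.abs(x) * rng.standard_normal(x.size)
        x = x + eps
    z = np.full(x.size, r_series_ohm, dtype=float) + 1j * x
    return ImpedanceSpectrum(grid, z, reactor_id=reactor_id, time_h=time_h, condition=condition)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full in-silico experiment: reactors × conditions × hourly sweeps."""

    preset: str = "kpneumoniae_like"
    n_reactors: int = 3
    hours: tuple[float, ...] = tuple(float(h) for h in range(0, 10))
    conditions: tuple[str, ...] = ("with_pb", "without_pb")
    noise: NoiseSpec = NoiseSpec()
    grid_f_min_hz: float = 10.0
    grid_f_max_hz: float = 1.0e6
    grid_n_points: int = 61
    pb: PbDepletionSpec = PbDepletionSpec()
    r_series_ohm: float = DEFAULT_R_SERIES_OHM

    def grid(self) -> FrequencyGrid:
        return FrequencyGrid.default(self.grid_f_min_hz, self.grid_f_max_hz, self.grid_n_points)


def simulate_experiment(
    config: ExperimentConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """Generate and write a complete synthetic dataset.

    Writes ``spectra.csv`` (rect dialect), ``growth.csv``, ``pb.csv`` and
    ``truth.json`` (every generating parameter, per-sweep ground truth
    included) into ``out_dir``; returns the paths.  Identical (config, seed)
    pairs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.noise.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    growth_spec = GROWTH_PRESETS[config.preset]
    linkage = LINKAGE_PRESETS[config.preset]
    grid = config.grid()
    times = np.asarray(config.hours, dtype=float)

    spectra: list[ImpedanceSpectrum] = []
    growth_rows, pb_rows = [], []
    truth_params: list[dict] = []
    reactor_counter = 0
    for condition in config.conditions:
        for i in range(config.n_reactors):
            # physical reactors are distinct vessels: ids unique across conditions
            reactor_counter += 1
            reactor = f"r{reactor_counter}"
            growth = simulate_growth(growth_spec, times, reactor_id=reactor, condition=condition)
            pb0 = config.pb.initial_mg_per_l if condition == "with_pb" else 0.0
            pb_spec = dataclasses.replace(config.pb, initial_mg_per_l=pb0,
                                          floor_mg_per_l=min(config.pb.floor_mg_per_l, pb0))
            pb = simulate_pb(pb_spec, growth)
            params_t = params_from_growth(linkage, growth, condition)
            for t, log_cfu, c_pb, params in zip(times, growth.log_cfu, pb.pb_mg_per_l, params_t):
                spectra.append(
                    simulate_spectrum(
                        params, grid, noise=config.noise, rng=rng,
                        r_series_ohm=config.r_series_ohm,
                        reactor_id=reactor, time_h=float(t), condition=condition,
                    )
                )
                growth_rows.append(
                    {"time_h": t, "reactor_id": reactor, "condition": condition, "log_cfu": log_cfu}
                )
                pb_rows.append({"time_h": t, "reactor_id": reactor, "pb_mg_per_l": c_pb})
                truth_params.append(
                    {"condition": condition, "reactor_id": reactor, "time_h": float(t),
                     "log_cfu": float(log_cfu), **params.to_dict()}
                )

    paths = {
        "spectra": out / "spectra.csv",
        "growth": out / "growth.csv",
        "pb": out / "pb.csv",
        "truth": out / "truth.json",
    }
    write_spectra(spectra, paths["spectra"], dialect="rect")
    pd.DataFrame(growth_rows).to_csv(paths["growth"], index=False, float_format="%.9g")
    pd.DataFrame(pb_rows).to_csv(paths["pb"], index=False, float_format="%.9g")

    truth = {
        "seed": seed,
        "preset": config.preset,
        "growth_spec": dataclasses.asdict(growth_spec),
        "linkage": {
            "neg_a0": dataclasses.asdict(linkage.neg_a0),
            "neg_b0": dataclasses.asdict(linkage.neg_b0),
            "neg_c0": dataclasses.asdict(linkage.neg_c0),
            "neg_d0": dataclasses.asdict(linkage.neg_d0),
            "with_pb_scale": linkage.with_pb_scale,
        },
        "noise": dataclasses.asdict(config.noise),
        "pb": dataclasses.asdict(config.pb),
        "grid": {"f_min_hz": config.grid_f_min_hz, "f_max_hz": config.grid_f_max_hz,
                 "n_points": config.grid_n_points},
        "r_series_ohm": config.r_series_ohm,
        "params_per_sweep": truth_params,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


# --------------------------------------------------------- chemistry helpers


def stock_concentration(mass_g: float, compound_mass_fraction: float, volume_l: float) -> float:
    """Stock concentration (mg/L) of an ion dissolved as a salt.

    E.g. 1.6 g Pb(NO3)2 (Pb mass fraction 207.2/331.2) in 0.1 L gives
    ≈ 1.0008e4 mg/L Pb(II) — 10,000 mg/L at two significant figures.
    """
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    if mass_g < 0:
        raise ValueError("mass must be non-negative")
    if not 0 < compound_mass_fraction <= 1:
        raise ValueError("mass fraction must lie in (0, 1]")
    return mass_g * compound_mass_fraction * 1000.0 / volume_l


def dilution_concentration(v_add_ml: float, c_stock_mg_l: float, v_reactor_ml: float) -> float:
    """Nominal reactor concentration after spiking stock solution.

    The added volume is not counted in the denominator, matching the nominal
    dosing convention (0.8 mL of 10,000 mg/L into 100 mL → 80 mg/L).
    """
    if v_reactor_ml <= 0:
        raise ValueError("reactor volume must be positive")
    if v_add_ml < 0 or c_stock_mg_l < 0:
        raise ValueError("added volume and stock concentration must be non-negative")
    return v_add_ml * c_stock_mg_l / v_reactor_ml
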