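"""Impedance sweep data model and I/O.

An electrochemical impedance spectroscopy (EIS) measurement applies a small
sinusoidal voltage across a pair of electrodes, records the resulting current,
and reports the complex impedance Z = V/I at each frequency of a sweep.  This
module holds the in-memory containers for a single sweep
(:class:`ImpedanceSpectrum`), the polar/rectangular conversions, the
Nyquist-plane projection used throughout EIS practice, and CSV readers/writers
for the long-format sweep tables the rest of the pipeline consumes.

Conventions
-----------
* Frequencies in Hz, impedances in Ω, time in hours.
* Phase angles are degrees in files and public interfaces, wrapped to
  (-180, 180]; radians are used internally.
* Capacitive reactance is stored negative; Nyquist plots show (R, -X) so that
  capacitive arcs land in the first quadrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyGrid",
    "ComplexReading",
    "ImpedanceSpectrum",
    "SinusoidPair",
    "SpectraFormatError",
    "ZeroCurrentError",
    "compute_impedance",
    "polar_to_rect",
    "rect_to_polar",
    "nyquist_points",
    "read_spectra",
    "write_spectra",
]

#: Default sweep bounds used by the measurement protocol this package targets.
DEFAULT_F_MIN_HZ = 10.0
DEFAULT_F_MAX_HZ = 1.0e6
DEFAULT_N_POINTS = 61

POLAR_COLUMNS = ("frequency_hz", "z_mag_ohm", "z_phase_deg")
RECT_COLUMNS = ("frequency_hz", "z_real_ohm", "z_imag_ohm")
META_COLUMNS = ("reactor_id", "time_h", "condition")

CONDITIONS = ("with_pb", "without_pb")


class SpectraFormatError(ValueError):
    """Raised when a sweep table violates the CSV contract."""


class ZeroCurrentError(ValueError):
    """Raised when the current phasor is zero: impedance is unmeasurable."""


def wrap_phase_deg(phase: np.ndarray | float) -> np.ndarray | float:
    """Wrap a phase angle in degrees to the interval (-180, 180]."""
    wrapped = -((-np.asarray(phase) + 180.0) % 360.0 - 180.0)
    return float(wrapped) if np.isscalar(phase) else wrapped


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly ascending, strictly positive frequency sweep.

    Parameters
    ----------
    frequencies : array-like of float
        Sweep frequencies in Hz.  Must be finite, positive, strictly
        ascending with no duplicates.
    """

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(f)):
            raise ValueError("frequency grid contains non-finite values")
        if np.any(f <= 0):
            raise ValueError("frequencies must be strictly positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly ascending (duplicate frequency?)")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def default(
        cls,
        f_min_hz: float = DEFAULT_F_MIN_HZ,
        f_max_hz: float = DEFAULT_F_MAX_HZ,
        n_points: int = DEFAULT_N_POINTS,
    ) -> "FrequencyGrid":
        """Log-spaced grid, 61 points over 10 Hz–1 MHz by default
        (~12 points per decade)."""
        return cls(np.logspace(math.log10(f_min_hz), math.log10(f_max_hz), n_points))

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies ω = 2πf in rad/s."""
        return 2.0 * np.pi * self.frequencies

    @property
    def s(self) -> np.ndarray:
        """Laplace-axis evaluation points s = jω = j·2πf."""
        return 1j * self.omega

    def __len__(self) -> int:
        return self.frequencies.size


@dataclass(frozen=True)
class ComplexReading:
    """One complex impedance sample, accessible in polar or rectangular form."""

    z: complex

    @classmethod
    def from_polar(cls, magnitude: float, phase_deg: float) -> "ComplexReading":
        if magnitude < 0:
            raise ValueError("impedance magnitude must be non-negative")
        return cls(magnitude * np.exp(1j * np.deg2rad(phase_deg)))

    @classmethod
    def from_rect(cls, resistance: float, reactance: float) -> "ComplexReading":
        return cls(complex(resistance, reactance))

    @property
    def magnitude(self) -> float:
        return abs(self.z)

    @property
    def phase_deg(self) -> float:
        if self.z == 0:
            return 0.0
        return wrap_phase_deg(math.degrees(np.angle(self.z)))

    @property
    def resistance(self) -> float:
        return self.z.real

    @property
    def reactance(self) -> float:
        return self.z.imag


@dataclass(frozen=True)
class SinusoidPair:
    """Simultaneously measured voltage and current phasors at one frequency."""

    voltage: complex
    current: complex

    def __post_init__(self) -> None:
        if abs(self.current) == 0:
            raise ZeroCurrentError("zero current phasor: impedance is unmeasurable")


@dataclass
class ImpedanceSpectrum:
    """One sweep: a frequency grid plus one complex impedance per frequency.

    ``reactor_id``, ``time_h`` and ``condition`` identify the sweep within a
    culture experiment; condition is ``"with_pb"`` or ``"without_pb"``.
    """

    grid: FrequencyGrid
    z: np.ndarray
    reactor_id: str = "r1"
    time_h: float = 0.0
    condition: str = "without_pb"

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=complex)
        if z.shape != (len(self.grid),):
            raise ValueError("need exactly one reading per grid frequency")
        if not np.all(np.isfinite(z)):
            raise SpectraFormatError("non-finite impedance value in spectrum")
        self.z = z

    @property
    def resistance(self) -> np.ndarray:
        return self.z.real

    @property
    def reactance(self) -> np.ndarray:
        return self.z.imag

    @property
    def readings(self) -> list[ComplexReading]:
        return [ComplexReading(complex(v)) for v in self.z]

    def plot_nyquist(self, ax=None, **kwargs):
        """Nyquist plot: resistance vs negative reactance, first quadrant
        for capacitive data."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = nyquist_points(self)
        ax.plot(pts[:, 0], pts[:, 1], marker="o", ms=3, **kwargs)
        ax.set_xlabel("R (Ω)")
        ax.set_ylabel("−X (Ω)")
        return ax


def compute_impedance(pair: SinusoidPair) -> ComplexReading:
    """Complex impedance of a voltage/current phasor pair, Z = V/I.

    The magnitude is |V|/|I| and the phase ∠V − ∠I, wrapped to (-180, 180].
    """
    return ComplexReading(pair.voltage / pair.current)


def polar_to_rect(reading: ComplexReading) -> tuple[float, float]:
    """(R, X) = (|Z|·cosθ, |Z|·sinθ) for a polar reading."""
    return reading.resistance, reading.reactance


def rect_to_polar(resistance: float, reactance: float) -> ComplexReading:
    """Inverse of :func:`polar_to_rect`."""
    return ComplexReading.from_rect(resistance, reactance)


def nyquist_points(spectrum: ImpedanceSpectrum) -> np.ndarray:
    """(R, -X) pairs ordered by ascending frequency, shape (n, 2).

    The reactance sign is flipped exactly once so that capacitive sweeps
    (X < 0) plot in the first quadrant.
    """
    return np.column_stack([spectrum.resistance, -spectrum.reactance])


def _infer_dialect(columns: Iterable[str]) -> Literal["polar", "rect"]:
    cols = set(columns)
    if set(POLAR_COLUMNS) <= cols:
        return "polar"
    if set(RECT_COLUMNS) <= cols:
        return "rect"
    raise SpectraFormatError(
        "missing columns: need "
        f"{POLAR_COLUMNS} (polar) or {RECT_COLUMNS} (rect), got {sorted(cols)}"
    )


def read_spectra(path: str | Path, dialect: str | None = None) -> list[ImpedanceSpectrum]:
    """Parse a long-format sweep CSV into a list of spectra.

    The file carries one row per (reactor, hour, frequency) with metadata
    columns ``reactor_id``, ``time_h``, ``condition`` and either polar columns
    (``z_mag_ohm``, ``z_phase_deg``) or rectangular ones (``z_real_ohm``,
    ``z_imag_ohm``).  Rows are grouped by (reactor, time, condition); each
    group becomes one :class:`ImpedanceSpectrum`.
    """
    df = pd.read_csv(path)
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise SpectraFormatError(f"missing columns: {missing_meta}")
    inferred = _infer_dialect(df.columns)
    if dialect is not None and dialect != inferred:
        raise SpectraFormatError(f"declared dialect {dialect!r} but file columns are {inferred!r}")

    value_cols = POLAR_COLUMNS if inferred == "polar" else RECT_COLUMNS
    if not np.all(np.isfinite(df[list(value_cols)].to_numpy(dtype=float))):
        raise SpectraFormatError("non-finite value in sweep table")

    spectra: list[ImpedanceSpectrum] = []
    for (reactor, time_h, condition), g in df.groupby(
        ["reactor_id", "time_h", "condition"], sort=True
    ):
        g = g.sort_values("frequency_hz")
        f = g["frequency_hz"].to_numpy(dtype=float)
        if np.any(np.diff(f) == 0):
            raise SpectraFormatError(
                f"duplicate frequency in sweep ({reactor}, t={time_h} h)"
            )
        grid = FrequencyGrid(f)
        if inferred == "polar":
            z = g["z_mag_ohm"].to_numpy(float) * np.exp(
                1j * np.deg2rad(g["z_phase_deg"].to_numpy(float))
            )
        else:
            z = g["z_real_ohm"].to_numpy(float) + 1j * g["z_imag_ohm"].to_numpy(float)
        spectra.append(
            ImpedanceSpectrum(grid, z, reactor_id=str(reactor), time_h=float(time_h), condition=str(condition))
        )
    return spectra


def write_spectra(
    spectra: Sequence[ImpedanceSpectrum],
    path: str | Path,
    dialect: Literal["polar", "rect"] = "rect",
) -> None:
    """Write spectra to a long-format CSV (inverse of :func:`read_spectra`)."""
    rows = []
    for sp in spectra:
        for f, z in zip(sp.grid.frequencies, sp.z):
            row = {
                "reactor_id": sp.reactor_id,
                "time_h": sp.time_h,
                "condition": sp.condition,
                "frequency_hz": f,
            }
            if dialect == "polar":
                row["z_mag_ohm"] = abs(z)
                row["z_phase_deg"] = wrap_phase_deg(math.degrees(np.angle(z))) if z != 0 else 0.0
            elif dialect == "rect":
                row["z_real_ohm"] = z.real
                row["z_imag_ohm"] = z.imag
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
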