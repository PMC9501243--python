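"""Laplace-domain equivalent-circuit reactance model.

The measured electrode/culture impedance is modelled as a short fractional
polynomial in the Laplace variable s = jω,

    Z(s) = a0 + b0·s^p1 + c0·s^-0.5 + d0·s^p2,

whose imaginary part (the reactance X) is what gets fitted.  Each power term
is a classical circuit element or its fractional generalisation:

* ``p = -1``  — ideal capacitor 1/(k1 s),
* ``p = +1``  — ideal inductor k2 s,
* ``p = -0.5`` — Warburg diffusion element, constant -45° phase,
* non-integer ``p`` — constant-phase/fractional element; the fixed low-
  frequency exponent p1 = -1.5 behaves as a fractional-power supercapacitor.

Evaluation uses the principal branch (jω)^p = ω^p·e^{jpπ/2}, so a single
term contributes reactance coeff·ω^p·sin(pπ/2) and holds a constant phase of
p·90° at every frequency.  The constant a0 is treated as a frequency-
independent reactive offset and participates directly in the reactance.

A note on units: b0 multiplies s^-1.5, so it is not a capacitance in the SI
sense even though the element behaves capacitively; coefficients are stored
as raw magnitudes in Ω·(rad/s)^-p pseudo-units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra import FrequencyGrid

__all__ = [
    "CircuitParams",
    "WarburgElement",
    "ElementMagnitudes",
    "WARBURG_EXPONENT",
    "term_reactance",
    "general_model_reactance",
    "canonical_model_reactance",
    "warburg_impedance",
    "capacitor_reactance",
    "inductor_reactance",
]

#: Diffusion (Warburg) exponent; held fixed in both fitting stages.
WARBURG_EXPONENT = -0.5

#: Canonical fixed exponents of the final reactance model.
P1_DEFAULT = -1.5
P2_DEFAULT = 1.0


@dataclass(frozen=True)
class CircuitParams:
    """Coefficients and exponents of the fractional reactance model.

    ``a0`` is a constant reactive offset in Ω; ``b0`` scales the fractional
    supercapacitor term s^p1; ``c0`` the Warburg term s^-0.5; ``d0`` the
    inductive term s^p2 (Henry when p2 = 1).  Coefficients may take either
    sign; capacitive behaviour corresponds to negative b0 and c0.
    """

    a0: float
    b0: float
    c0: float
    d0: float
    p1: float = P1_DEFAULT
    p2: float = P2_DEFAULT

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.a0, self.b0, self.c0, self.d0, self.p1, self.p2])):
            raise ValueError("circuit parameters must be finite")
        if self.p1 >= 0:
            raise ValueError("low-frequency exponent p1 must be negative")
        if self.p2 <= 0:
            raise ValueError("high-frequency exponent p2 must be positive")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a0, self.b0, self.c0, self.d0])

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        return cls(**{k: float(d[k]) for k in ("a0", "b0", "c0", "d0", "p1", "p2")})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CircuitParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class WarburgElement:
    """Diffusion impedance element, Z_W(ω) = A_W·ω^-0.5·(1 − j)."""

    A_W: float

    def __post_init__(self) -> None:
        if self.A_W < 0:
            raise ValueError("Warburg coefficient must be non-negative")


@dataclass(frozen=True)
class ElementMagnitudes:
    """Ideal-element magnitudes: capacitance k1 (F) and inductance k2 (H)."""

    k1: float = 1.0
    k2: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("ideal element magnitudes must be positive")


def _omega(grid: FrequencyGrid | np.ndarray) -> np.ndarray:
    w = grid.omega if isinstance(grid, FrequencyGrid) else np.asarray(grid, dtype=float)
    if np.any(w == 0):
        raise ValueError("ω = 0 is outside the model domain (negative-exponent terms diverge)")
    return w


def term_reactance(coefficient: float, exponent: float, grid: FrequencyGrid | np.ndarray) -> np.ndarray:
    """Imaginary part of coeff·(jω)^p on the principal branch:
    coeff·ω^p·sin(pπ/2)."""
    w = _omega(grid)
    return coefficient * w**exponent * np.sin(exponent * np.pi / 2.0)


def general_model_reactance(
    terms: Sequence[tuple[float, float]],
    a0: float,
    grid: FrequencyGrid | np.ndarray,
) -> np.ndarray:
    """Reactance of an arbitrary fractional polynomial a0 + Σ coeff·s^p.

    ``terms`` is a list of (coefficient, exponent) pairs; ``grid`` may be a
    :class:`FrequencyGrid` or a raw ω array in rad/s.
    """
    w = _omega(grid)
    x = np.full_like(w, float(a0))
    for coeff, expo in terms:
        if not np.isfinite(expo):
            raise ValueError("term exponent must be finite")
        x = x + term_reactance(coeff, expo, w)
    return x


def canonical_model_reactance(params: CircuitParams, grid: FrequencyGrid | np.ndarray) -> np.ndarray:
    """Reactance of the full model a0 + b0·s^p1 + c0·s^-0.5 + d0·s^p2.

    With the canonical exponents (p1, p2) = (-1.5, 1) this reduces to
    X(ω) = a0 − (b0/√2)·ω^-1.5 − (c0/√2)·ω^-0.5 + d0·ω.
    """
    return general_model_reactance(
        [(params.b0, params.p1), (params.c0, WARBURG_EXPONENT), (params.d0, params.p2)],
        params.a0,
        grid,
    )


def warburg_impedance(elem: WarburgElement | float, grid: FrequencyGrid | np.ndarray) -> np.ndarray:
    """Complex Warburg impedance Z_W(ω) = A_W·ω^-0.5·(1 − j).

    Magnitude √2·A_W·ω^-0.5, phase a constant −45°: on a Nyquist plot
    (R vs −X) the element traces the 45° line through the origin.
    """
    a_w = elem.A_W if isinstance(elem, WarburgElement) else WarburgElement(float(elem)).A_W
    w = _omega(grid)
    return a_w * w**WARBURG_EXPONENT * (1.0 - 1.0j)


def capacitor_reactance(k1: float, grid: FrequencyGrid | np.ndarray) -> np.ndarray:
    """Ideal capacitor 1/(k1·s): reactance −1/(k1·ω)."""
    if k1 <= 0:
        raise ValueError("capacitance must be positive")
    return term_reactance(1.0 / k1, -1.0, grid)


def inductor_reactance(k2: float, grid: FrequencyGrid | np.ndarray) -> np.ndarray:
    """Ideal inductor k2·s: reactance k2·ω."""
    if k2 <= 0:
        raise ValueError("inductance must be positive")
    return term_reactance(k2, 1.0, grid)
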