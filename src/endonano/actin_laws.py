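"""Closed-form force and rate laws of force-generating actin assembly.

Brownian-ratchet polymerization kinetics under load, the resulting stall
force, Kramers force-accelerated crosslinker unbinding, and the piecewise
membrane invagination resistance with its snap-through collapse.  Values
are wrapped in unit-tagged quantities so that mixing units inconsistently
fails loudly.

Default parameters: kon = 400 µM⁻¹s⁻¹ (treated as per-concentration so that
kon*A1 is a rate), koff = 1.4 s⁻¹, A1 = 40 µM, δ = 2.8 nm, kBT = 4.114 pN·nm
(25 °C), crosslinker koff = 0.025 s⁻¹ with fu = 10 pN, and a lift force of
200 pN collapsing at 60 nm depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: thermal energy at 25 °C, pN·nm
KBT_DEFAULT = 4.114


@dataclass(frozen=True)
class Quantity:
    """A number tagged with a unit string; add/sub require matching units."""

    value: float
    unit: str

    def __add__(self, other: "Quantity") -> "Quantity":
        self._check(other)
        return Quantity(self.value + other.value, self.unit)

    def __sub__(self, other: "Quantity") -> "Quantity":
        self._check(other)
        return Quantity(self.value - other.value, self.unit)

    def _check(self, other) -> None:
        if not isinstance(other, Quantity):
            raise TypeError("can only combine Quantity with Quantity")
        if other.unit != self.unit:
            raise ValueError(f"unit mismatch: {self.unit!r} vs {other.unit!r}")

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class RatchetParams:
    """Brownian-ratchet polymerization parameters.

    ``kon`` in µM⁻¹·s⁻¹, ``koff`` in s⁻¹, ``A1`` (free monomer
    concentration) in µM, ``delta`` (added-monomer extension) in nm,
    ``kBT`` in pN·nm.
    """

    kon: float = 400.0
    koff: float = 1.4
    A1: float = 40.0
    delta: float = 2.8
    kBT: float = KBT_DEFAULT

    def __post_init__(self) -> None:
        for name in ("kon", "koff", "A1", "delta", "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def critical_concentration(self) -> Quantity:
        """A1* = koff / kon, µM."""
        return Quantity(self.koff / self.kon, "uM")


@dataclass
class CrosslinkerParams:
    """Kramers unbinding: zero-force rate ``koff0`` (s⁻¹), force scale ``fu`` (pN)."""

    koff0: float = 0.025
    fu: float = 10.0

    def __post_init__(self) -> None:
        if self.koff0 <= 0 or self.fu <= 0:
            raise ValueError("koff0 and fu must be positive")


@dataclass
class InvaginationLaw:
    """Piecewise resistance to membrane invagination.

    A lift force ``f0`` (pN) is needed to start pulling the membrane; the
    resistance then grows linearly with slope ``k_pi`` (pN/nm) until the
    snap-through depth ``L0`` (nm), beyond which it collapses to zero.
    """

    f0: float = 200.0
    k_pi: float = 800.0 / 60.0  # rises to 1000 pN at 60 nm with defaults
    L0: float = 60.0

    def __post_init__(self) -> None:
        if self.f0 < 0:
            raise ValueError("f0 must be >= 0")
        if not self.L0 > 0:
            raise ValueError("L0 must be > 0")


def polymerization_rate(p: RatchetParams, force: float) -> tuple[Quantity, Quantity]:
    """Loaded barbed-end kinetics: (k+, k-) in s⁻¹.

    k+ = kon * A1 * exp(-f*delta/kBT); k- = koff, independent of force.
    """
    if force < 0:
        raise ValueError("force must be >= 0")
    k_plus = p.kon * p.A1 * math.exp(-force * p.delta / p.kBT)
    return Quantity(k_plus, "1/s"), Quantity(p.koff, "1/s")


def stall_force(p: RatchetParams) -> Quantity:
    """Force at which net assembly stops: kBT * ln(A1/A1*) / delta, pN."""
    a1_star = p.critical_concentration.value
    if p.A1 < a1_star:
        raise ValueError("A1 must be at least the critical concentration A1*")
    return Quantity(p.kBT * math.log(p.A1 / a1_star) / p.delta, "pN")


def crosslinker_unbinding_rate(c: CrosslinkerParams, force: float) -> Quantity:
    """Kramers law: ku = koff0 * exp(f/fu), s⁻¹."""
    if force < 0:
        raise ValueError("force must be >= 0")
    return Quantity(c.koff0 * math.exp(force / c.fu), "1/s")


def invagination_resistance(law: InvaginationLaw, L: float) -> Quantity:
    """Resistance (pN) at invagination depth ``L`` (nm).

    Zero for L <= 0, affine ``f0 + k_pi * L`` on (0, L0), and zero again at
    and beyond the snap-through depth L0.
    """
    if L <= 0 or L >= law.L0:
        return Quantity(0.0, "pN")
    return Quantity(law.f0 + law.k_pi * L, "pN")
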