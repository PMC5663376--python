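"""1D scatter profiles with an explicit unit-state machine.

A :class:`ScatterProfile` is an intensity-vs-q curve carrying a per-point
spread and a unit state that advances only in the fixed correction order
raw_rate → dark_corrected → transmission_normalized → background_subtracted
→ absolute.  The state machine enforces that the four-step correction chain
is applied strictly in order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np


class UnitState(enum.IntEnum):
    raw_rate = 0
    dark_corrected = 1
    transmission_normalized = 2
    background_subtracted = 3
    absolute = 4


class GridError(ValueError):
    """Two profiles do not share the same q grid."""


class UnitStateError(ValueError):
    """A correction was applied out of order."""


@dataclass
class ScatterProfile:
    """Radially averaged 1D scatter profile.

    Parameters
    ----------
    q : strictly increasing grid, nm⁻¹.
    intensity : per-q values (units depend on ``unit_state``; absolute
        profiles are in cm⁻¹ sr⁻¹).
    sigma : per-q spread, same units as intensity.
    unit_state : position in the correction chain.
    provenance : ordered list of applied corrections.
    npix : pixels contributing per bin (radial averages only).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    unit_state: UnitState = UnitState.raw_rate
    provenance: list[str] = field(default_factory=list)
    npix: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is None:
            self.sigma = np.zeros_like(self.intensity)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        self.unit_state = UnitState(self.unit_state)

    # -- helpers ---------------------------------------------------------
    def require_state(self, state: UnitState) -> None:
        if self.unit_state != state:
            raise UnitStateError(
                f"profile is {self.unit_state.name}, expected {state.name}"
            )

    def same_grid(self, other: "ScatterProfile") -> None:
        if self.q.shape != other.q.shape or not np.allclose(self.q, other.q):
            raise GridError("profiles do not share a q grid")

    def evolve(self, *, step: str, new_state: UnitState, **changes) -> "ScatterProfile":
        if int(new_state) != int(self.unit_state) + 1:
            raise UnitStateError(
                f"cannot go from {self.unit_state.name} to {new_state.name}"
            )
        out = replace(self, unit_state=new_state, **changes)
        out.provenance = list(self.provenance) + [step]
        return out

    def window_slice(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        mask = (self.q >= lo) & (self.q <= hi)
        if not np.any(mask):
            raise ValueError(f"window {window} contains no grid points")
        return mask

    def value_at(self, q0: float) -> float:
        """Intensity at the bin nearest q0 (nearest-bin lookup)."""
        if q0 < self.q[0] or q0 > self.q[-1]:
            raise ValueError(f"q0={q0} outside profile range")
        return float(self.intensity[int(np.argmin(np.abs(self.q - q0)))])

    # -- plain-text I/O --------------------------------------------------
    def save_txt(self, path) -> None:
        header = (
            f"unit_state: {self.unit_state.name}\n"
            f"provenance: {' | '.join(self.provenance)}\n"
            "q_nm_inv intensity sigma"
        )
        np.savetxt(path, np.column_stack([self.q, self.intensity, self.sigma]),
                   header=header)

    @classmethod
    def load_txt(cls, path) -> "ScatterProfile":
        state = UnitState.raw_rate
        prov: list[str] = []
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if body.startswith("unit_state:"):
                    state = UnitState[body.split(":", 1)[1].strip()]
                elif body.startswith("provenance:"):
                    txt = body.split(":", 1)[1].strip()
                    prov = [p.strip() for p in txt.split("|") if p.strip()]
        data = np.loadtxt(path)
        return cls(q=data[:, 0], intensity=data[:, 1], sigma=data[:, 2],
                   unit_state=state, provenance=prov)
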