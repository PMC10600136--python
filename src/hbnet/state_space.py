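"""Ten-state fixed-reference ordinal partition of the hemoglobin signal.

The five components share two degrees of freedom, so their joint sign
pattern is determined by position in the (total, sat) plane.  Each
component's null line passes through the origin of that plane; the five
lines partition it into ten sectors, and only the ten sign patterns realized
by those sectors are admissible (out of 32 conceivable ones).

Within the linearized dependency model (valid for deviations small relative
to the absolute baselines)::

    oxy   ~  s0 * total + (total0 / 100) * sat
    deoxy =  total - oxy
    exc   =  total - 2 * oxy

where ``s0`` is the baseline saturation fraction and ``total0`` the molar
baseline; ``total`` is in molar, ``sat`` in percent.

State numbering convention: State 1 is the sector whose lower boundary is
the positive ``total`` half-axis (i.e. the sector just above it), and labels
increase counterclockwise.  All downstream quantities are invariant to
cyclic relabeling; ``relabel`` applies a cyclic shift if another convention
is preferred.

Zero handling: an exactly-zero component deviation is treated as positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .hb_signal import COMPONENTS, DEFAULT_S0, DEFAULT_TOTAL0, HbImageTimeSeries

__all__ = [
    "StateGeometry",
    "TransitionType",
    "InvalidGeometryError",
    "StateAssignmentError",
    "build_geometry",
    "assign_states",
    "transition_class",
    "reversal_category",
    "decode_transition",
    "transition_types",
    "N_STATES",
    "N_TRANSITION_TYPES",
]

N_STATES = 10
N_TRANSITION_TYPES = N_STATES * N_STATES


class InvalidGeometryError(ValueError):
    """Raised for geometrically impossible (s0, total0) parameters."""


class StateAssignmentError(ValueError):
    """Raised when too many observations have inadmissible sign patterns."""


@dataclass(frozen=True)
class StateGeometry:
    """Null-line angles and the sector -> sign-vector table.

    ``sector_table`` lists, for states 1..10 in counterclockwise order, the
    sign vector (signs of deoxy, exc, oxy, sat, total; each +1 or -1).
    ``boundary_angles`` are the 10 sector lower-boundary angles in
    ``[0, 2*pi)``, in the same order; sector ``i`` spans
    ``[boundary_angles[i], boundary_angles[i+1])``.
    """

    s0: float
    total0: float
    null_angles: Dict[str, float]           # component -> line angle mod pi
    sector_table: Tuple[Tuple[int, ...], ...]
    boundary_angles: Tuple[float, ...]

    def sign_vector(self, state: int) -> Tuple[int, ...]:
        if not 1 <= state <= N_STATES:
            raise ValueError(f"state must be in 1..{N_STATES}, got {state}")
        return self.sector_table[state - 1]

    def state_of_signs(self, signs: Sequence[int]) -> int:
        """State label for a sign vector, or -1 if inadmissible."""
        try:
            return self.sector_table.index(tuple(signs)) + 1
        except ValueError:
            return -1

    def relabel(self, shift: int) -> "StateGeometry":
        """Cyclically shift state labels (new State 1 = old State 1+shift)."""
        shift %= N_STATES
        return StateGeometry(
            s0=self.s0,
            total0=self.total0,
            null_angles=dict(self.null_angles),
            sector_table=tuple(
                self.sector_table[(i + shift) % N_STATES] for i in range(N_STATES)
            ),
            boundary_angles=tuple(
                self.boundary_angles[(i + shift) % N_STATES] for i in range(N_STATES)
            ),
        )

    # -- plain-text round trip -------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "s0": self.s0,
                "total0": self.total0,
                "null_angles": self.null_angles,
                "sector_table": [list(v) for v in self.sector_table],
                "boundary_angles": list(self.boundary_angles),
                "components": list(COMPONENTS),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "StateGeometry":
        d = json.loads(text)
        return cls(
            s0=float(d["s0"]),
            total0=float(d["total0"]),
            null_angles={k: float(v) for k, v in d["null_angles"].items()},
            sector_table=tuple(tuple(int(s) for s in row) for row in d["sector_table"]),
            boundary_angles=tuple(float(a) for a in d["boundary_angles"]),
        )


def _sign_functionals(s0: float, total0: float) -> Dict[str, Tuple[float, float]]:
    """Coefficients (a, b) such that component ~ a*total + b*sat in the plane."""
    c = total0 / 100.0
    return {
        "deoxy": (1.0 - s0, -c),
        "exc": (1.0 - 2.0 * s0, -2.0 * c),
        "oxy": (s0, c),
        "sat": (0.0, 1.0),
        "total": (1.0, 0.0),
    }


def build_geometry(s0: float = DEFAULT_S0, total0: float = DEFAULT_TOTAL0) -> StateGeometry:
    """Construct the ten-sector geometry for baselines (s0, total0)."""
    if not 0.0 < s0 < 1.0 or total0 <= 0.0:
        raise InvalidGeometryError(f"need 0 < s0 < 1 and total0 > 0, got {s0}, {total0}")
    if not 0.5 < s0 < 1.0:
        warnings.warn(
            f"s0={s0} is outside the canonical (0.5, 1) regime; proceeding",
            stacklevel=2,
        )

    funcs = _sign_functionals(s0, total0)
    # null line of component = {a*x + b*y = 0}; angle of the line mod pi
    null_angles = {
        name: float(np.arctan2(a, -b) % np.pi) for name, (a, b) in funcs.items()
    }
    if len({round(v, 12) for v in null_angles.values()}) != 5:
        raise InvalidGeometryError(
            f"null lines are not distinct for s0={s0}, total0={total0}"
        )

    # ten boundary rays: both half-lines of each null line
    rays = sorted({(ang) % (2 * np.pi) for ang in null_angles.values()}
                  | {(ang + np.pi) % (2 * np.pi) for ang in null_angles.values()})
    rays = np.array(rays)
    # rotate so the first boundary is the positive-total half-axis (angle 0)
    start = int(np.argmin(np.abs(rays)))
    rays = np.concatenate([rays[start:], rays[:start] + 2 * np.pi])

    table: List[Tuple[int, ...]] = []
    for i in range(N_STATES):
        mid = 0.5 * (rays[i] + rays[i + 1] if i + 1 < len(rays) else rays[i] + rays[0] + 2 * np.pi)
        x, y = np.cos(mid), np.sin(mid)
        signs = tuple(
            1 if funcs[name][0] * x + funcs[name][1] * y >= 0 else -1
            for name in COMPONENTS
        )
        table.append(signs)
    if len(set(table)) != N_STATES:
        raise InvalidGeometryError("sectors do not realize 10 distinct sign vectors")

    return StateGeometry(
        s0=float(s0),
        total0=float(total0),
        null_angles=null_angles,
        sector_table=tuple(table),
        boundary_angles=tuple(float(a % (2 * np.pi)) for a in rays[:N_STATES]),
    )


def _signs_with_zero_positive(x: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(x) >= 0, 1, -1)


def assign_states(
    series: HbImageTimeSeries,
    geometry: StateGeometry,
    max_fallback_rate: float = 0.01,
) -> np.ndarray:
    """Map each (frame, voxel) sample to its state label 1..10.

    Primary assignment matches the observed signs of the five components
    (exact zeros counted as positive) against the sector table.  Samples
    whose observed sign vector is inadmissible -- possible when the data do
    not satisfy the linear dependencies exactly -- fall back to the sector
    functionals evaluated in the (total, sat) plane.  A fallback rate above
    ``max_fallback_rate`` raises :class:`StateAssignmentError`.
    """
    signs = np.stack(
        [_signs_with_zero_positive(series[name]) for name in COMPONENTS], axis=-1
    )
    # encode sign vectors as 5-bit keys for a table lookup
    bits = (signs > 0).astype(np.int64)
    keys = (
        bits[..., 0] * 16 + bits[..., 1] * 8 + bits[..., 2] * 4
        + bits[..., 3] * 2 + bits[..., 4]
    )
    lut = np.full(32, -1, dtype=np.int64)
    for idx, vec in enumerate(geometry.sector_table):
        key = sum(int(v > 0) << (4 - i) for i, v in enumerate(vec))
        lut[key] = idx + 1
    states = lut[keys]

    # an all-zero sample sits at the plane origin, where the
    # zero-as-positive rule has no sector to point at; State 1 by convention
    all_zero = np.ones(states.shape, dtype=bool)
    for name in COMPONENTS:
        all_zero &= series[name] == 0
    states[all_zero & (states < 0)] = 1

    bad = states < 0
    n_bad = int(bad.sum())
    if n_bad:
        rate = n_bad / states.size
        if rate > max_fallback_rate:
            raise StateAssignmentError(
                f"{n_bad}/{states.size} samples ({100 * rate:.2f}%) have "
                "inadmissible sign vectors; inputs likely violate the "
                "component dependencies"
            )
        states[bad] = _states_from_plane(
            series["total"][bad], series["sat"][bad], geometry
        )
    return states


def _states_from_plane(
    total: np.ndarray, sat: np.ndarray, geometry: StateGeometry
) -> np.ndarray:
    """Sector lookup from (total, sat) coordinates via the sign functionals.

    Always yields an admissible state (zero deviations count as positive).
    """
    total = np.asarray(total, dtype=float)
    sat = np.asarray(sat, dtype=float)
    funcs = _sign_functionals(geometry.s0, geometry.total0)
    bits = [
        (funcs[name][0] * total + funcs[name][1] * sat >= 0).astype(np.int64)
        for name in COMPONENTS
    ]
    keys = bits[0] * 16 + bits[1] * 8 + bits[2] * 4 + bits[3] * 2 + bits[4]
    lut = np.full(32, -1, dtype=np.int64)
    for idx, vec in enumerate(geometry.sector_table):
        key = sum(int(v > 0) << (4 - i) for i, v in enumerate(vec))
        lut[key] = idx + 1
    out = lut[keys]
    if np.any(out < 0):
        # the only point whose zero-as-positive sign vector can be
        # inadmissible is the exact origin (all functionals zero); assign it
        # to State 1 as a documented tie-break
        bad = out < 0
        if np.any((np.broadcast_to(total, out.shape)[bad] != 0)
                  | (np.broadcast_to(sat, out.shape)[bad] != 0)):
            raise StateAssignmentError("plane lookup produced inadmissible sign vector")
        out = np.where(bad, 1, out)
    return out


def transition_class(s1, s2):
    """Cyclic sector distance m in 0..5 between two states (arrays ok)."""
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    if np.any((s1 < 1) | (s1 > N_STATES)) or np.any((s2 < 1) | (s2 > N_STATES)):
        raise ValueError("states must be in 1..10")
    d = np.abs(s1 - s2)
    m = np.minimum(d, N_STATES - d)
    return m if m.ndim else int(m)


def decode_transition(k) -> Tuple[np.ndarray, np.ndarray]:
    """(pre, post) states for transition-type index k in 1..100."""
    k = np.asarray(k)
    if np.any((k < 1) | (k > N_TRANSITION_TYPES)):
        raise ValueError("transition type index must be in 1..100")
    s1 = np.ceil(k / N_STATES).astype(int)
    s2 = (k - N_STATES * (s1 - 1)).astype(int)
    return s1, s2


@dataclass(frozen=True)
class TransitionType:
    """Decoded transition type: index, states, Class, per-component reversals."""

    k: int
    s1: int
    s2: int
    class_m: int
    reversal_flags: Dict[str, bool]

    @classmethod
    def from_index(cls, k: int, geometry: StateGeometry) -> "TransitionType":
        s1, s2 = decode_transition(k)
        v1 = geometry.sign_vector(int(s1))
        v2 = geometry.sign_vector(int(s2))
        flags = {name: v1[i] != v2[i] for i, name in enumerate(COMPONENTS)}
        return cls(
            k=int(k), s1=int(s1), s2=int(s2),
            class_m=transition_class(int(s1), int(s2)),
            reversal_flags=flags,
        )


def transition_types(geometry: StateGeometry) -> List[TransitionType]:
    """All 100 decoded transition types, in index order."""
    return [TransitionType.from_index(k, geometry) for k in range(1, N_TRANSITION_TYPES + 1)]


def reversal_category(k: int, component: str, geometry: StateGeometry) -> int:
    """1 if ``component``'s algebraic sign differs between pre and post states."""
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")
    return int(TransitionType.from_index(k, geometry).reversal_flags[component])
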