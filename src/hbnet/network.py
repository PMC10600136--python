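"""Transition matrix and adjacency-matrix coefficient suites.

Given a state matrix ``S`` (N_t x N_v, values 1..10), the transition-type
matrix is ``T = 10*(S[:-1] - 1) + S[1:]`` ((N_t - 1) x N_v, values 1..100);
self-transitions are counted.  From ``T`` and the component matrices, 18
coefficient classes are computed per transition type:

* 3 state-based: transition probability (percent), pre- and post-transition
  dwell times (seconds);
* 15 component-based: pre-transition mean, post-transition mean and flux for
  each of the five components.

Coefficients for transition types that never occur are NaN (missing), never
zero.  The default averaging scheme is the grand average (GA); TMSM and SMTM
average first over one dimension, then the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .hb_signal import COMPONENTS, DEFAULT_FRAME_RATE, HbImageTimeSeries
from .state_space import (
    N_STATES,
    N_TRANSITION_TYPES,
    StateGeometry,
    assign_states,
    decode_transition,
    transition_class,
)

__all__ = [
    "TransitionMatrix",
    "AdjacencySuite",
    "AVERAGING_SCHEMES",
    "transition_index",
    "transition_counts",
    "probabilities",
    "dwell_times",
    "component_transition_stats",
    "adjacency_suite",
    "group_mean_suite",
]

AVERAGING_SCHEMES = ("GA", "TMSM", "SMTM")

#: The 18 coefficient-class names, in canonical order.
COEFFICIENT_CLASSES: Tuple[str, ...] = (
    ("P", "tau_pre", "tau_post")
    + tuple(f"mu_pre_{x}" for x in COMPONENTS)
    + tuple(f"mu_post_{x}" for x in COMPONENTS)
    + tuple(f"flux_{x}" for x in COMPONENTS)
)


@dataclass(frozen=True)
class TransitionMatrix:
    """(N_t - 1) x N_v integer matrix of transition-type indices 1..100."""

    T: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.T)
        if T.ndim != 2 or T.size == 0:
            raise ValueError("transition matrix must be a nonempty 2-D array")
        if T.min() < 1 or T.max() > N_TRANSITION_TYPES:
            raise ValueError("transition-type indices must lie in 1..100")
        object.__setattr__(self, "T", T.astype(np.int64))

    @property
    def n_timesteps(self) -> int:
        return self.T.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.T.shape[1]


def transition_index(S: np.ndarray) -> TransitionMatrix:
    """Synchronous transition-type matrix from a state matrix."""
    S = np.asarray(S)
    if S.ndim == 1:
        S = S[:, None]
    if S.shape[0] < 2:
        raise ValueError("need at least 2 time frames to form transitions")
    if S.min() < 1 or S.max() > N_STATES:
        raise ValueError("state values must lie in 1..10")
    T = N_STATES * (S[:-1] - 1) + S[1:]
    return TransitionMatrix(T=T)


def transition_counts(tm: TransitionMatrix) -> np.ndarray:
    """100-vector of occurrence counts per transition type."""
    return np.bincount(tm.T.ravel(), minlength=N_TRANSITION_TYPES + 1)[1:]


def probabilities(counts: np.ndarray) -> np.ndarray:
    """Counts -> percent probabilities; sums to 100."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no transitions counted")
    return 100.0 * counts / total


def _runs(column: np.ndarray) -> List[Tuple[int, int, int]]:
    """Maximal constant runs of a 1-D array as (value, start, length)."""
    n = len(column)
    boundaries = np.flatnonzero(column[1:] != column[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])
    return [(int(column[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def dwell_times(
    S: np.ndarray,
    frame_rate: float = DEFAULT_FRAME_RATE,
    counts: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean pre- and post-transition dwell times (seconds) per type.

    For a type-k occurrence at time step i (frames i, i+1), the pre-dwell is
    the length of the pre-state run ending at frame i, and the post-dwell is
    the length of the post-state run starting at frame i+1.  Occurrences in
    the first (last) step contribute no pre- (post-) dwell.  For the ten
    self-transition types, a run of length L yields consecutive occurrences
    with dwell values 1..L-1; only the largest value in each such sequence
    enters the sums.  Sums are normalized by the full occurrence counts.
    """
    S = np.asarray(S)
    if S.ndim == 1:
        S = S[:, None]
    tm = transition_index(S)
    if counts is None:
        counts = transition_counts(tm)
    n_ts = tm.n_timesteps

    pre_sum = np.zeros(N_TRANSITION_TYPES)
    post_sum = np.zeros(N_TRANSITION_TYPES)
    for j in range(S.shape[1]):
        runs = _runs(S[:, j])
        for r, (state, start, length) in enumerate(runs):
            k_self = 11 * state - 10
            if length >= 2:
                # self-type occurrences at steps start+1 .. start+length-1
                # (1-based); max pre-dwell (= length-1) sits at the last of
                # them, max post-dwell at the first.
                last_step = start + length - 1
                first_step = start + 1
                if last_step >= 2:
                    pre_sum[k_self - 1] += length - 1
                if first_step <= n_ts - 1:
                    post_sum[k_self - 1] += length - 1
            if r + 1 < len(runs):
                # non-self transition out of this run, at 1-based step
                # start+length (between frames start+length and +1)
                step = start + length
                nxt_state, _, nxt_len = runs[r + 1]
                k = N_STATES * (state - 1) + nxt_state
                if step >= 2:
                    pre_sum[k - 1] += length
                if step <= n_ts - 1:
                    post_sum[k - 1] += nxt_len

    with np.errstate(invalid="ignore", divide="ignore"):
        tau_pre = np.where(counts > 0, pre_sum / counts, np.nan) / frame_rate
        tau_post = np.where(counts > 0, post_sum / counts, np.nan) / frame_rate
    return tau_pre, tau_post


def component_transition_stats(
    X: np.ndarray,
    tm: TransitionMatrix,
    scheme: str = "GA",
    counts: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-type pre-mean, post-mean and flux of one component matrix.

    GA sums over all occurrences simultaneously and normalizes by the type
    count.  TMSM takes the spatial mean over occurrences at each time step,
    then the mean over steps with at least one occurrence; SMTM does the
    transpose.  Missing types yield NaN.
    """
    scheme = scheme.upper()
    if scheme not in AVERAGING_SCHEMES:
        raise ValueError(f"scheme must be one of {AVERAGING_SCHEMES}, got {scheme!r}")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    T = tm.T
    if X.shape != (T.shape[0] + 1, T.shape[1]):
        raise ValueError(
            f"component shape {X.shape} does not align with transitions {T.shape}"
        )
    pre_val = X[:-1]
    post_val = X[1:]
    diff_val = post_val - pre_val

    if scheme == "GA":
        if counts is None:
            counts = transition_counts(tm)
        out = []
        for val in (pre_val, post_val, diff_val):
            sums = np.bincount(
                T.ravel(), weights=val.ravel(), minlength=N_TRANSITION_TYPES + 1
            )[1:]
            with np.errstate(invalid="ignore", divide="ignore"):
                out.append(np.where(counts > 0, sums / counts, np.nan))
        return tuple(out)

    axis = 1 if scheme == "TMSM" else 0  # inner mean over voxels (TMSM) or time
    out = []
    for val in (pre_val, post_val, diff_val):
        acc = np.full(N_TRANSITION_TYPES, np.nan)
        for k in range(1, N_TRANSITION_TYPES + 1):
            mask = T == k
            occ = mask.sum(axis=axis)
            if not occ.any():
                continue
            inner = np.where(
                occ > 0, (val * mask).sum(axis=axis) / np.maximum(occ, 1), np.nan
            )
            acc[k - 1] = np.nanmean(inner)
        out.append(acc)
    return tuple(out)


@dataclass
class AdjacencySuite:
    """The 18 per-transition-type coefficient vectors plus counts.

    Each coefficient is a length-100 vector (NaN where the type never
    occurs), viewable as a 10x10 matrix with rows = pre-transition state.
    """

    coefficients: Dict[str, np.ndarray]
    counts: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    averaging_scheme: str = "GA"
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(COEFFICIENT_CLASSES) - set(self.coefficients)
        if missing:
            raise ValueError(f"missing coefficient classes: {sorted(missing)}")
        for name, v in self.coefficients.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (N_TRANSITION_TYPES,):
                raise ValueError(f"coefficient {name} must be a 100-vector")
            self.coefficients[name] = v

    @property
    def coefficient_classes(self) -> Tuple[str, ...]:
        return COEFFICIENT_CLASSES

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "dwell_flux":
            return self.dwell_flux
        return self.coefficients[name]

    @property
    def P(self) -> np.ndarray:
        return self.coefficients["P"]

    @property
    def dwell_flux(self) -> np.ndarray:
        """Post minus pre dwell time ("dwell-time flux"), seconds."""
        return self.coefficients["tau_post"] - self.coefficients["tau_pre"]

    def matrix(self, name: str) -> np.ndarray:
        """10x10 view of a coefficient (rows: pre-state, cols: post-state)."""
        return self[name].reshape(N_STATES, N_STATES)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (coefficient class, type)."""
        k = np.arange(1, N_TRANSITION_TYPES + 1)
        s1, s2 = decode_transition(k)
        rows = []
        for name in COEFFICIENT_CLASSES:
            rows.append(
                pd.DataFrame(
                    {
                        "coefficient_class": name,
                        "k": k,
                        "s1": s1,
                        "s2": s2,
                        "class_m": transition_class(s1, s2),
                        "value": self.coefficients[name],
                        "count": self.counts,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float = DEFAULT_FRAME_RATE,
                   averaging_scheme: str = "GA") -> "AdjacencySuite":
        coeffs = {}
        counts = np.zeros(N_TRANSITION_TYPES)
        for name, sub in df.groupby("coefficient_class"):
            sub = sub.sort_values("k")
            if len(sub) != N_TRANSITION_TYPES:
                raise ValueError(f"coefficient {name} does not cover all 100 types")
            coeffs[name] = sub["value"].to_numpy(dtype=float)
            counts = sub["count"].to_numpy(dtype=float)
        return cls(coefficients=coeffs, counts=counts,
                   frame_rate=frame_rate, averaging_scheme=averaging_scheme)


def adjacency_suite(
    series: HbImageTimeSeries,
    geometry: StateGeometry,
    scheme: str = "GA",
    states: Optional[np.ndarray] = None,
) -> AdjacencySuite:
    """Compute all 18 coefficient classes for one image time series."""
    if states is None:
        states = assign_states(series, geometry)
    tm = transition_index(states)
    counts = transition_counts(tm)
    coeffs: Dict[str, np.ndarray] = {"P": probabilities(counts)}
    tau_pre, tau_post = dwell_times(states, series.frame_rate, counts=counts)
    coeffs["tau_pre"] = tau_pre
    coeffs["tau_post"] = tau_post
    for name in COMPONENTS:
        mu_pre, mu_post, flux = component_transition_stats(
            series[name], tm, scheme=scheme, counts=counts if scheme == "GA" else None
        )
        coeffs[f"mu_pre_{name}"] = mu_pre
        coeffs[f"mu_post_{name}"] = mu_post
        coeffs[f"flux_{name}"] = flux
    return AdjacencySuite(
        coefficients=coeffs,
        counts=counts,
        frame_rate=series.frame_rate,
        averaging_scheme=scheme.upper(),
    )


def group_mean_suite(suites: Iterable[AdjacencySuite]) -> AdjacencySuite:
    """Missing-aware arithmetic mean of suites, per transition type.

    Types missing in some subjects are averaged over the subjects where they
    are available; per-type availability counts are recorded in ``meta``.
    """
    suites = list(suites)
    if not suites:
        raise ValueError("need at least one suite")
    schemes = {s.averaging_scheme for s in suites}
    coeffs: Dict[str, np.ndarray] = {}
    avail: Dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore"):
        for name in COEFFICIENT_CLASSES:
            stacked = np.stack([s.coefficients[name] for s in suites])
            n_avail = np.sum(~np.isnan(stacked), axis=0)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                coeffs[name] = np.nanmean(stacked, axis=0)
            avail[name] = n_avail
    counts = np.mean(np.stack([s.counts for s in suites]), axis=0)
    return AdjacencySuite(
        coefficients=coeffs,
        counts=counts,
        frame_rate=suites[0].frame_rate,
        averaging_scheme=schemes.pop() if len(schemes) == 1 else "mixed",
        meta={"n_subjects": len(suites), "availability": avail},
    )
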