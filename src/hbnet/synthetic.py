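"""Synthetic inputs, parameter-recovery fixtures, null models and surrogates.

Everything is seeded through :class:`numpy.random.Generator` (PCG64); a
fixed seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .hb_signal import (
    DEFAULT_FRAME_RATE,
    DEFAULT_S0,
    DEFAULT_TOTAL0,
    HbImageTimeSeries,
    compute_dependent_components,
)
from .state_space import (
    N_STATES,
    N_TRANSITION_TYPES,
    StateGeometry,
    build_geometry,
    decode_transition,
)

__all__ = [
    "SimConfig",
    "MarkovFixture",
    "generate_hb_series",
    "markov_amplitude_fixture",
    "michaelis_menten_increments",
    "geometric_null_model",
    "shuffle_time",
    "phase_randomize",
    "surrogate_series",
]


@dataclass
class SimConfig:
    """Parameters of the paired synthetic hemoglobin series generator."""

    n_frames: int = 700
    n_voxels: int = 2000
    frame_rate: float = DEFAULT_FRAME_RATE
    seed: int = 0
    # shared slow oscillation (vasomotor band) in the oxy/deoxy channels
    osc_freqs: Tuple[float, ...] = (0.08, 0.12)       # Hz
    osc_amp: float = 2e-8                             # molar
    # voxel-specific AR(1) noise
    noise_tau: float = 5.0                            # seconds
    noise_sd: float = 3e-8                            # molar
    baseline: Tuple[float, float] = (
        DEFAULT_S0 * DEFAULT_TOTAL0,
        (1.0 - DEFAULT_S0) * DEFAULT_TOTAL0,
    )
    # "affected" series: extra anti-correlated (volume-preserving) noise
    # inflating the saturation-axis spread
    sat_inflation: float = 2.0

    def __post_init__(self) -> None:
        if not 2 <= self.n_frames <= 10 ** 5:
            raise ValueError("n_frames must be in [2, 1e5]")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.osc_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be nonnegative")

    def to_dict(self) -> Dict[str, object]:
        return asdict(self)


def _ar1(rng: np.random.Generator, n_t: int, n_v: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise, one independent process per voxel."""
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    x = np.empty((n_t, n_v))
    x[0] = rng.normal(0.0, sd, n_v)
    eps = rng.normal(0.0, innov_sd, (n_t - 1, n_v))
    for i in range(1, n_t):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return x


def _oscillation(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    t = np.arange(cfg.n_frames) / cfg.frame_rate
    osc = np.zeros(cfg.n_frames)
    for f in cfg.osc_freqs:
        osc += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return cfg.osc_amp * osc / max(len(cfg.osc_freqs), 1)


def generate_hb_series(
    config: SimConfig,
) -> Tuple[HbImageTimeSeries, HbImageTimeSeries]:
    """Paired ("affected", "unaffected") synthetic series.

    Per voxel, oxy and deoxy are a shared slow oscillation (with
    voxel-specific gains) plus independent AR(1) noise.  The affected member
    of the pair carries additional volume-preserving (oxy up, deoxy down)
    noise, inflating its saturation-axis spread by ``sat_inflation`` without
    changing the total-axis spread.
    """
    rng = np.random.default_rng(config.seed)
    rho = float(np.exp(-1.0 / (config.noise_tau * config.frame_rate)))

    def one(affected: bool) -> HbImageTimeSeries:
        osc = _oscillation(rng, config)
        gain_o = rng.uniform(0.5, 1.5, config.n_voxels)
        gain_d = rng.uniform(0.2, 0.8, config.n_voxels)
        oxy = np.outer(osc, gain_o) + _ar1(
            rng, config.n_frames, config.n_voxels, rho, config.noise_sd
        )
        deoxy = np.outer(osc, gain_d) + _ar1(
            rng, config.n_frames, config.n_voxels, rho, config.noise_sd
        )
        if affected and config.sat_inflation > 0:
            extra_sd = config.noise_sd * config.sat_inflation
            extra = _ar1(rng, config.n_frames, config.n_voxels, rho, extra_sd)
            oxy = oxy + extra
            deoxy = deoxy - extra
        return compute_dependent_components(
            oxy, deoxy, baseline=config.baseline, frame_rate=config.frame_rate
        )

    return one(True), one(False)


# ---------------------------------------------------------------------------
# Markov-chain fixtures with controllable statistics

def _state_points(
    geometry: StateGeometry, radius_total: float, radius_sat: float
) -> np.ndarray:
    """Representative (total, sat) coordinates, one interior point per state.

    Sector midpoints are taken in coordinates normalized by the two radii
    (where the sectors are not pathologically thin) and mapped back, which
    keeps each point strictly inside its sector for any radius combination.
    Row ``s - 1`` holds the point for state ``s``.
    """
    from .state_space import _sign_functionals, _states_from_plane

    funcs = _sign_functionals(geometry.s0, geometry.total0)
    # null lines in normalized coordinates (x', y') = (x/rt, y/rs)
    angles = set()
    for a, b in funcs.values():
        ang = float(np.arctan2(a * radius_total, -b * radius_sat) % np.pi)
        angles |= {ang, (ang + np.pi) % (2 * np.pi)}
    rays = np.sort(np.array(list(angles)))
    mids = 0.5 * (rays + np.concatenate([rays[1:], [rays[0] + 2 * np.pi]]))
    x = radius_total * np.cos(mids)
    y = radius_sat * np.sin(mids)
    states = _states_from_plane(x, y, geometry)
    points = np.empty((N_STATES, 2))
    points[states - 1, 0] = x
    points[states - 1, 1] = y
    return points


def _components_from_plane(
    total: np.ndarray, sat: np.ndarray, geometry: StateGeometry
) -> Dict[str, np.ndarray]:
    """Five component matrices from plane coordinates via the linearization."""
    c = geometry.total0 / 100.0
    oxy = geometry.s0 * total + c * sat
    return {
        "deoxy": total - oxy,
        "exc": total - 2.0 * oxy,
        "oxy": oxy,
        "sat": sat,
        "total": total,
    }


@dataclass
class MarkovFixture:
    """State matrix plus component matrices sampled from a Markov chain."""

    states: np.ndarray                      # (n_frames, n_voxels)
    components: Dict[str, np.ndarray]
    geometry: StateGeometry
    frame_rate: float = DEFAULT_FRAME_RATE
    meta: Dict[str, object] = field(default_factory=dict)


def markov_amplitude_fixture(
    P_target: np.ndarray,
    amplitude_model: Optional[Dict[str, float]] = None,
    n_frames: int = 5000,
    n_voxels: int = 1,
    geometry: Optional[StateGeometry] = None,
    seed: int = 0,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> MarkovFixture:
    """Sample a state/component series whose transition-type distribution
    converges to ``P_target`` (percent, sums to 100).

    ``amplitude_model`` holds ``radius_total`` / ``radius_sat`` (scales of
    the per-state representative plane points) and ``jitter`` (relative
    within-sector scatter).  Component values are placed at each state's
    representative point, guaranteeing sign consistency with the sector
    table; a sign-inconsistent model (jitter too large to stay within a
    sector) raises ``ValueError``.

    The realized transition distribution converges to ``P_target`` provided
    the target is balanced (its pre- and post-state marginals coincide), as
    is the case for any stationary chain; unbalanced targets are matched
    only approximately.
    """
    P_target = np.asarray(P_target, dtype=float)
    if P_target.shape != (N_TRANSITION_TYPES,):
        raise ValueError("P_target must be a 100-vector")
    if not np.isclose(P_target.sum(), 100.0):
        raise ValueError(f"P_target must sum to 100, sums to {P_target.sum()}")
    if np.any(P_target < 0):
        raise ValueError("P_target must be nonnegative")
    geometry = geometry or build_geometry()
    model = {"radius_total": 3e-8, "radius_sat": 0.03, "jitter": 0.2}
    model.update(amplitude_model or {})

    joint = (P_target / 100.0).reshape(N_STATES, N_STATES)
    marginal = joint.sum(axis=1)
    if np.any(marginal <= 0):
        raise ValueError("every pre-transition state needs positive probability")
    cond = joint / marginal[:, None]

    rng = np.random.default_rng(seed)
    states = np.empty((n_frames, n_voxels), dtype=np.int64)
    states[0] = rng.choice(N_STATES, size=n_voxels, p=marginal / marginal.sum()) + 1
    u = rng.random((n_frames - 1, n_voxels))
    cum = np.cumsum(cond, axis=1)
    for i in range(1, n_frames):
        row = cum[states[i - 1] - 1]
        states[i] = 1 + (u[i - 1][:, None] > row).sum(axis=1)

    pts = _state_points(geometry, model["radius_total"], model["radius_sat"])
    base = pts[states - 1]                      # (n_frames, n_voxels, 2)
    jitter = model["jitter"]
    if jitter:
        base = base * rng.uniform(1.0 - jitter, 1.0 + jitter, base.shape[:2] + (1,))
    total = base[..., 0]
    sat = base[..., 1]
    components = _components_from_plane(total, sat, geometry)

    # sign consistency of the amplitude model with the sector table
    from .state_space import _states_from_plane  # internal reuse

    check = _states_from_plane(total[:200], sat[:200], geometry)
    if np.any(check != states[:200]):
        raise ValueError("amplitude model produces sign-inconsistent component values")

    return MarkovFixture(
        states=states,
        components=components,
        geometry=geometry,
        frame_rate=frame_rate,
        meta={"P_target": P_target, "model": model, "seed": seed},
    )


def michaelis_menten_increments(
    states: np.ndarray,
    vmax: float,
    km: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    x0: float = 0.0,
) -> np.ndarray:
    """Component matrix whose per-type flux equals Vmax*P/(Km+P).

    ``P`` is the realized transition-type distribution of ``states`` (in
    percent), so the injected flux is exactly consistent with the
    probabilities the analysis pipeline will estimate.  The component is a
    cumulative sum of type-dependent increments plus optional white noise.
    """
    from .network import probabilities, transition_counts, transition_index

    S = np.asarray(states)
    if S.ndim == 1:
        S = S[:, None]
    tm = transition_index(S)
    P = probabilities(transition_counts(tm))
    delta = np.where(P > 0, vmax * P / (km + P), 0.0)
    steps = delta[tm.T - 1]
    X = np.vstack([np.full((1, S.shape[1]), x0), x0 + np.cumsum(steps, axis=0)])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        X = X + rng.normal(0.0, noise_sd, X.shape)
    return X


# ---------------------------------------------------------------------------
# geometric null model

def geometric_null_model(
    geometry: Optional[StateGeometry] = None,
    distance_kernel: Callable[[np.ndarray], np.ndarray] = lambda d: np.exp(-3.0 * d),
    n_samples: int = 200_000,
    radius_total: float = 1.0,
    radius_sat: float = 1.0,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Monte-Carlo pre-transition mean coordinates under a distance-kernel null.

    Point pairs are drawn uniformly from an ellipse-shaped region of the
    (total, sat) plane (axes ``radius_total``, ``radius_sat``) and accepted
    with probability proportional to ``distance_kernel`` of their normalized
    separation.  The kernel must be monotone non-increasing.  Returns the
    per-transition-type mean pre-transition coordinates, per-pre-state
    "spoke" linearity diagnostics (R^2 of a line through the ten same-
    pre-state means), and the post-state ordering along each spoke.
    """
    geometry = geometry or build_geometry()
    grid = np.linspace(0.0, 2.0, 64)
    kv = np.asarray(distance_kernel(grid), dtype=float)
    if np.any(np.diff(kv) > 1e-12) or np.any(kv < 0):
        raise ValueError("distance_kernel must be nonnegative and monotone non-increasing")
    kmax = float(kv.max())
    if kmax <= 0:
        raise ValueError("distance_kernel must be positive somewhere")

    rng = np.random.default_rng(seed)
    from .state_space import _states_from_plane

    accepted_pre = []
    accepted_post = []
    batch = 100_000
    n_acc = 0
    while n_acc < n_samples:
        # uniform over the ellipse via rejection from the bounding box
        p = rng.uniform(-1.0, 1.0, (batch, 2, 2))
        inside = (p[:, :, 0] ** 2 + p[:, :, 1] ** 2 <= 1.0).all(axis=1)
        p = p[inside]
        d = np.hypot(p[:, 0, 0] - p[:, 1, 0], p[:, 0, 1] - p[:, 1, 1])
        keep = rng.random(len(p)) < np.asarray(distance_kernel(d)) / kmax
        p = p[keep]
        accepted_pre.append(p[:, 0] * [radius_total, radius_sat])
        accepted_post.append(p[:, 1] * [radius_total, radius_sat])
        n_acc += len(p)
    pre = np.concatenate(accepted_pre)[:n_samples]
    post = np.concatenate(accepted_post)[:n_samples]

    s1 = _states_from_plane(pre[:, 0], pre[:, 1], geometry)
    s2 = _states_from_plane(post[:, 0], post[:, 1], geometry)
    k = N_STATES * (s1 - 1) + s2

    mean_xy = np.full((N_TRANSITION_TYPES, 2), np.nan)
    counts = np.bincount(k, minlength=N_TRANSITION_TYPES + 1)[1:]
    for col in range(2):
        sums = np.bincount(k, weights=pre[:, col], minlength=N_TRANSITION_TYPES + 1)[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_xy[:, col] = np.where(counts > 0, sums / counts, np.nan)

    spoke_r2 = np.full(N_STATES, np.nan)
    post_order = {}
    for pre_state in range(1, N_STATES + 1):
        idx = np.arange((pre_state - 1) * N_STATES, pre_state * N_STATES)
        xy = mean_xy[idx]
        ok = np.all(np.isfinite(xy), axis=1)
        if ok.sum() < 3:
            continue
        x, y = xy[ok, 0], xy[ok, 1]
        # R^2 of the total-least-squares line through the spoke points
        centered = np.column_stack([x - x.mean(), y - y.mean()])
        svals = np.linalg.svd(centered, compute_uv=False)
        spoke_r2[pre_state - 1] = 1.0 - svals[-1] ** 2 / max(np.sum(svals ** 2), 1e-300)
        # order of post-states by angular position of the spoke points
        ang = np.arctan2(y, x)
        post_order[pre_state] = (np.flatnonzero(ok)[np.argsort(ang)] + 1).tolist()

    return {
        "mean_pre": mean_xy,
        "counts": counts,
        "spoke_r2": spoke_r2,
        "post_state_order": post_order,
    }


# ---------------------------------------------------------------------------
# surrogates

def shuffle_time(X: np.ndarray, seed: int = 0, permutation: Optional[np.ndarray] = None) -> np.ndarray:
    """Permute time frames (one shared permutation across voxels)."""
    X = np.asarray(X)
    if permutation is None:
        permutation = np.random.default_rng(seed).permutation(X.shape[0])
    return X[permutation]


def phase_randomize(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """Fourier-phase randomization preserving each voxel's power spectrum."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n_t = X.shape[0]
    if n_t < 3:
        raise ValueError("phase randomization needs at least 3 frames")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(X, axis=0)
    n_f = spec.shape[0]
    phases = rng.uniform(0, 2 * np.pi, (n_f, X.shape[1]))
    phases[0] = 0.0            # keep DC real
    if n_t % 2 == 0:
        phases[-1] = 0.0       # keep Nyquist real
    surr = np.abs(spec) * np.exp(1j * phases)
    # restore original DC/Nyquist signs (amplitude alone loses them)
    surr[0] = spec[0]
    if n_t % 2 == 0:
        surr[-1] = spec[-1]
    return np.fft.irfft(surr, n=n_t, axis=0)


def surrogate_series(
    series: HbImageTimeSeries, kind: str, seed: int = 0
) -> HbImageTimeSeries:
    """Surrogate of a five-component series.

    The transformation is applied to the independent oxy/deoxy channels and
    the dependent components are recomputed, preserving the elementwise
    identities.  ``kind`` is ``'shuffle_time'`` (one frame permutation
    shared by both channels and all voxels) or ``'phase_randomize'``.
    """
    if kind == "shuffle_time":
        perm = np.random.default_rng(seed).permutation(series.n_frames)
        oxy = shuffle_time(series["oxy"], permutation=perm)
        deoxy = shuffle_time(series["deoxy"], permutation=perm)
    elif kind == "phase_randomize":
        oxy = phase_randomize(series["oxy"], seed=seed)
        deoxy = phase_randomize(series["deoxy"], seed=seed + 1)
    else:
        raise ValueError(f"unknown surrogate kind {kind!r}")
    return compute_dependent_components(
        oxy,
        deoxy,
        baseline=series.baseline,
        frame_rate=series.frame_rate,
        detrend=False,
    )
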