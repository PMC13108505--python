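"""2D epileptor neural-field dynamics and Euler integration.

Each source carries a fast variable ``x`` (proxy for ictal power) and a slow
permittivity variable ``z``:

    dx/dt = 1 - x^3 - 2 x^2 - z + I
    dz/dt = (1/tau) * [ 4 (x - x0) - z
                        - G * sum_j K_ij (xbar_j - xbar_i)
                        - gamma * (W_hom * S(x, theta)) ]

with ``x0`` the per-source tissue excitability, ``G`` the global scaling of
the region-level connectome ``K`` acting on region-average activity ``xbar``,
and ``W_hom * S(x, theta)`` the pseudospectral short-range coupling applied
to the sigmoid-transformed field (cortical grid nodes only; subcortical
point nodes have no local neighbourhood).  An isolated node (G = 0,
gamma = 0) transitions to the seizing upstate when ``x0`` exceeds a critical
value near -2.06 for I = 3.1, consistent with the ~-2.1 excitability bound
of the 2D reduction.

Integration is explicit Euler at dt = 0.05 s for 600 steps, with states
stored every 0.1 s, yielding 300 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .harmonics import LocalCouplingOperator, sigmoid
from .sources import SourceSpace

__all__ = [
    "FieldState",
    "ModelParams",
    "SimulationConfig",
    "SourceTrajectory",
    "IntegrationDivergedError",
    "drift",
    "simulate",
    "isolated_node_threshold",
    "DEFAULT_CURRENT",
]

DEFAULT_CURRENT = 3.1  # external current I of the 2D reduction


class IntegrationDivergedError(RuntimeError):
    """Raised when the Euler solution becomes non-finite."""


@dataclass
class FieldState:
    """Fast/slow state over all sources."""

    x: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if self.x.shape != self.z.shape:
            raise ValueError("x and z must have identical shape")

    @classmethod
    def uniform(cls, n_sources: int, x: float = -2.0, z: float = 5.0) -> "FieldState":
        return cls(np.full(n_sources, x), np.full(n_sources, z))


@dataclass
class ModelParams:
    """Epileptor field parameters.

    ``space`` and ``local_op`` may be ``None`` for isolated-node work, in
    which case the long-range and homogeneous couplings are omitted.
    """

    x0: np.ndarray
    G: float = 1.0
    tau: float = 25.0
    gamma: float = 1.0
    theta: float = -1.0
    I: float = DEFAULT_CURRENT
    K: np.ndarray | None = None
    space: SourceSpace | None = None
    local_op: LocalCouplingOperator | None = None

    def __post_init__(self) -> None:
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.K is not None:
            self.K = np.asarray(self.K, dtype=float)
            if (self.K < 0).any():
                raise ValueError("connectome weights must be nonnegative")
            self._K_rowsum = self.K.sum(axis=1)
        if self.space is not None:
            counts = self.space.region_counts()
            self._counts_safe = np.maximum(counts, 1).astype(float)

    def region_mean(self, x: np.ndarray) -> np.ndarray:
        """Region-average activity xbar (zero for empty regions)."""
        sums = np.bincount(self.space.labels, weights=x, minlength=self.space.n_regions)
        return sums / self._counts_safe

    def long_range(self, x: np.ndarray) -> np.ndarray:
        """Per-source term sum_j K_ij (xbar_j - xbar_i), i = source's region."""
        xbar = self.region_mean(x)
        c_reg = self.K @ xbar - self._K_rowsum * xbar
        return c_reg[self.space.labels]

    def homogeneous(self, x: np.ndarray) -> np.ndarray:
        """Per-source W_hom * S(x, theta); zero on subcortical nodes."""
        out = np.zeros_like(x)
        s = sigmoid(x, self.theta)
        for h in range(2):
            sl = self.space.hemisphere_slice(h)
            out[sl] = self.local_op.apply(s[sl])
        return out


@dataclass
class SimulationConfig:
    dt: float = 0.05  # s
    n_steps: int = 600
    subsample_s: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        ratio = self.subsample_s / self.dt
        self.store_every = int(round(ratio))
        if abs(ratio - self.store_every) > 1e-9 or self.store_every < 1:
            raise ValueError("subsample interval must be an integer multiple of dt")
        if self.n_steps % self.store_every:
            raise ValueError("n_steps must be divisible by the subsample ratio")

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.store_every


@dataclass
class SourceTrajectory:
    """Subsampled state trajectories, frames x sources."""

    x: np.ndarray
    z: np.ndarray
    times_s: np.ndarray
    config: SimulationConfig | None = field(default=None, repr=False)


def drift(state: FieldState, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dx/dt, dz/dt) of the epileptor field."""
    x, z = state.x, state.z
    if not (np.isfinite(x).all() and np.isfinite(z).all()):
        raise IntegrationDivergedError("non-finite state passed to drift")
    dx = 1.0 - x**3 - 2.0 * x**2 - z + params.I
    bracket = 4.0 * (x - params.x0) - z
    if params.G != 0.0 and params.K is not None and params.space is not None:
        bracket = bracket - params.G * params.long_range(x)
    if params.gamma != 0.0 and params.local_op is not None and params.space is not None:
        bracket = bracket - params.gamma * params.homogeneous(x)
    dz = bracket / params.tau
    return dx, dz


def simulate(
    state0: FieldState,
    params: ModelParams,
    config: SimulationConfig | None = None,
    keep_tape: bool = False,
) -> SourceTrajectory | tuple[SourceTrajectory, np.ndarray, np.ndarray]:
    """Explicit-Euler integration with periodic frame storage.

    With ``keep_tape=True``, also return the full per-step state arrays
    ``(x_all, z_all)`` of shape ``(n_steps + 1, n_sources)`` (needed by the
    adjoint gradient of the MAP objective).
    """
    if config is None:
        config = SimulationConfig()
    x = state0.x.astype(float).copy()
    z = state0.z.astype(float).copy()
    n = len(x)
    frames_x = np.empty((config.n_frames, n))
    frames_z = np.empty((config.n_frames, n))
    if keep_tape:
        tape_x = np.empty((config.n_steps + 1, n))
        tape_z = np.empty((config.n_steps + 1, n))
        tape_x[0], tape_z[0] = x, z
    frame = 0
    state = FieldState(x, z)
    for step in range(1, config.n_steps + 1):
        # overflow to inf is the detected divergence condition, not noise
        with np.errstate(over="ignore", invalid="ignore"):
            dx, dz = drift(state, params)
            x = x + config.dt * dx
            z = z + config.dt * dz
        if not (np.isfinite(x).all() and np.isfinite(z).all()):
            raise IntegrationDivergedError(
                f"integration diverged at step {step} (t = {step * config.dt:.2f} s)"
            )
        state = FieldState(x, z)
        if keep_tape:
            tape_x[step], tape_z[step] = x, z
        if step % config.store_every == 0:
            frames_x[frame], frames_z[frame] = x, z
            frame += 1
    times = config.subsample_s * np.arange(1, config.n_frames + 1)
    traj = SourceTrajectory(x=frames_x, z=frames_z, times_s=times, config=config)
    if keep_tape:
        return traj, tape_x, tape_z
    return traj


def _isolated_seizes(
    x0: float, I: float, tau: float, dt: float, n_steps: int
) -> bool:
    """Does a single uncoupled node starting at (-2, 5) reach the upstate?"""
    x, z = -2.0, 5.0
    for _ in range(n_steps):
        dx = 1.0 - x**3 - 2.0 * x**2 - z + I
        dz = (4.0 * (x - x0) - z) / tau
        x += dt * dx
        z += dt * dz
        if x > 0.0:
            return True
    return False


def isolated_node_threshold(
    I: float = DEFAULT_CURRENT,
    bracket: tuple[float, float] = (-2.5, -1.5),
    resolution: float = 0.005,
    tau: float = 10.0,
    horizon_s: float = 200.0,
    dt: float = 0.05,
) -> float:
    """Bisect the critical excitability of an isolated epileptor node.

    Returns the smallest ``x0`` (to within ``resolution``) whose trajectory
    from (x, z) = (-2, 5) crosses ``x > 0`` within the horizon.  ``tau`` only
    rescales the slow timescale and therefore the onset latency, not the
    threshold; a short ``tau`` keeps the horizon modest.
    """
    n_steps = int(round(horizon_s / dt))
    lo, hi = bracket
    seize_lo = _isolated_seizes(lo, I, tau, dt, n_steps)
    seize_hi = _isolated_seizes(hi, I, tau, dt, n_steps)
    if seize_lo or not seize_hi:
        raise ValueError("bracket does not straddle the seizure transition")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _isolated_seizes(mid, I, tau, dt, n_steps):
            hi = mid
        else:
            lo = mid
    return hi
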