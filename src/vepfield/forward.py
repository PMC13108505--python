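"""SEEG forward model: gain matrices, bipolar montage, log-power features.

Source activity reaches a depth-electrode contact with an inverse-square
distance law weighted by the source's cortical surface area,
``G_ij = a_i / d_ij**2`` (no tissue-orientation dependence).  Monopolar
gains for mesh vertices are aggregated onto the pseudospectral grid by
summing over each grid node's nearest-neighbour vertices, which conserves
per-sensor gain mass.  Differences of adjacent contacts on the same
electrode give the bipolar montage, floored at a small positive constant.

The data feature is SEEG log power (SLP): for the model prediction,
``alpha * log(G_bip @ exp(x)) + beta`` evaluated at the 300 stored frames;
for raw recordings, high-pass 10 Hz -> sliding-window power -> log ->
low-pass 0.05 Hz -> resampling to 300 points.  Observed features are
augmented with 50 Gaussian-noise copies (sd 0.1) for optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .epileptor import SourceTrajectory
from .geometry import SphericalBrain, vertex_areas
from .sources import SourceSpace

__all__ = [
    "SensorSet",
    "GainMatrix",
    "SEEGFeatures",
    "monopolar_gain",
    "aggregate_gain",
    "bipolar_gain",
    "predicted_slp",
    "extract_slp",
    "augment",
    "build_gain",
    "N_FEATURE_TIMEPOINTS",
    "MIN_SENSOR_DISTANCE_MM",
    "BIPOLAR_FLOOR",
]

logger = logging.getLogger("vepfield.forward")

N_FEATURE_TIMEPOINTS = 300
MIN_SENSOR_DISTANCE_MM = 1.0  # floor on source-contact distance
BIPOLAR_FLOOR = 1e-12


@dataclass
class SensorSet:
    """Implanted depth-electrode contacts grouped by electrode."""

    contact_ids: list[str]
    electrode_ids: list[str]
    positions_mm: np.ndarray  # (n_contacts, 3)

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float).reshape(-1, 3)
        if not (
            len(self.contact_ids) == len(self.electrode_ids) == len(self.positions_mm)
        ):
            raise ValueError("contact ids, electrode ids and positions must align")
        if not np.isfinite(self.positions_mm).all():
            raise ValueError("sensor positions must be finite")

    @property
    def n_contacts(self) -> int:
        return len(self.contact_ids)

    def bipolar_pairs(self) -> list[tuple[int, int]]:
        """Adjacent contact index pairs within each electrode (input order)."""
        pairs: list[tuple[int, int]] = []
        by_electrode: dict[str, list[int]] = {}
        for i, e in enumerate(self.electrode_ids):
            by_electrode.setdefault(e, []).append(i)
        for e, members in by_electrode.items():
            if len(members) < 2:
                logger.warning("electrode %s has a single contact; no bipolar pair", e)
                continue
            pairs.extend(zip(members[:-1], members[1:]))
        return pairs

    def bipolar_names(self) -> list[str]:
        return [
            f"{self.contact_ids[a]}-{self.contact_ids[b]}"
            for a, b in self.bipolar_pairs()
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contact_id": self.contact_ids,
                "electrode_id": self.electrode_ids,
                "x_mm": self.positions_mm[:, 0],
                "y_mm": self.positions_mm[:, 1],
                "z_mm": self.positions_mm[:, 2],
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "SensorSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            contact_ids=[str(c) for c in df["contact_id"]],
            electrode_ids=[str(e) for e in df["electrode_id"]],
            positions_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        )


@dataclass
class GainMatrix:
    """Monopolar, grid-aggregated and bipolar source-to-sensor gains."""

    monopolar: np.ndarray  # (n_contacts, n_mesh_vertices + n_subcortical)
    aggregated: np.ndarray | None = None  # (n_contacts, n_sources)
    bipolar: np.ndarray | None = None  # (n_pairs, n_sources)
    bipolar_channels: list[str] = field(default_factory=list)


@dataclass
class SEEGFeatures:
    """Log-power features, channels x 300 time points."""

    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("features must be 2-d (channels, time)")
        if not np.isfinite(self.values).all():
            raise ValueError("features must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def save(self, path) -> None:
        np.savez(path, values=self.values, channel_names=np.array(self.channel_names))

    @classmethod
    def load(cls, path) -> "SEEGFeatures":
        data = np.load(path, allow_pickle=False)
        return cls(
            values=data["values"], channel_names=[str(c) for c in data["channel_names"]]
        )


def _mesh_positions_and_areas(brain: SphericalBrain) -> tuple[np.ndarray, np.ndarray]:
    pos, area = [], []
    for h, hemi in enumerate(brain.hemispheres):
        pos.append(brain.hemisphere_centers_mm[h] + brain.radius_mm * hemi.vertices)
        area.append(vertex_areas(hemi, radius_mm=brain.radius_mm))
    return np.vstack(pos), np.concatenate(area)


def monopolar_gain(brain: SphericalBrain, sensors: SensorSet) -> GainMatrix:
    """Inverse-square gain ``a_i / d_ij^2`` from every source to every contact.

    Columns are ordered [hemisphere-0 mesh vertices, hemisphere-1 mesh
    vertices, subcortical nodes].  Subcortical point nodes have no mesh area;
    they are weighted by the mean cortical vertex area so both source kinds
    share a scale.  Distances below ``MIN_SENSOR_DISTANCE_MM`` are clamped.
    """
    positions, areas = _mesh_positions_and_areas(brain)
    if brain.n_subcortical:
        positions = np.vstack([positions, brain.subcortical_positions_mm])
        areas = np.concatenate(
            [areas, np.full(brain.n_subcortical, areas.mean())]
        )
    diff = sensors.positions_mm[:, None, :] - positions[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    n_clamped = int((d < MIN_SENSOR_DISTANCE_MM).sum())
    if n_clamped:
        logger.warning(
            "%d source-contact distances below %.1f mm clamped",
            n_clamped,
            MIN_SENSOR_DISTANCE_MM,
        )
    d = np.maximum(d, MIN_SENSOR_DISTANCE_MM)
    return GainMatrix(monopolar=areas[None, :] / d**2)


def aggregate_gain(gain: GainMatrix, space: SourceSpace) -> GainMatrix:
    """Sum mesh-vertex gains onto each vertex's nearest grid node.

    Subcortical columns pass through unchanged.  Per-sensor gain mass over
    cortical columns is conserved exactly.
    """
    g = gain.monopolar
    n_sub = space.brain.n_subcortical
    agg = np.zeros((g.shape[0], space.n_sources))
    col = 0
    for h in range(2):
        vmap = space.vertex_maps[h]
        n_mesh = space.brain.hemispheres[h].n_vertices
        block = g[:, col : col + n_mesh]
        sl = space.hemisphere_slice(h)
        target = np.zeros((g.shape[0], space.grid.n_nodes))
        np.add.at(target.T, vmap.forward, block.T)
        agg[:, sl] = target
        col += n_mesh
    if n_sub:
        agg[:, space.n_cortical :] = g[:, col : col + n_sub]
    gain.aggregated = agg
    return gain


def bipolar_gain(gain: GainMatrix, sensors: SensorSet) -> GainMatrix:
    """Absolute adjacent-contact differences, floored for positivity."""
    if gain.aggregated is None:
        raise ValueError("aggregate_gain must be applied first")
    pairs = sensors.bipolar_pairs()
    if not pairs:
        raise ValueError("no electrode has two or more contacts")
    rows = [np.abs(gain.aggregated[b] - gain.aggregated[a]) for a, b in pairs]
    gain.bipolar = np.maximum(np.vstack(rows), BIPOLAR_FLOOR)
    gain.bipolar_channels = sensors.bipolar_names()
    return gain


def build_gain(brain: SphericalBrain, space: SourceSpace, sensors: SensorSet) -> GainMatrix:
    """Monopolar -> aggregated -> bipolar pipeline in one call."""
    return bipolar_gain(aggregate_gain(monopolar_gain(brain, sensors), space), sensors)


def predicted_slp(
    x_traj: SourceTrajectory | np.ndarray,
    bipolar: np.ndarray,
    alpha: float = 1.0,
    beta: float = 0.0,
    channel_names: list[str] | None = None,
    strict: bool = True,
) -> SEEGFeatures:
    """Model-predicted SLP: ``alpha * log(G_bip @ exp(x)) + beta``.

    ``x_traj`` provides the fast variable at the stored frames (300 under
    the canonical integration settings; ``strict=False`` lifts the check
    for reduced configurations); the exponential maps it to a positive
    power-like quantity before mixing through the (positive) bipolar
    gains, so the log is finite.
    """
    x = x_traj.x if isinstance(x_traj, SourceTrajectory) else np.asarray(x_traj)
    if strict and x.shape[0] != N_FEATURE_TIMEPOINTS:
        raise ValueError(f"trajectory must have {N_FEATURE_TIMEPOINTS} frames")
    power = np.exp(x) @ bipolar.T  # (time, channels)
    slp = alpha * np.log(power) + beta
    if not np.isfinite(slp).all():
        bad = np.flatnonzero(~np.isfinite(slp).all(axis=0))
        raise ValueError(f"non-finite predicted SLP in channels {bad.tolist()}")
    return SEEGFeatures(values=slp.T, channel_names=channel_names or [])


def extract_slp(
    raw: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.5,
    hp_hz: float = 10.0,
    lp_hz: float = 0.05,
    log_floor: float = 1e-10,
    channel_names: list[str] | None = None,
) -> SEEGFeatures:
    """Empirical SLP from raw sensor time series (channels x samples).

    High-pass at 10 Hz (zero-phase, order 4), mean-square power over a
    sliding window (1 s, 50% overlap), log transform with a small floor,
    zero-phase low-pass at 0.05 Hz to remove short spikes, then uniform
    resampling to exactly 300 points.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if fs <= 2 * hp_hz:
        raise ValueError("sampling rate must exceed twice the high-pass edge")
    win = int(round(window_s * fs))
    hop = max(1, int(round(win * (1.0 - overlap))))
    if raw.shape[1] < win:
        raise ValueError("record shorter than one analysis window")
    sos_hp = signal.butter(4, hp_hz, btype="highpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos_hp, raw, axis=1)
    starts = np.arange(0, raw.shape[1] - win + 1, hop)
    frames = np.stack(
        [filtered[:, s : s + win] for s in starts], axis=1
    )  # (chan, n_win, win)
    power = np.mean(frames**2, axis=2)
    logp = np.log(log_floor + power)
    fs_p = fs / hop
    if 0 < lp_hz < fs_p / 2 and logp.shape[1] > 21:
        sos_lp = signal.butter(2, lp_hz, btype="lowpass", fs=fs_p, output="sos")
        logp = signal.sosfiltfilt(sos_lp, logp, axis=1)
    t_src = np.linspace(0.0, 1.0, logp.shape[1])
    t_dst = np.linspace(0.0, 1.0, N_FEATURE_TIMEPOINTS)
    out = np.stack([np.interp(t_dst, t_src, row) for row in logp])
    return SEEGFeatures(values=out, channel_names=channel_names or [])


def augment(
    features: SEEGFeatures,
    n: int = 50,
    sd: float = 0.1,
    seed: int | None = None,
) -> np.ndarray:
    """``n`` noisy copies (i.i.d. Gaussian, mean 0, given sd) of the features.

    Returns an array of shape ``(n, channels, 300)``.
    """
    if sd < 0:
        raise ValueError("noise standard deviation must be nonnegative")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.repeat(features.values[None, :, :], n, axis=0)
    noise = rng.normal(0.0, sd, size=(n,) + features.values.shape)
    return features.values[None, :, :] + noise
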