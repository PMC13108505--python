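"""Epileptogenic-zone classification and validation statistics.

Sources whose fast variable shows a sustained depolarization shift are given
an onset time; with ``t_lambda`` the earliest onset, sources with onsets
within a tolerance ``t_eps`` of ``t_lambda`` form the epileptogenic zone
(EZ), later onsets the propagation zone, and silent sources are healthy.
Region-level predictions threshold on the percentage of a region's sources
labelled EZ.  Validation against a (resection-style) ground-truth mask uses
precision and recall, paired t tests across seizures, and a power analysis
for the minimum detectable paired effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .epileptor import SourceTrajectory
from .forward import SensorSet
from .sources import SourceSpace

__all__ = [
    "HEALTHY",
    "PROPAGATION",
    "EZ",
    "EZPrediction",
    "ResectionMask",
    "detect_onsets",
    "classify_ez",
    "classify_ez_by_region",
    "classify_sampled_regions",
    "classify_sources_via_regions",
    "quantile_region_onsets",
    "region_labels_to_sources",
    "region_onsets",
    "mask_to_highres",
    "ez_to_parcellation",
    "precision_recall",
    "implantation_coverage",
    "implanted_regions",
    "sampled_regions",
    "paired_t",
    "min_detectable_effect",
]

HEALTHY, PROPAGATION, EZ = 0, 1, 2


@dataclass
class EZPrediction:
    """Per-source onset times (NaN = never seizes) and 3-way labels."""

    onset_times_s: np.ndarray
    labels: np.ndarray  # values in {HEALTHY, PROPAGATION, EZ}
    t_eps_s: float | None = None

    def ez_mask(self) -> np.ndarray:
        return self.labels == EZ


@dataclass
class ResectionMask:
    """Binary resection labels at region level and at source resolution."""

    region_mask: np.ndarray  # (n_regions,) in {0, 1}
    highres_mask: np.ndarray | None = None  # (n_sources,) in {0, 1}


def detect_onsets(
    x_traj: SourceTrajectory | np.ndarray,
    onset_level: float = 0.0,
    min_frames: int = 2,
    times_s: np.ndarray | None = None,
) -> np.ndarray:
    """First time each source's fast variable exceeds ``onset_level`` and
    stays above it for at least ``min_frames`` consecutive frames.

    Returns onset times in seconds, NaN where no sustained crossing occurs.
    """
    if isinstance(x_traj, SourceTrajectory):
        times_s = x_traj.times_s
        x = x_traj.x
    else:
        x = np.atleast_2d(np.asarray(x_traj, dtype=float))
        if times_s is None:
            raise ValueError("times_s required when passing a bare array")
    if not np.isfinite(x).all():
        raise ValueError("trajectory must be finite")
    above = x > onset_level  # (frames, sources)
    n_frames = above.shape[0]
    if min_frames > 1:
        sustained = above[: n_frames - min_frames + 1].copy()
        for k in range(1, min_frames):
            sustained &= above[k : n_frames - min_frames + 1 + k]
    else:
        sustained = above
    onsets = np.full(x.shape[1], np.nan)
    any_onset = sustained.any(axis=0)
    first = np.argmax(sustained, axis=0)
    onsets[any_onset] = np.asarray(times_s)[first[any_onset]]
    return onsets


def classify_ez(onsets: np.ndarray, t_eps_s: float) -> EZPrediction:
    """Label sources EZ / propagation / healthy from their onset times."""
    onsets = np.asarray(onsets, dtype=float)
    labels = np.full(onsets.shape, HEALTHY, dtype=int)
    seizing = np.isfinite(onsets)
    if seizing.any():
        t_lambda = np.nanmin(onsets)
        labels[seizing & (onsets <= t_lambda + t_eps_s)] = EZ
        labels[seizing & (onsets > t_lambda + t_eps_s)] = PROPAGATION
    return EZPrediction(onset_times_s=onsets, labels=labels, t_eps_s=t_eps_s)


def region_onsets(
    onsets: np.ndarray, labels: np.ndarray, n_regions: int
) -> np.ndarray:
    """Region onset = earliest onset among the region's sources (NaN if none)."""
    out = np.full(n_regions, np.nan)
    seizing = np.isfinite(onsets)
    for r in np.unique(labels[seizing]):
        out[r] = onsets[seizing & (labels == r)].min()
    return out


def classify_ez_by_region(
    onsets: np.ndarray, source_labels: np.ndarray, n_regions: int, t_eps_s: float
) -> EZPrediction:
    """Classify at region granularity: a region's onset is the earliest onset
    among its sources, and regions with onsets within ``t_eps_s`` of the
    overall earliest are EZ.  Returns a region-level prediction; broadcast
    to sources with :func:`region_labels_to_sources`."""
    return classify_ez(region_onsets(onsets, source_labels, n_regions), t_eps_s)


def region_labels_to_sources(
    region_pred: EZPrediction, source_labels: np.ndarray
) -> np.ndarray:
    """Per-source labels induced by a region-level classification."""
    return region_pred.labels[np.asarray(source_labels, dtype=int)]


def quantile_region_onsets(
    onsets: np.ndarray,
    source_labels: np.ndarray,
    n_regions: int,
    fraction: float = 0.2,
) -> np.ndarray:
    """Region onset = time at which ``fraction`` of its sources have seized.

    The earliest-member onset is sensitive to a single stray source; the
    fractional onset (the ``ceil(fraction * n)``-th smallest member onset,
    NaN when fewer sources ever seize) requires the same share of a region
    to participate as the vertex-percentage threshold used for
    parcellation-level calls, and is robust to isolated spurious sources.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    source_labels = np.asarray(source_labels, dtype=int)
    out = np.full(n_regions, np.nan)
    for r in range(n_regions):
        member_onsets = onsets[source_labels == r]
        if member_onsets.size == 0:
            continue
        k = int(np.ceil(fraction * member_onsets.size))
        seizing = np.sort(member_onsets[np.isfinite(member_onsets)])
        if seizing.size >= k:
            out[r] = seizing[k - 1]
    return out


def classify_sources_via_regions(
    onsets: np.ndarray, source_labels: np.ndarray, n_regions: int, t_eps_s: float
) -> EZPrediction:
    """Region-granularity classification expressed at source resolution.

    Every source inherits its region's label and onset (the earliest onset
    among the region's sources), analogous to lifting a region-level
    resection mask to the vertex level.
    """
    source_labels = np.asarray(source_labels, dtype=int)
    reg = classify_ez_by_region(onsets, source_labels, n_regions, t_eps_s)
    return EZPrediction(
        onset_times_s=reg.onset_times_s[source_labels],
        labels=reg.labels[source_labels],
        t_eps_s=t_eps_s,
    )


def classify_sampled_regions(
    onsets: np.ndarray,
    source_labels: np.ndarray,
    n_regions: int,
    t_eps_s: float,
    candidates: np.ndarray | None = None,
    fraction: float = 0.2,
) -> EZPrediction:
    """Stray-robust region classification over implantation-sampled tissue.

    Region onsets are fractional (:func:`quantile_region_onsets`); the
    earliest-onset anchor and EZ membership are evaluated over
    ``candidates`` (boolean per region, e.g. :func:`implanted_regions`) —
    an SEEG-driven classification can only speak about tissue the
    implantation observes.  Returns a source-level prediction with region
    labels and onsets broadcast to sources; non-candidate regions are
    labelled healthy.
    """
    source_labels = np.asarray(source_labels, dtype=int)
    reg_onsets = quantile_region_onsets(onsets, source_labels, n_regions, fraction)
    if candidates is not None:
        reg_onsets = np.where(np.asarray(candidates, bool), reg_onsets, np.nan)
    reg = classify_ez(reg_onsets, t_eps_s)
    return EZPrediction(
        onset_times_s=reg.onset_times_s[source_labels],
        labels=reg.labels[source_labels],
        t_eps_s=t_eps_s,
    )


def mask_to_highres(region_mask: np.ndarray, source_labels: np.ndarray) -> np.ndarray:
    """Lift a region-level binary mask to source resolution by region lookup."""
    region_mask = np.asarray(region_mask).astype(int)
    source_labels = np.asarray(source_labels, dtype=int)
    if source_labels.min() < 0 or source_labels.max() >= len(region_mask):
        raise ValueError("source carries a region id outside the mask")
    return region_mask[source_labels]


def ez_to_parcellation(
    pred: EZPrediction | np.ndarray,
    source_labels: np.ndarray,
    n_regions: int,
    pct_threshold: float = 20.0,
) -> np.ndarray:
    """Region-level EZ labels: a region is EZ iff at least ``pct_threshold``
    percent of its sources are EZ.  Empty regions are excluded (False)."""
    if not 0.0 < pct_threshold <= 100.0:
        raise ValueError("pct_threshold must be in (0, 100]")
    ez_src = pred.ez_mask() if isinstance(pred, EZPrediction) else np.asarray(pred, bool)
    counts = np.bincount(source_labels, minlength=n_regions).astype(float)
    ez_counts = np.bincount(
        source_labels, weights=ez_src.astype(float), minlength=n_regions
    )
    out = np.zeros(n_regions, dtype=bool)
    nonempty = counts > 0
    out[nonempty] = 100.0 * ez_counts[nonempty] / counts[nonempty] >= pct_threshold
    return out


def precision_recall(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """Precision and recall of a binary prediction against binary truth.

    Precision is 0 by convention when nothing is predicted positive; recall
    is 1 when the truth contains no positives.
    """
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    tp = int((predicted & truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return precision, recall


def implanted_regions(
    sensors: SensorSet, space: SourceSpace, radius_mm: float = 3.0
) -> np.ndarray:
    """Boolean per region: any source within ``radius_mm`` of any contact."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    d = np.linalg.norm(
        space.positions_mm[:, None, :] - sensors.positions_mm[None, :, :], axis=2
    )
    near = (d <= radius_mm).any(axis=1)  # per source
    out = np.zeros(space.n_regions, dtype=bool)
    out[np.unique(space.labels[near])] = True
    return out


def sampled_regions(
    sensors: SensorSet, space: SourceSpace, radius_mm: float = 3.0
) -> np.ndarray:
    """Regions sampled by the implantation, robust to coarse source grids.

    Union of (a) the radius rule of :func:`implanted_regions` and (b) the
    region owning the radial surface projection of each contact onto its
    hemisphere — the cortical territory each electrode trajectory
    traverses.  On fine grids (b) adds nothing beyond (a); on coarse grids
    the nearest source can sit farther than ``radius_mm`` from a contact
    that is plainly inside a region's territory.
    """
    out = implanted_regions(sensors, space, radius_mm).copy()
    brain = space.brain
    centers = brain.hemisphere_centers_mm
    units = space.grid.unit_vectors()
    for pos in sensors.positions_mm:
        h = int(np.argmin(np.linalg.norm(pos - centers, axis=1)))
        radial = pos - centers[h]
        norm = np.linalg.norm(radial)
        if norm < 1e-9:
            continue
        node = int(np.argmax(units @ (radial / norm)))
        out[space.labels[h * space.grid.n_nodes + node]] = True
    return out


def implantation_coverage(
    region_ez: np.ndarray,
    sensors: SensorSet,
    space: SourceSpace,
    radius_mm: float = 3.0,
) -> float:
    """Percentage of predicted EZ regions lying outside the implantation."""
    region_ez = np.asarray(region_ez).astype(bool)
    n_ez = int(region_ez.sum())
    if n_ez == 0:
        return 0.0
    implanted = implanted_regions(sensors, space, radius_mm)
    outside = int((region_ez & ~implanted).sum())
    return 100.0 * outside / n_ez


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Classical paired-samples t test; returns (t, dof, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-d samples with n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, n - 1, 1.0
        raise ValueError("degenerate paired t: zero-variance nonzero differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def _paired_t_power(d: float, n: int, alpha: float) -> float:
    """Power of the two-sided paired t test at effect size d (Cohen's d_z)."""
    dof = n - 1
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    ncp = d * np.sqrt(n)
    return float(
        stats.nct.sf(t_crit, dof, ncp) + stats.nct.cdf(-t_crit, dof, ncp)
    )


def min_detectable_effect(alpha: float = 0.05, power: float = 0.8, n: int = 12) -> float:
    """Smallest Cohen's d with at least the target power for a two-sided
    paired t test, found by root-finding on the noncentral t power curve."""
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must lie in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 pairs")
    hi = 1.0
    while _paired_t_power(hi, n, alpha) < power:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("target power unattainable at this sample size")
    return float(
        optimize.brentq(lambda d: _paired_t_power(d, n, alpha) - power, 1e-9, hi)
    )
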