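"""Self-contained synthetic brains, connectomes, implantations and seizures.

The generator emulates the structural features of a presurgical dataset
without any patient data: two icosphere hemispheres carrying a contiguous
parcellation (72 cortical + 9 subcortical regions per hemisphere by
default, the VEP-atlas layout), a nonnegative distance-decaying random
connectome, linear depth electrodes whose contacts pass near chosen
regions, and a ground-truth excitability map with ``x0 = -1.8`` inside the
epileptogenic-zone regions and ``x0 = -3.0`` elsewhere.  Seizure activity
is obtained by integrating the epileptor field from ``(x, z) = (-2, 5)``
and projected to bipolar SEEG log power, optionally with the 50-copy
Gaussian augmentation (sd 0.1) used for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epileptor import (
    FieldState,
    ModelParams,
    SimulationConfig,
    SourceTrajectory,
    simulate,
)
from .forward import GainMatrix, SEEGFeatures, SensorSet, augment, build_gain, predicted_slp
from .geometry import Hemisphere, SphericalBrain, icosphere
from .harmonics import LocalCouplingOperator, build_local_coupling
from .sources import SourceSpace, build_source_space

__all__ = [
    "SyntheticScenario",
    "generate_brain",
    "generate_connectome",
    "generate_sensors",
    "build_scenario",
    "EZ_EXCITABILITY",
    "HEALTHY_EXCITABILITY",
]

EZ_EXCITABILITY = -1.8
HEALTHY_EXCITABILITY = -3.0
N_SUBCORTICAL_PER_HEMI = 9


@dataclass
class SyntheticScenario:
    """A fully specified ground-truth dataset for one synthetic seizure."""

    brain: SphericalBrain
    connectome: np.ndarray
    sensors: SensorSet
    space: SourceSpace
    local_op: LocalCouplingOperator
    params: ModelParams
    sim_config: SimulationConfig
    x0_true: np.ndarray
    ez_regions: list[int]
    ez_source_mask: np.ndarray
    trajectory: SourceTrajectory
    gain: GainMatrix
    features: SEEGFeatures
    augmented: np.ndarray | None
    seed: int


def _farthest_point_seeds(vertices: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k seed vertex indices by farthest-point sampling (angular distance)."""
    first = int(rng.integers(len(vertices)))
    seeds = [first]
    min_dot = vertices @ vertices[first]
    for _ in range(k - 1):
        nxt = int(np.argmin(min_dot))  # farthest = smallest max dot
        seeds.append(nxt)
        min_dot = np.maximum(min_dot, vertices @ vertices[nxt])
    return np.array(seeds)


def generate_brain(
    n_regions_per_hemi: int = 81,
    mesh_level: int = 4,
    seed: int = 0,
    radius_mm: float = 100.0,
    hemisphere_offset_mm: float = 100.0,
) -> SphericalBrain:
    """Two icosphere hemispheres with a seeded contiguous parcellation.

    Per hemisphere, ``n_regions_per_hemi - 9`` cortical regions are grown
    from farthest-point seeds (each vertex joins its nearest seed by angular
    distance, which yields geodesically convex, hence connected, patches),
    and 9 subcortical regions are realized as point nodes inside the sphere.
    Region ids: hemisphere 0 cortical, then its subcortical, then the same
    for hemisphere 1.  The hemisphere spheres are placed tangent (centres
    at ±radius) so the two cortical sheets never interpenetrate — sources
    of one hemisphere cannot masquerade as the other's in the sensor gain.
    """
    if n_regions_per_hemi < N_SUBCORTICAL_PER_HEMI + 1:
        raise ValueError("need at least one cortical region per hemisphere")
    n_cort = n_regions_per_hemi - N_SUBCORTICAL_PER_HEMI
    rng = np.random.default_rng(seed)
    verts, faces = icosphere(mesh_level)

    hemis = []
    sub_regions, sub_positions = [], []
    records = []
    centers = np.array(
        [[-hemisphere_offset_mm, 0.0, 0.0], [hemisphere_offset_mm, 0.0, 0.0]]
    )
    for h in range(2):
        offset = h * n_regions_per_hemi
        seeds = _farthest_point_seeds(verts, n_cort, rng)
        labels = offset + np.argmax(verts @ verts[seeds].T, axis=1)
        hemis.append(Hemisphere(vertices=verts.copy(), triangles=faces.copy(), labels=labels))
        for r in range(n_cort):
            records.append((offset + r, f"hemi{h}-cortical-{r}", h, True))
        for s in range(N_SUBCORTICAL_PER_HEMI):
            rid = offset + n_cort + s
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            depth = rng.uniform(0.25, 0.5) * radius_mm
            sub_regions.append(rid)
            sub_positions.append(centers[h] + depth * direction)
            records.append((rid, f"hemi{h}-subcortical-{s}", h, False))

    parcellation = pd.DataFrame(
        records, columns=["region_id", "name", "hemisphere", "is_cortical"]
    )
    return SphericalBrain(
        hemispheres=(hemis[0], hemis[1]),
        radius_mm=radius_mm,
        subcortical_regions=np.array(sub_regions),
        subcortical_positions_mm=np.array(sub_positions),
        parcellation=parcellation,
        hemisphere_centers_mm=centers,
    )


def region_centroids(brain: SphericalBrain) -> np.ndarray:
    """3D centroid (mm) of every region: mean unit vertex reprojected to the
    sphere for cortical regions, the node position for subcortical ones."""
    n = brain.n_regions
    out = np.zeros((n, 3))
    for h, hemi in enumerate(brain.hemispheres):
        for r in np.unique(hemi.labels):
            mean = hemi.vertices[hemi.labels == r].mean(axis=0)
            mean /= np.linalg.norm(mean)
            out[r] = brain.hemisphere_centers_mm[h] + brain.radius_mm * mean
    for rid, pos in zip(brain.subcortical_regions, brain.subcortical_positions_mm):
        out[rid] = pos
    return out


def generate_connectome(
    brain: SphericalBrain,
    seed: int = 0,
    decay_mm: float = 50.0,
    weight_sigma: float = 0.5,
) -> np.ndarray:
    """Nonnegative random connectome with distance-decaying weights.

    ``K_ij = exp(-d_ij / decay_mm) * lognormal`` between region centroids,
    zero diagonal, rows normalized to unit sum.
    """
    rng = np.random.default_rng(seed)
    c = region_centroids(brain)
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
    raw = np.exp(-d / decay_mm) * rng.lognormal(0.0, weight_sigma, size=d.shape)
    raw = 0.5 * (raw + raw.T)
    np.fill_diagonal(raw, 0.0)
    return raw / raw.sum(axis=1, keepdims=True)


def generate_sensors(
    brain: SphericalBrain,
    n_electrodes: int = 6,
    contacts_per_electrode: int = 8,
    near_regions: list[int] | None = None,
    seed: int = 0,
) -> SensorSet:
    """Linear depth electrodes targeting specified regions.

    Electrode ``e`` targets ``near_regions[e % len(near_regions)]`` (random
    regions when none are given).  For a cortical target the shaft enters
    at the target centroid on the sphere surface and descends radially
    inward with 3.5 mm contact spacing (superficial contacts sample the
    target's cortex, deep contacts the interior); for a subcortical target
    the contacts are equispaced on the segment from the surface entry
    point to the target node so the deepest contact reaches it.
    """
    if n_electrodes < 1 or contacts_per_electrode < 1:
        raise ValueError("electrode and contact counts must be >= 1")
    contact_spacing_mm = 3.5
    rng = np.random.default_rng(seed)
    centroids = region_centroids(brain)
    if near_regions is None:
        near_regions = list(rng.choice(brain.n_regions, size=n_electrodes, replace=False))
    contact_ids, electrode_ids, positions = [], [], []
    hemi_of_region = {}
    is_cortical = {}
    if brain.parcellation is not None:
        hemi_of_region = dict(
            zip(brain.parcellation["region_id"], brain.parcellation["hemisphere"])
        )
        is_cortical = dict(
            zip(brain.parcellation["region_id"], brain.parcellation["is_cortical"])
        )
    for e in range(n_electrodes):
        target_region = int(near_regions[e % len(near_regions)])
        target = centroids[target_region]
        h = int(hemi_of_region.get(target_region, 0))
        center = brain.hemisphere_centers_mm[h]
        radial = target - center
        norm = np.linalg.norm(radial)
        if norm < 1e-9:
            radial, norm = np.array([0.0, 0.0, 1.0]), 1.0
        inward = -radial / norm
        entry = center + brain.radius_mm * radial / norm
        # small seeded lateral offset so shafts are not exactly radial
        lateral = rng.normal(scale=1.0, size=3)
        lateral -= (lateral @ inward) * inward
        cortical = bool(is_cortical.get(target_region, norm > 0.9 * brain.radius_mm))
        for c in range(contacts_per_electrode):
            if cortical:
                pos = entry + c * contact_spacing_mm * inward + lateral
            else:
                frac = c / max(contacts_per_electrode - 1, 1)
                pos = entry + frac * (target - entry) + (1.0 - frac) * lateral
            contact_ids.append(f"E{e}c{c}")
            electrode_ids.append(f"E{e}")
            positions.append(pos)
    return SensorSet(
        contact_ids=contact_ids,
        electrode_ids=electrode_ids,
        positions_mm=np.array(positions),
    )


def build_scenario(
    brain: SphericalBrain,
    connectome: np.ndarray,
    sensors: SensorSet,
    ez_regions: list[int],
    grid_degree: int = 32,
    G: float = 1.0,
    tau: float = 30.0,
    sim_config: SimulationConfig | None = None,
    n_augment: int = 50,
    augment_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticScenario:
    """Assemble ground truth and simulate the synthetic seizure.

    Excitability is ``-1.8`` for every source in an EZ region and ``-3.0``
    elsewhere; the initial state is ``(x, z) = (-2, 5)`` everywhere.
    """
    ez_regions = [int(r) for r in ez_regions]
    if not ez_regions:
        raise ValueError("ez_regions must be non-empty")
    space = build_source_space(brain, grid_degree)
    known = set(np.unique(space.labels))
    for r in ez_regions:
        if r not in known:
            raise ValueError(f"EZ region {r} has no sources in the parcellation")
    local_op = build_local_coupling(space.grid, radius_mm=brain.radius_mm)

    ez_mask = np.isin(space.labels, ez_regions)
    x0 = np.where(ez_mask, EZ_EXCITABILITY, HEALTHY_EXCITABILITY)
    params = ModelParams(
        x0=x0, G=G, tau=tau, K=connectome, space=space, local_op=local_op
    )
    config = sim_config or SimulationConfig()
    state0 = FieldState.uniform(space.n_sources)
    traj = simulate(state0, params, config)

    gain = build_gain(brain, space, sensors)
    features = predicted_slp(
        traj,
        gain.bipolar,
        alpha=1.0,
        beta=0.0,
        channel_names=gain.bipolar_channels,
        strict=False,
    )
    augmented = (
        augment(features, n=n_augment, sd=augment_sd, seed=seed) if n_augment else None
    )
    return SyntheticScenario(
        brain=brain,
        connectome=connectome,
        sensors=sensors,
        space=space,
        local_op=local_op,
        params=params,
        sim_config=config,
        x0_true=x0,
        ez_regions=ez_regions,
        ez_source_mask=ez_mask,
        trajectory=traj,
        gain=gain,
        features=features,
        augmented=augmented,
        seed=seed,
    )


def default_scenario(
    mesh_level: int = 4,
    grid_degree: int = 16,
    seed: int = 0,
    n_ez: int = 3,
    include_subcortical_ez: bool = True,
    n_electrodes: int = 10,
    **kwargs,
) -> SyntheticScenario:
    """The package's reference synthetic study: 3 EZ regions (two cortical
    neighbours plus one subcortical node, mirroring a temporal-plus-thalamus
    design), depth electrodes targeting the EZ for identifiability."""
    brain = generate_brain(mesh_level=mesh_level, seed=seed)
    connectome = generate_connectome(brain, seed=seed + 1)
    centroids = region_centroids(brain)
    # pick adjacent cortical regions in hemisphere 0: the one nearest to a
    # fixed probe direction and its nearest cortical neighbours
    n_cort = 72
    cortical = np.arange(n_cort)
    probe = brain.hemisphere_centers_mm[0] + brain.radius_mm * np.array([0.0, 0.6, 0.8]) / 1.0
    d_probe = np.linalg.norm(centroids[cortical] - probe, axis=1)
    order = cortical[np.argsort(d_probe)]
    n_cort_ez = n_ez - 1 if include_subcortical_ez else n_ez
    ez = [int(r) for r in order[:n_cort_ez]]
    if include_subcortical_ez:
        ez.append(int(brain.subcortical_regions[0]))
    # implantation: the EZ itself, its immediate neighbours, distal survey
    # electrodes across the ipsilateral hemisphere, and contralateral
    # survey electrodes (real implantations sample the hypothesized
    # network and rule out contralateral onset, rather than probing only
    # the suspected onset zone; distal and contralateral channels anchor
    # the baseline and constrain otherwise-unobserved tissue)
    n_near = max(0, min(3, n_electrodes - len(ez)))
    near = [int(r) for r in order[n_cort_ez : n_cort_ez + n_near]]
    n_rest = max(0, n_electrodes - len(ez) - n_near)
    n_contra = min(2, n_rest)
    n_far = n_rest - n_contra
    far = [int(r) for r in order[::-1][: 2 * n_far : 2]]
    # contralateral homotopic neighbourhood: hemisphere-1 regions nearest
    # the mirrored probe direction
    cortical1 = np.arange(n_cort + 9, 2 * n_cort + 9)
    probe1 = brain.hemisphere_centers_mm[1] + brain.radius_mm * np.array([0.0, 0.6, 0.8])
    d1 = np.linalg.norm(centroids[cortical1] - probe1, axis=1)
    contra = [int(r) for r in cortical1[np.argsort(d1)][:n_contra]]
    sensors = generate_sensors(
        brain,
        n_electrodes=n_electrodes,
        near_regions=ez + near + far + contra,
        seed=seed + 2,
    )
    return build_scenario(
        brain, connectome, sensors, ez, grid_degree=grid_degree, seed=seed + 3, **kwargs
    )
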