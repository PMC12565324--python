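"""Synthetic half-cavity surfaces and populations with latent morphotypes.

The surface is a parametric half-shell S(u, v) over the unit square:
``u`` runs antero-posterior (0 = front), ``v`` infero-superior (0 = floor).
The shell bulges laterally (+X) with band-limited half-widths, extends in
depth along +Y, and rises along +Z:

    X = s * [(1 - v) w_i + v ws(u)] sin(pi v)
    Y = s * [d u - c sin(pi v) ramp(u)]
    Z = s * H v

``ws(u)`` equals the anterior width ``w_a`` for u <= 0.4 and the
posterior-superior width ``w_p`` for u >= 0.6 (cosine-blended between), so
each width parameter acts only on its own band; ``ramp(u)`` confines the
frontal-edge curvature ``c`` to u < 0.3.  Landmarks are placed at fixed
(u, v) anchors that are multiples of 1/20, so any mesh resolution that is a
multiple of 20 carries them exactly on grid vertices.

Morphotype populations draw per-specimen parameters around per-cluster
means; digitization noise is added to landmark coordinates only, keeping
the surface exact for projection tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry_io import (
    CohortTable,
    LandmarkConfiguration,
    SpecimenRecord,
    TemplateDefinition,
    TriangleMesh,
    mirror_configuration,
    mirror_mesh,
)

__all__ = [
    "CavityParams",
    "PopulationSpec",
    "SyntheticSpecimen",
    "SyntheticPopulation",
    "DEFAULT_CLUSTER_MEANS",
    "generate_template",
    "generate_specimen",
    "generate_population",
    "surface_points",
]

SHELL_HEIGHT = 28.0  # mm, parameter-independent so Z carries minimal variation

FIXED_ANCHORS = np.array(
    [
        [0.00, 0.00],  # 0 anterior origin (nostril plane / cavity front angle)
        [0.00, 0.20],  # 1 vestibule front
        [0.10, 0.85],  # 2 nasal-valve top
        [0.30, 1.00],  # 3 cavity crest, front of olfactory region
        [0.75, 1.00],  # 4 cavity crest, back of olfactory region
        [1.00, 0.90],  # 5 choana top
        [0.50, 0.00],  # 6 cavity floor low point
        [1.00, 0.00],  # 7 nostril-plane posterior maximum
        [0.10, 0.15],  # 8 nasal-valve bottom (below the semi-landmark bands)
        [0.20, 0.10],  # 9 inferior-meatus front
    ]
)

FIXED_LABELS = (
    "anterior_origin",
    "vestibule_front",
    "valve_top",
    "olfactory_front",
    "olfactory_back",
    "choana_top",
    "floor_low",
    "nostril_back",
    "valve_bottom",
    "meatus_front",
)


@dataclass
class CavityParams:
    """Shape parameters of one cavity (mm, except the unitless global size)."""

    anterior_width: float = 9.0  # w_a: lateral half-width of the anterior band
    posterior_superior_width: float = 7.0  # w_p: half-width of the posterior band
    inferior_width: float = 5.5  # w_i: half-width along the floor
    depth: float = 35.0  # d: antero-posterior extent
    frontal_curvature: float = 4.0  # c: forward bow of the frontal edge
    global_size: float = 1.0  # s

    def __post_init__(self) -> None:
        for name, val in self.as_dict().items():
            if val <= 0:
                raise ValueError(f"cavity parameter {name} must be positive, got {val}")

    def as_dict(self) -> dict[str, float]:
        return {
            "anterior_width": self.anterior_width,
            "posterior_superior_width": self.posterior_superior_width,
            "inferior_width": self.inferior_width,
            "depth": self.depth,
            "frontal_curvature": self.frontal_curvature,
            "global_size": self.global_size,
        }

    def as_array(self) -> np.ndarray:
        return np.array(list(self.as_dict().values()))


#: cluster means encoding the target qualitative contrasts: cluster 1 widest
#: and shallowest with the flattest frontal edge, cluster 3 narrowest,
#: deepest and most curved, cluster 2 intermediate with the widest floor.
DEFAULT_CLUSTER_MEANS: dict[int, CavityParams] = {
    1: CavityParams(10.5, 8.8, 5.0, 31.0, 2.5),
    2: CavityParams(9.0, 7.0, 6.5, 35.0, 4.0),
    3: CavityParams(7.5, 7.0, 5.0, 39.0, 5.5),
}

#: per-parameter within-cluster standard deviations (global size held fixed)
DEFAULT_WITHIN_SD: dict[str, float] = {
    "anterior_width": 0.35,
    "posterior_superior_width": 0.35,
    "inferior_width": 0.35,
    "depth": 0.6,
    "frontal_curvature": 0.35,
    "global_size": 0.0,
}


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def surface_points(u: np.ndarray, v: np.ndarray, params: CavityParams) -> np.ndarray:
    """Evaluate the parametric shell at (u, v) pairs; returns (n, 3)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    p = params
    ws = p.anterior_width + (p.posterior_superior_width - p.anterior_width) * _smoothstep(
        (u - 0.4) / 0.2
    )
    halfwidth = (1.0 - v) * p.inferior_width + v * ws
    ramp = 1.0 - _smoothstep(u / 0.3)
    x = halfwidth * np.sin(np.pi * v)
    y = p.depth * u - p.frontal_curvature * np.sin(np.pi * v) * ramp
    z = SHELL_HEIGHT * v
    return p.global_size * np.stack([x, y, z], axis=-1)


def _grid_mesh(params: CavityParams, resolution: int) -> TriangleMesh:
    r = resolution
    uu, vv = np.meshgrid(np.linspace(0, 1, r + 1), np.linspace(0, 1, r + 1), indexing="ij")
    verts = surface_points(uu.ravel(), vv.ravel(), params)
    idx = np.arange((r + 1) * (r + 1)).reshape(r + 1, r + 1)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    tris = np.concatenate([np.stack([a, b, c], 1), np.stack([a, c, d], 1)])
    return TriangleMesh(verts, tris)


def _patch_grid() -> tuple[np.ndarray, np.ndarray]:
    """(u, v) anchors of the 200 semi-landmarks and their patch ids."""
    v_vals = np.round(np.arange(0.25, 0.7001, 0.05), 10)
    anchors = []
    patches = []
    for patch, u_start in ((1, 0.05), (2, 0.55)):
        u_vals = np.round(np.arange(u_start, u_start + 0.4501, 0.05), 10)
        for u in u_vals:
            for v in v_vals:
                anchors.append((u, v))
                patches.append(patch)
    return np.array(anchors), np.array(patches, np.int64)


def generate_template(resolution: int = 40, params: CavityParams | None = None) -> TemplateDefinition:
    """Build the template surface with its 10 fixed and 200 semi-landmarks.

    Landmarks are evaluated parametrically; with ``resolution`` a multiple
    of 20 they coincide with mesh grid vertices exactly.
    """
    if resolution < 4:
        raise ValueError("resolution too coarse for a usable template")
    params = params or CavityParams()
    mesh = _grid_mesh(params, resolution)
    fixed = surface_points(FIXED_ANCHORS[:, 0], FIXED_ANCHORS[:, 1], params)
    anchors, patches = _patch_grid()
    semis = surface_points(anchors[:, 0], anchors[:, 1], params)
    return TemplateDefinition(mesh, fixed, FIXED_LABELS, semis, patches)


def generate_specimen(
    params: CavityParams,
    side: str = "right",
    sigma_dig: float = 0.0,
    seed: int | np.random.Generator = 0,
    resolution: int = 20,
    specimen_id: str = "specimen",
) -> tuple[TriangleMesh, LandmarkConfiguration]:
    """Evaluate the shell under ``params``; returns the mesh and the
    ground-truth 210-landmark configuration (noise on landmarks only)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mesh = _grid_mesh(params, resolution)
    fixed = surface_points(FIXED_ANCHORS[:, 0], FIXED_ANCHORS[:, 1], params)
    anchors, patches = _patch_grid()
    semis = surface_points(anchors[:, 0], anchors[:, 1], params)
    coords = np.vstack([fixed, semis])
    patch_ids = np.concatenate([np.zeros(10, np.int64), patches])
    config = LandmarkConfiguration(specimen_id, coords, patch_ids)
    if side == "left":
        mesh = mirror_mesh(mesh)
        config = mirror_configuration(config)
    elif side != "right":
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    if sigma_dig > 0:
        noisy = config.coordinates + rng.normal(0.0, sigma_dig, config.coordinates.shape)
        config = replace(config, coordinates=noisy)
    return mesh, config


@dataclass
class PopulationSpec:
    """Sampling plan for a two-sided synthetic cohort with latent morphotypes."""

    n_patients: int = 45
    cluster_proportions: tuple[float, ...] = (0.25, 0.5, 0.25)
    cluster_means: dict[int, CavityParams] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_MEANS)
    )
    within_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WITHIN_SD))
    sigma_dig: float = 0.3
    side_effect: float = 0.0  # +X offset added to left-side landmarks (mm)
    rho_pair: float = 0.75  # probability a side inherits the patient's latent cluster
    seed: int = 0
    mesh_resolution: int = 20

    def __post_init__(self) -> None:
        props = np.asarray(self.cluster_proportions, float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        if self.sigma_dig < 0 or self.side_effect < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if not 0.0 <= self.rho_pair <= 1.0:
            raise ValueError("rho_pair must lie in [0, 1]")
        if len(self.cluster_means) != len(props):
            raise ValueError("one mean parameter set per cluster required")


@dataclass
class SyntheticSpecimen:
    record: SpecimenRecord
    mesh: TriangleMesh
    landmarks: LandmarkConfiguration  # ground-truth correspondence, with noise
    true_cluster: int
    params: CavityParams


@dataclass
class SyntheticPopulation:
    spec: PopulationSpec
    specimens: list[SyntheticSpecimen]
    cohort: CohortTable

    @property
    def records(self) -> list[SpecimenRecord]:
        return [s.record for s in self.specimens]

    def true_labels(self) -> dict[str, int]:
        return {s.record.specimen_id: s.true_cluster for s in self.specimens}


def _sample_params(
    mean: CavityParams, within_sd: dict[str, float], rng: np.random.Generator
) -> CavityParams:
    vals = {}
    for name, mu in mean.as_dict().items():
        sd = within_sd.get(name, 0.0)
        v = rng.normal(mu, sd) if sd > 0 else mu
        vals[name] = max(v, 0.05 * mu)  # keep parameters positive
    return CavityParams(**vals)


def generate_population(spec: PopulationSpec) -> SyntheticPopulation:
    """Sample a full two-sided cohort according to ``spec`` (fully seeded).

    Per patient: a latent cluster is drawn from the proportions; each side
    keeps it with probability ``rho_pair`` (else resamples), giving
    Table-5-like mixed pairs.  Sex and age are independent of cluster.
    """
    rng = np.random.default_rng(spec.seed)
    cluster_ids = sorted(spec.cluster_means)
    props = np.asarray(spec.cluster_proportions, float)
    specimens: list[SyntheticSpecimen] = []
    cohort_rows = []
    for i in range(spec.n_patients):
        patient_id = f"P{i:03d}"
        latent = cluster_ids[rng.choice(len(props), p=props)]
        sex = "female" if rng.random() < 0.5 else "male"
        age = float(np.clip(rng.normal(54.0, 20.0), 15, 85))
        cohort_rows.append({"patient_id": patient_id, "sex": sex, "age": age})
        for side in ("right", "left"):
            cluster = latent
            if rng.random() > spec.rho_pair:
                cluster = cluster_ids[rng.choice(len(props), p=props)]
            params = _sample_params(spec.cluster_means[cluster], spec.within_sd, rng)
            specimen_id = f"{patient_id}_{side[0].upper()}"
            mesh, config = generate_specimen(
                params,
                side=side,
                sigma_dig=spec.sigma_dig,
                seed=rng,
                resolution=spec.mesh_resolution,
                specimen_id=specimen_id,
            )
            if side == "left" and spec.side_effect > 0:
                coords = config.coordinates.copy()
                coords[:, 0] += spec.side_effect
                config = replace(config, coordinates=coords)
            record = SpecimenRecord(specimen_id, patient_id, side)
            specimens.append(SyntheticSpecimen(record, mesh, config, cluster, params))
    cohort = CohortTable(pd.DataFrame(cohort_rows))
    return SyntheticPopulation(spec, specimens, cohort)
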