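"""Spiculated tumor surface phantoms.

Builds the suite of star-shaped surfaces ``r(theta, phi) = rho(theta, phi)``
from the spiculated radial law (:mod:`spiculo.harmonics`), cuts each at the
horizontal mid-plane to give a flat printable base, rescales every model to
an identical base extent, and serializes the result as binary STL.

The default sweep d = 11, 14, ..., 92 yields 28 models ranging from the most
spiculated (d = 11) to a nearly smooth dome (d = 92).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .geometry import (
    as_mesh,
    clip_halfspace_z,
    ensure_outward,
    max_planar_extent,
)
from .harmonics import HarmonicSpec, eval_real_harmonic

__all__ = [
    "HarmonicSpec",
    "ModelSuite",
    "build_surface_mesh",
    "cut_and_scale",
    "generate_suite",
    "write_stl",
    "read_stl",
    "suite_stl_name",
]

#: resolution floor below which an l=10 harmonic's lobes are undersampled
MIN_THETA = 32
MIN_PHI = 64

DEFAULT_N_THETA = 128
DEFAULT_N_PHI = 256


@dataclass(frozen=True)
class ModelSuite:
    """Ordered collection of (spec, mesh) pairs, ascending in d."""

    specs: tuple[HarmonicSpec, ...]
    meshes: tuple[trimesh.Trimesh, ...]

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(zip(self.specs, self.meshes))

    @property
    def d_values(self) -> np.ndarray:
        return np.array([s.spiculation_d for s in self.specs])


def build_surface_mesh(
    spec: HarmonicSpec,
    n_theta: int = DEFAULT_N_THETA,
    n_phi: int = DEFAULT_N_PHI,
) -> trimesh.Trimesh:
    """Closed star-shaped surface mesh of the radial law.

    A latitude-longitude grid with both poles collapsed to single vertices;
    each quad cell is split along its shorter diagonal (ties split along the
    (i, j)-(i+1, j+1) diagonal).  The harmonic normalizer max|Re{Y}| is taken
    over this same grid, so every vertex satisfies |p| = rho(theta, phi)
    exactly.
    """
    if n_theta < MIN_THETA or n_phi < MIN_PHI:
        raise ValueError(
            f"resolution below floor ({MIN_THETA}, {MIN_PHI}): "
            f"got ({n_theta}, {n_phi})"
        )
    theta = np.linspace(0.0, np.pi, n_theta + 1)
    phi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    tg, pg = np.meshgrid(theta, phi, indexing="ij")
    y = eval_real_harmonic(spec.degree_l, spec.order_m, tg, pg)
    normalizer = float(np.abs(y).max())
    if spec.amplitude_A == 0 or normalizer == 0:
        rho = np.full_like(tg, float(spec.spiculation_d))
    else:
        rho = spec.spiculation_d + spec.amplitude_A * y / normalizer

    # vertices: north pole, interior rings, south pole
    xyz = np.stack(
        [
            rho * np.sin(tg) * np.cos(pg),
            rho * np.sin(tg) * np.sin(pg),
            rho * np.cos(tg),
        ],
        axis=-1,
    )
    north = xyz[0].mean(axis=0)  # all phi coincide at the pole
    south = xyz[-1].mean(axis=0)
    rings = xyz[1:-1].reshape(-1, 3)  # (n_theta-1) * n_phi
    vertices = np.vstack([north[None, :], rings, south[None, :]])

    v = vertices
    j = np.arange(n_phi)
    jn = (j + 1) % n_phi
    north_faces = np.stack(
        [np.zeros(n_phi, dtype=np.int64), 1 + j, 1 + jn], axis=1
    )
    # interior quads between rings i and i+1, split along the shorter
    # diagonal (tie -> the a-c diagonal)
    i = np.arange(1, n_theta - 1)[:, None]
    a = 1 + (i - 1) * n_phi + j
    b = 1 + (i - 1) * n_phi + jn
    c = 1 + i * n_phi + jn
    d = 1 + i * n_phi + j
    ac = np.sum((v[a] - v[c]) ** 2, axis=-1)
    bd = np.sum((v[b] - v[d]) ** 2, axis=-1)
    use_ac = ac <= bd
    f1 = np.where(use_ac[..., None], np.stack([a, b, c], -1), np.stack([a, b, d], -1))
    f2 = np.where(use_ac[..., None], np.stack([a, c, d], -1), np.stack([b, c, d], -1))
    quad_faces = np.concatenate(
        [f1.reshape(-1, 3), f2.reshape(-1, 3)], axis=0
    )
    sp = len(vertices) - 1
    base = 1 + (n_theta - 2) * n_phi
    south_faces = np.stack(
        [np.full(n_phi, sp, dtype=np.int64), base + jn, base + j], axis=1
    )
    faces = np.vstack([north_faces, quad_faces, south_faces]).astype(np.int64)
    return ensure_outward(as_mesh(vertices, faces))


def cut_and_scale(mesh: trimesh.Trimesh, base_size: float = 50.0) -> trimesh.Trimesh:
    """Keep the z >= 0 half, cap the cut, and normalize the base extent.

    The open cut is capped with a planar fan; the whole model is then scaled
    uniformly so the maximal horizontal extent of the base cross-section
    equals ``base_size`` (mm).  Uniform scaling preserves every dimensionless
    shape feature of the model exactly.
    """
    if base_size <= 0:
        raise ValueError("base_size must be positive")
    half, boundary = clip_halfspace_z(mesh, 0.0)
    extent = max_planar_extent(boundary)
    if extent <= 0:
        raise ValueError("degenerate base cross-section")
    scaled = as_mesh(half.vertices * (base_size / extent), half.faces)
    return scaled


def generate_suite(
    d_start: float = 11.0,
    d_stop: float = 92.0,
    d_step: float = 3.0,
    degree_l: int = 10,
    order_m: int = 5,
    amplitude_A: float = 10.0,
    base_size: float = 50.0,
    n_theta: int = DEFAULT_N_THETA,
    n_phi: int = DEFAULT_N_PHI,
) -> ModelSuite:
    """Generate the cut-and-scaled phantom suite over the d sweep.

    The default sweep (11 to 92 in steps of 3) produces 28 models.
    Deterministic: identical parameters give identical vertex arrays.
    """
    if d_step <= 0:
        raise ValueError("d_step must be positive")
    d_values = np.arange(d_start, d_stop + 0.5 * d_step, d_step)
    if len(d_values) == 0:
        raise ValueError("empty d sweep")
    specs = []
    meshes = []
    for d in d_values:
        spec = HarmonicSpec(degree_l, order_m, amplitude_A, float(d))
        full = build_surface_mesh(spec, n_theta=n_theta, n_phi=n_phi)
        meshes.append(cut_and_scale(full, base_size))
        specs.append(spec)
    return ModelSuite(tuple(specs), tuple(meshes))


def suite_stl_name(spec: HarmonicSpec) -> str:
    return f"phantom_d{int(round(spec.spiculation_d)):02d}.stl"


def write_stl(mesh: trimesh.Trimesh, path) -> None:
    """Binary little-endian STL, units mm."""
    Path(path).write_bytes(trimesh.exchange.stl.export_stl(mesh))


def read_stl(path) -> trimesh.Trimesh:
    """Read an STL surface, welding the per-facet duplicate vertices.

    STL stores a triangle soup; exact-duplicate vertices are merged so a
    closed surface round-trips to a watertight mesh.
    """
    loaded = trimesh.load_mesh(str(path), process=False)
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    unique, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return as_mesh(unique, inverse[faces])
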