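"""Voxelized presynaptic geometries.

A synaptic bouton is modeled as a rotationally symmetric prolate ellipsoid
whose long axis is collinear with a cylindrical axon; the axon passes
through the bouton, so the accessible space is the union of the ellipsoid
interior and the axon lumen, giving two openings at the poles of the major
axis.  The lattice resolution is 25 nm.  Mitochondria and vacuoles are
excluded volume (``OCCUPIED``); synaptic vesicles occupy single voxels that
remain accessible but additionally permit binding (``VESICLE``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# voxel labels
EXTERIOR = 0
CYTOSOL = 1
VESICLE = 2
OCCUPIED = 3

LABEL_NAMES = {EXTERIOR: "exterior", CYTOSOL: "cytosol",
               VESICLE: "vesicle", OCCUPIED: "occupied"}

DEFAULT_VOXEL_EDGE = 25.0     # nm
DEFAULT_AXON_DIAMETER = 200.0  # nm
DEFAULT_AXON_LENGTH = 5000.0   # nm


class GeometryError(ValueError):
    """Raised when a requested geometry is infeasible."""


@dataclass
class GeometryParams:
    """Interpretable parameters of one bouton geometry.

    ``major_axis_length`` is the EM-scale major-axis length in nm; it is
    multiplied by ``rescale_factor`` (default 2, matching the size mismatch
    between EM and fluorescence images of the same synapses) when the voxel
    grid is built.
    """

    major_axis_length: float            # nm, before rescaling
    aspect_ratio: float = 1.5           # major/minor, >= 1 is prolate
    n_vesicles: int = 0
    n_mitochondria: int = 0
    n_vacuoles: int = 0
    organelle_volume_fraction: float = 0.0
    rescale_factor: float = 2.0

    def validate(self) -> None:
        if not self.major_axis_length > 0:
            raise GeometryError("major_axis_length must be positive")
        if not self.aspect_ratio >= 1.0:
            raise GeometryError("aspect_ratio must be >= 1 (prolate along the axon)")
        if self.n_vesicles < 0 or self.n_mitochondria < 0 or self.n_vacuoles < 0:
            raise GeometryError("counts must be nonnegative")
        if not 0.0 <= self.organelle_volume_fraction < 1.0:
            raise GeometryError("organelle_volume_fraction must be in [0, 1)")
        if self.rescale_factor <= 0:
            raise GeometryError("rescale_factor must be positive")

    @property
    def built_length(self) -> float:
        """Major-axis length (nm) after rescaling, as used on the lattice."""
        return self.major_axis_length * self.rescale_factor


@dataclass
class VoxelGrid:
    """Labeled 3D lattice holding one synapse + axon geometry.

    Axis 0 is the axon axis and is periodic. ``synapse_mask`` marks the
    ellipsoid interior (including organelle and vesicle voxels), and
    ``axon_mask`` the axon lumen outside the ellipsoid.
    """

    labels: np.ndarray                  # int8, shape (nx, ny, nz)
    voxel_edge: float = DEFAULT_VOXEL_EDGE
    periodic_axis: int = 0
    axon_diameter: float = DEFAULT_AXON_DIAMETER
    axon_length: float = DEFAULT_AXON_LENGTH
    center: tuple = (0.0, 0.0, 0.0)     # physical nm
    semi_axes: tuple = (0.0, 0.0, 0.0)  # ellipsoid semi-axes, nm
    params: Optional[GeometryParams] = None
    seed: Optional[int] = None
    synapse_mask: np.ndarray = field(default=None, repr=False)
    axon_mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.synapse_mask is None or self.axon_mask is None:
            self._compute_masks()

    def _compute_masks(self):
        a = self.voxel_edge
        nx, ny, nz = self.labels.shape
        x = (np.arange(nx) + 0.5) * a
        y = (np.arange(ny) + 0.5) * a
        z = (np.arange(nz) + 0.5) * a
        cx, cy, cz = self.center
        sx, sy, sz = self.semi_axes
        if sx > 0:
            e = ((x[:, None, None] - cx) / sx) ** 2 + \
                ((y[None, :, None] - cy) / sy) ** 2 + \
                ((z[None, None, :] - cz) / sz) ** 2
            self.synapse_mask = e <= 1.0
        else:
            self.synapse_mask = np.zeros(self.labels.shape, dtype=bool)
        r = self.axon_diameter / 2.0
        cyl = ((y[None, :, None] - cy) ** 2 + (z[None, None, :] - cz) ** 2) <= r ** 2
        cyl = np.broadcast_to(cyl, self.labels.shape)
        self.axon_mask = cyl & ~self.synapse_mask

    # -- basic queries ----------------------------------------------------
    @property
    def accessible_mask(self) -> np.ndarray:
        return (self.labels == CYTOSOL) | (self.labels == VESICLE)

    @property
    def n_accessible(self) -> int:
        return int(self.accessible_mask.sum())

    def accessible_synapse_voxels(self) -> int:
        return int((self.accessible_mask & self.synapse_mask).sum())

    @property
    def synapse_length(self) -> float:
        """Major-axis length of the bouton in nm (2x the first semi-axis)."""
        return 2.0 * self.semi_axes[0]

    def save(self, path) -> None:
        """JSON header line + flat row-major label bytes."""
        header = {
            "voxel_edge": self.voxel_edge,
            "shape": list(self.labels.shape),
            "periodic_axis": self.periodic_axis,
            "axon_diameter": self.axon_diameter,
            "axon_length": self.axon_length,
            "center": list(self.center),
            "semi_axes": list(self.semi_axes),
            "params": asdict(self.params) if self.params else None,
            "seed": self.seed,
        }
        with open(path, "wb") as fh:
            fh.write(json.dumps(header).encode() + b"\n")
            fh.write(np.ascontiguousarray(self.labels, dtype=np.int8).tobytes())

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            raw = fh.read()
        shape = tuple(header["shape"])
        labels = np.frombuffer(raw, dtype=np.int8).reshape(shape).copy()
        params = GeometryParams(**header["params"]) if header["params"] else None
        return cls(labels=labels, voxel_edge=header["voxel_edge"],
                   periodic_axis=header["periodic_axis"],
                   axon_diameter=header["axon_diameter"],
                   axon_length=header["axon_length"],
                   center=tuple(header["center"]),
                   semi_axes=tuple(header["semi_axes"]),
                   params=params, seed=header["seed"])


def _connected(accessible: np.ndarray, periodic_axis: int = 0) -> bool:
    """All accessible voxels reachable by face moves (periodic along axis 0)."""
    from scipy import ndimage

    lab, n = ndimage.label(accessible)
    if n <= 1:
        return n >= 0
    # merge components that touch across the periodic boundary
    lo = lab.take(0, axis=periodic_axis)
    hi = lab.take(-1, axis=periodic_axis)
    parent = {i: i for i in range(1, n + 1)}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    touching = (lo > 0) & (hi > 0)
    for i, j in zip(lo[touching].ravel(), hi[touching].ravel()):
        pi, pj = find(int(i)), find(int(j))
        if pi != pj:
            parent[pi] = pj
    roots = {find(i) for i in range(1, n + 1)}
    return len(roots) == 1


def build_geometry(params: GeometryParams, seed: int,
                   voxel_edge: float = DEFAULT_VOXEL_EDGE,
                   axon_diameter: float = DEFAULT_AXON_DIAMETER,
                   axon_length: float = DEFAULT_AXON_LENGTH,
                   max_tries: int = 50) -> VoxelGrid:
    """Voxelize one bouton+axon geometry.

    Organelles are placed as random ellipsoidal blobs totaling
    ``organelle_volume_fraction`` of the bouton volume; placements that
    disconnect the accessible space are rejected and resampled. Vesicle
    voxels are drawn uniformly from the remaining cytosol of the bouton.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    a = voxel_edge
    L = params.built_length
    if L >= 0.92 * axon_length:
        raise GeometryError(
            f"bouton length {L:.0f} nm does not fit in the {axon_length:.0f} nm axon")

    semi_major = L / 2.0
    semi_minor = L / (2.0 * params.aspect_ratio)
    half_width = max(semi_minor, axon_diameter / 2.0)
    nx = int(round(axon_length / a))
    nyz = 2 * int(np.ceil(half_width / a)) + 3
    shape = (nx, nyz, nyz)
    center = (nx * a / 2.0, nyz * a / 2.0, nyz * a / 2.0)

    grid = VoxelGrid(labels=np.zeros(shape, dtype=np.int8), voxel_edge=a,
                     axon_diameter=axon_diameter, axon_length=axon_length,
                     center=center, semi_axes=(semi_major, semi_minor, semi_minor),
                     params=params, seed=seed)
    labels = grid.labels
    labels[grid.synapse_mask | grid.axon_mask] = CYTOSOL

    syn_vox = int(grid.synapse_mask.sum())
    if syn_vox == 0:
        raise GeometryError("bouton smaller than one voxel")

    # --- organelles ------------------------------------------------------
    n_blobs = params.n_mitochondria + params.n_vacuoles
    target_total = int(round(params.organelle_volume_fraction * syn_vox))
    if target_total > 0 and n_blobs == 0:
        raise GeometryError("organelle_volume_fraction > 0 but no organelles requested")
    if target_total >= syn_vox:
        raise GeometryError("requested organelle volume exceeds the bouton volume")
    if n_blobs > 0 and target_total > 0:
        # split total volume over blobs with random weights
        w = rng.dirichlet(np.full(n_blobs, 2.0))
        blob_sizes = np.maximum(1, np.round(w * target_total).astype(int))
        syn_idx = np.argwhere(grid.synapse_mask)
        coords = (syn_idx + 0.5) * a
        for size in blob_sizes:
            placed = False
            for _ in range(max_tries):
                c = coords[rng.integers(len(coords))]
                ax_ratio = rng.lognormal(0.0, 0.4, size=3)
                d2 = (((coords - c) / ax_ratio) ** 2).sum(axis=1)
                free = labels[tuple(syn_idx.T)] == CYTOSOL
                d2 = np.where(free, d2, np.inf)
                order = np.argsort(d2)
                k = min(size, int(free.sum()) - 1)
                if k <= 0:
                    raise GeometryError("no cytosol left for organelle placement")
                chosen = syn_idx[order[:k]]
                labels[tuple(chosen.T)] = OCCUPIED
                if _connected(grid.accessible_mask):
                    placed = True
                    break
                labels[tuple(chosen.T)] = CYTOSOL  # undo, retry
            if not placed:
                raise GeometryError(
                    "could not place organelles without disconnecting the bouton")

    # --- vesicles ---------------------------------------------------------
    free_syn = np.argwhere((labels == CYTOSOL) & grid.synapse_mask)
    if params.n_vesicles > len(free_syn):
        raise GeometryError(
            f"n_vesicles={params.n_vesicles} exceeds {len(free_syn)} available "
            "cytosol voxels in the bouton")
    if params.n_vesicles > 0:
        pick = rng.choice(len(free_syn), size=params.n_vesicles, replace=False)
        labels[tuple(free_syn[pick].T)] = VESICLE

    if not _connected(grid.accessible_mask):
        raise GeometryError("accessible space is disconnected")
    return grid


def build_axon_tube(voxel_edge: float = DEFAULT_VOXEL_EDGE,
                    axon_diameter: float = DEFAULT_AXON_DIAMETER,
                    axon_length: float = DEFAULT_AXON_LENGTH) -> VoxelGrid:
    """A bouton-free periodic axon cylinder.

    Useful for axon-FRAP measurements: the shaft is identical in every
    ensemble geometry and holds no vesicles, and without the bouton the
    whole protein pool contributes to the (otherwise photon-starved) axon
    ROI.
    """
    a = voxel_edge
    nx = int(round(axon_length / a))
    nyz = 2 * int(np.ceil(axon_diameter / 2.0 / a)) + 3
    shape = (nx, nyz, nyz)
    center = (nx * a / 2.0, nyz * a / 2.0, nyz * a / 2.0)
    grid = VoxelGrid(labels=np.zeros(shape, dtype=np.int8), voxel_edge=a,
                     axon_diameter=axon_diameter, axon_length=axon_length,
                     center=center, semi_axes=(0.0, 0.0, 0.0))
    grid.labels[grid.axon_mask] = CYTOSOL
    return grid


def vesicle_density(grid: VoxelGrid) -> float:
    """Fraction of accessible bouton voxels that carry a vesicle."""
    acc = grid.accessible_mask & grid.synapse_mask
    n_acc = int(acc.sum())
    if n_acc == 0:
        raise GeometryError("grid has no accessible synapse voxels")
    n_ves = int((grid.labels[grid.synapse_mask] == VESICLE).sum())
    return n_ves / n_acc


# --------------------------------------------------------------------------
# ensemble sampling
# --------------------------------------------------------------------------

#: Default per-parameter distributions for the heterogeneous bouton ensemble.
#: Volume-like quantities are log-normal; organelle counts are Poisson.
#: The vesicle count is specified through a log-normal vesicle *density*
#: (vesicle voxels per accessible bouton voxel) so that vesicle number scales
#: with bouton volume; its median is calibrated so the ensemble-average
#: density is ~0.0456, the value consistent with published effective
#: diffusion coefficients of vesicle-binding synaptic proteins.
DEFAULT_DISTRIBUTIONS = {
    "major_axis_length": {"dist": "lognormal", "median": 510.0, "sigma": 0.17,
                          "clip": [375.0, 750.0]},
    "aspect_ratio": {"dist": "lognormal", "median": 1.4, "sigma": 0.25,
                     "clip": [1.0, 2.2]},
    "vesicle_density": {"dist": "lognormal", "median": 0.0410, "sigma": 0.30,
                        "clip": [0.005, 0.2]},
    "n_mitochondria": {"dist": "poisson", "lam": 1.0},
    "n_vacuoles": {"dist": "poisson", "lam": 2.0},
    "organelle_volume_fraction": {"dist": "lognormal", "median": 0.10,
                                  "sigma": 0.5, "clip": [0.0, 0.30]},
    "rescale_factor": {"dist": "constant", "value": 2.0},
}


@dataclass
class EnsembleSpec:
    """Sampling spec for a heterogeneous ensemble of bouton geometries."""

    n_geometries: int = 30
    distributions: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_DISTRIBUTIONS.items()})
    seed: int = 0
    voxel_edge: float = DEFAULT_VOXEL_EDGE


def _draw(rng: np.random.Generator, spec: dict, size: int) -> np.ndarray:
    kind = spec.get("dist")
    if kind == "lognormal":
        x = rng.lognormal(np.log(spec["median"]), spec["sigma"], size=size)
    elif kind == "poisson":
        x = rng.poisson(spec["lam"], size=size).astype(float)
    elif kind == "uniform":
        x = rng.uniform(spec["low"], spec["high"], size=size)
    elif kind == "constant":
        x = np.full(size, float(spec["value"]))
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    if "clip" in spec:
        x = np.clip(x, spec["clip"][0], spec["clip"][1])
    return x


def sample_ensemble(spec: EnsembleSpec) -> list[GeometryParams]:
    """Draw reproducible geometry parameter sets for an ensemble."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_geometries
    d = spec.distributions
    L = _draw(rng, d["major_axis_length"], n)
    ar = _draw(rng, d["aspect_ratio"], n)
    rho = _draw(rng, d["vesicle_density"], n)
    n_mito = _draw(rng, d["n_mitochondria"], n).astype(int)
    n_vac = _draw(rng, d["n_vacuoles"], n).astype(int)
    ofrac = _draw(rng, d["organelle_volume_fraction"], n)
    resc = _draw(rng, d["rescale_factor"], n)

    out = []
    a3 = spec.voxel_edge ** 3
    for i in range(n):
        # expected accessible bouton voxels for the sampled ellipsoid
        semi_major = L[i] * resc[i] / 2.0
        semi_minor = semi_major / ar[i]
        vol = 4.0 / 3.0 * np.pi * semi_major * semi_minor ** 2
        n_acc = vol * (1.0 - ofrac[i]) / a3
        n_org = int(n_mito[i]) + int(n_vac[i])
        p = GeometryParams(
            major_axis_length=float(L[i]),
            aspect_ratio=float(ar[i]),
            n_vesicles=int(round(rho[i] * n_acc)),
            n_mitochondria=int(n_mito[i]),
            n_vacuoles=int(n_vac[i]),
            # a bouton without organelle bodies occupies no organelle volume
            organelle_volume_fraction=float(ofrac[i]) if n_org else 0.0,
            rescale_factor=float(resc[i]),
        )
        p.validate()
        out.append(p)
    return out


def build_ensemble(spec: EnsembleSpec) -> list[VoxelGrid]:
    """Sample parameters and voxelize every geometry of the ensemble."""
    params = sample_ensemble(spec)
    seeds = np.random.SeedSequence(spec.seed).spawn(len(params))
    return [build_geometry(p, seed=int(s.generate_state(1)[0] % (2 ** 31)),
                           voxel_edge=spec.voxel_edge)
            for p, s in zip(params, seeds)]


# --------------------------------------------------------------------------
# parameter tables
# --------------------------------------------------------------------------

def read_geometry_table(path) -> list[GeometryParams]:
    """Read a CSV of geometry parameters (columns named after GeometryParams)."""
    df = pd.read_csv(path)
    required = {"major_axis_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"geometry table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        kwargs = {k: float(row[k]) for k in df.columns
                  if k in GeometryParams.__dataclass_fields__}
        for k in ("n_vesicles", "n_mitochondria", "n_vacuoles"):
            if k in kwargs:
                kwargs[k] = int(kwargs[k])
        p = GeometryParams(**kwargs)
        p.validate()
        out.append(p)
    return out


def write_geometry_table(params: Sequence[GeometryParams], path) -> None:
    pd.DataFrame([asdict(p) for p in params]).to_csv(path, index=False)
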