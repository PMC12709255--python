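"""Event-driven stochastic reaction-diffusion on the voxel lattice.

Diffusion is inter-voxel hopping at rate D/a^2 per accessible face (6D/a^2
total for an unobstructed voxel); in vesicle voxels free proteins bind at
rate k_b and bound proteins unbind at rate 1/T.  Bound proteins do not hop.
Events are scheduled with the next subvolume method: an indexed priority
queue selects the voxel of the next event, the direct method selects the
event within it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _core
from .geometry import VoxelGrid, CYTOSOL, VESICLE

#: species indices
FREE_UNBLEACHED, FREE_BLEACHED, BOUND_UNBLEACHED, BOUND_BLEACHED = 0, 1, 2, 3

DEFAULT_N_PROTEINS = 5000


class QuiescentState(RuntimeError):
    """No event can occur: the total propensity is zero."""


@dataclass
class KineticParams:
    """Mobility hypothesis for one protein.

    D in um^2/s, binding rate k_b in 1/s, mean vesicle retention time T in s.
    ``k_b == 0`` or ``T == 0`` disables binding.
    """

    D: float
    k_b: float = 0.0
    T: float = 0.0

    def __post_init__(self):
        if self.D < 0 or self.k_b < 0 or self.T < 0:
            raise ValueError("D, k_b and T must be nonnegative")
        if self.T == 0 and self.k_b > 0:
            raise ValueError("T = 0 with k_b > 0 is invalid (instant unbinding)")

    @property
    def binding(self) -> bool:
        return self.k_b > 0 and self.T > 0

    @property
    def D_nm2(self) -> float:
        return self.D * 1e6  # um^2/s -> nm^2/s


class LatticeIndex:
    """Flat arrays over accessible voxels plus a compacted neighbor table."""

    def __init__(self, grid: VoxelGrid):
        self.grid = grid
        acc = grid.accessible_mask
        self.shape = grid.labels.shape
        self.coords = np.argwhere(acc).astype(np.int32)          # (n, 3)
        self.n_voxels = len(self.coords)
        if self.n_voxels == 0:
            raise ValueError("grid has no accessible voxels")
        self.index_map = np.full(self.shape, -1, dtype=np.int32)
        self.index_map[acc] = np.arange(self.n_voxels, dtype=np.int32)

        nx = self.shape[0]
        nb = np.full((self.n_voxels, 6), -1, dtype=np.int32)
        wrapf = np.zeros((self.n_voxels, 6), dtype=np.uint8)
        k = 0
        for axis in range(3):
            for d in (-1, 1):
                tgt = self.coords.copy()
                tgt[:, axis] += d
                wrapped = np.zeros(self.n_voxels, dtype=bool)
                if axis == grid.periodic_axis:
                    wrapped = (tgt[:, axis] < 0) | (tgt[:, axis] >= nx)
                    tgt[:, axis] %= nx
                valid = np.all((tgt >= 0) & (tgt < np.array(self.shape)), axis=1)
                idx = np.full(self.n_voxels, -1, dtype=np.int32)
                idx[valid] = self.index_map[tuple(tgt[valid].T)]
                nb[:, k] = idx
                wrapf[:, k] = wrapped & (idx >= 0)
                k += 1
        # compact open faces to the front
        order = np.argsort(nb < 0, axis=1, kind="stable")
        self.neighbors = np.take_along_axis(nb, order, axis=1)
        self.wrap = np.take_along_axis(wrapf, order, axis=1)
        self.n_open = (self.neighbors >= 0).sum(axis=1).astype(np.uint8)

        flat_labels = grid.labels[acc]
        self.vesicle = (flat_labels == VESICLE).astype(np.uint8)
        self.in_synapse = grid.synapse_mask[acc]
        self.in_axon = grid.axon_mask[acc]

    def mask_to_flat(self, mask3d: np.ndarray) -> np.ndarray:
        """Boolean 3D mask -> boolean over accessible voxels."""
        return mask3d[self.grid.accessible_mask]


@dataclass
class EquilibrationPolicy:
    """How to relax the initial condition before an experiment.

    ``horizon=None`` picks ``max(1 s, 5 T)``: the initial condition is drawn
    from the exact diffusion-binding equilibrium measure, so the burn-in only
    needs to decorrelate placement, not transport protein across the system.
    ``check_stationarity`` compares bouton occupancy between the two halves
    of the horizon and warns when they differ beyond counting noise.
    """

    horizon: Optional[float] = None
    check_stationarity: bool = True
    n_checkpoints: int = 8
    z_threshold: float = 4.0

    def resolve_horizon(self, params: KineticParams) -> float:
        if self.horizon is not None:
            return self.horizon
        return max(1.0, 5.0 * params.T)


class Simulation:
    """Mutable simulation state bound to one grid and parameter set."""

    def __init__(self, grid: VoxelGrid, params: KineticParams,
                 n_proteins: int = DEFAULT_N_PROTEINS, seed: int = 0,
                 init: str = "equilibrium", lattice: Optional[LatticeIndex] = None):
        self.grid = grid
        self.params = params
        self.lattice = lattice if lattice is not None else LatticeIndex(grid)
        self.n_proteins = int(n_proteins)
        self.seed = seed

        ss = np.random.SeedSequence(seed)
        self.rng = np.random.default_rng(ss)
        st = ss.generate_state(2, dtype=np.uint64)
        if st[0] == 0 and st[1] == 0:
            st[0] = np.uint64(0x9E3779B97F4A7C15)
        self._rng_state = st.copy()

        lat = self.lattice
        a = grid.voxel_edge
        self.hop = params.D_nm2 / (a * a)          # per open face, 1/s
        self.ku = 1.0 / params.T if params.binding else 0.0
        kb = params.k_b if params.binding else 0.0
        self._kb_ves = np.where(lat.vesicle == 1, kb, 0.0)

        self.counts = np.zeros((lat.n_voxels, 4), dtype=np.int64)
        self._seed_proteins(init)

        self.time = 0.0
        self._heap_t = np.empty(lat.n_voxels, dtype=np.float64)
        self._heap_v = np.empty(lat.n_voxels, dtype=np.int32)
        self._pos = np.empty(lat.n_voxels, dtype=np.int32)
        self._no_bleach = np.zeros(lat.n_voxels, dtype=np.uint8)
        _core.init_queue(self.counts, lat.n_open, self._kb_ves, self.ku,
                         self.hop, self._heap_t, self._heap_v, self._pos,
                         self.time, self._rng_state)

    # -- initial condition --------------------------------------------------
    def _seed_proteins(self, init: str) -> None:
        lat = self.lattice
        n = self.n_proteins
        p = self.params
        if init == "equilibrium":
            # stationary measure: voxel weight 1 (+ k_b*T extra on vesicles)
            kT = p.k_b * p.T if p.binding else 0.0
            w = 1.0 + kT * lat.vesicle
            occ = self.rng.multinomial(n, w / w.sum())
            p_bound = kT / (1.0 + kT) if kT > 0 else 0.0
            bound = np.zeros_like(occ)
            if p_bound > 0:
                ves = lat.vesicle == 1
                bound[ves] = self.rng.binomial(occ[ves], p_bound)
            self.counts[:, FREE_UNBLEACHED] = occ - bound
            self.counts[:, BOUND_UNBLEACHED] = bound
        elif init == "uniform":
            occ = self.rng.multinomial(n, np.full(lat.n_voxels, 1.0 / lat.n_voxels))
            self.counts[:, FREE_UNBLEACHED] = occ
        elif init == "axon":
            w = lat.in_axon.astype(float)
            if w.sum() == 0:
                raise ValueError("grid has no axon voxels")
            self.counts[:, FREE_UNBLEACHED] = self.rng.multinomial(n, w / w.sum())
        else:
            raise ValueError(f"unknown init mode {init!r}")

    def _requeue(self) -> None:
        """Recompute all event times (after an external state change)."""
        lat = self.lattice
        _core.init_queue(self.counts, lat.n_open, self._kb_ves, self.ku,
                         self.hop, self._heap_t, self._heap_v, self._pos,
                         self.time, self._rng_state)

    # -- running -------------------------------------------------------------
    def advance(self, t_stop: float, bleach_mask: Optional[np.ndarray] = None,
                max_events: int = 2 ** 62) -> int:
        """Run events up to ``t_stop`` (absolute sim time); returns #events."""
        if t_stop < self.time:
            raise ValueError("t_stop precedes current simulation time")
        lat = self.lattice
        active = bleach_mask is not None
        mask = bleach_mask if active else self._no_bleach
        t, n = _core.advance(self.counts, lat.neighbors, lat.wrap, lat.n_open,
                             self._kb_ves, self.ku, self.hop,
                             self._heap_t, self._heap_v, self._pos,
                             self._rng_state, t_stop, mask, active, max_events)
        self.time = t
        return n

    def step(self) -> float:
        """Execute exactly one event; returns its time. Raises if quiescent."""
        if not np.isfinite(self._heap_t[0]):
            raise QuiescentState("total propensity is zero; time cannot advance")
        self.advance(np.inf, max_events=1)
        return self.time

    # -- bleaching ------------------------------------------------------------
    def apply_instant_bleach(self, region: np.ndarray) -> None:
        """Flag every protein in ``region`` (bool over accessible voxels)."""
        if region.dtype != bool:
            region = region.astype(bool)
        if not region.any():
            raise ValueError("bleach region is empty")
        c = self.counts
        c[region, FREE_BLEACHED] += c[region, FREE_UNBLEACHED]
        c[region, FREE_UNBLEACHED] = 0
        c[region, BOUND_BLEACHED] += c[region, BOUND_UNBLEACHED]
        c[region, BOUND_UNBLEACHED] = 0
        # propensities are label-blind, but event identities change: requeue
        self._requeue()

    def run_continuous_bleach(self, region: np.ndarray, t_b: float) -> None:
        """80-ms style protocol: instant flag, then convert movers for t_b."""
        if t_b <= 0:
            raise ValueError("t_b must be positive for continuous bleaching")
        self.apply_instant_bleach(region)
        self.advance(self.time + t_b, bleach_mask=region.astype(np.uint8))

    # -- observables ------------------------------------------------------------
    def unbleached(self) -> np.ndarray:
        return self.counts[:, FREE_UNBLEACHED] + self.counts[:, BOUND_UNBLEACHED]

    def total_count(self) -> int:
        return int(self.counts.sum())

    def species_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def voxel_propensities(sim: Simulation, voxel) -> dict:
    """Per-channel propensities of one voxel (3D index or flat index)."""
    lat = sim.lattice
    v = int(lat.index_map[tuple(voxel)]) if np.ndim(voxel) else int(voxel)
    if v < 0:
        raise ValueError("voxel is not accessible")
    c = sim.counts[v]
    hop = sim.hop * int(lat.n_open[v])
    kv = sim._kb_ves[v]
    return {
        "hop_free_unbleached": c[0] * hop,
        "hop_free_bleached": c[1] * hop,
        "bind_unbleached": c[0] * kv,
        "bind_bleached": c[1] * kv,
        "unbind_unbleached": c[2] * sim.ku,
        "unbind_bleached": c[3] * sim.ku,
        "total": c[0] * (hop + kv) + c[1] * (hop + kv) + (c[2] + c[3]) * sim.ku,
    }


@dataclass
class EquilibrationReport:
    horizon: float
    stationary: bool
    checkpoints: np.ndarray = field(default=None, repr=False)


def equilibrate(sim: Simulation,
                policy: Optional[EquilibrationPolicy] = None) -> EquilibrationReport:
    """Relax toward steady state; optionally test stationarity.

    The stationarity check compares mean bouton occupancy between the first
    and second half of the horizon with a z-test against binomial counting
    noise; failure emits a warning and sets ``stationary=False``.
    """
    policy = policy or EquilibrationPolicy()
    horizon = policy.resolve_horizon(sim.params)
    lat = sim.lattice
    t0 = sim.time
    ncp = max(2, policy.n_checkpoints)
    cps = np.empty(ncp)
    for i in range(ncp):
        sim.advance(t0 + horizon * (i + 1) / ncp)
        cps[i] = sim.counts[lat.in_synapse].sum()
    stationary = True
    if policy.check_stationarity:
        h1, h2 = cps[: ncp // 2], cps[ncp // 2:]
        # binomial occupancy noise for independent walkers
        frac = cps.mean() / max(sim.n_proteins, 1)
        sd = np.sqrt(max(sim.n_proteins * frac * (1 - frac), 1.0))
        z = abs(h1.mean() - h2.mean()) / (sd * np.sqrt(2.0 / max(len(h1), 1)))
        if z > policy.z_threshold:
            stationary = False
            warnings.warn(
                f"equilibration horizon {horizon:.3g} s ended before the bouton "
                f"occupancy became stationary (z={z:.1f})", RuntimeWarning)
    return EquilibrationReport(horizon=horizon, stationary=stationary,
                               checkpoints=cps)


def save_snapshots(path, frames, times, **meta):
    """Per-frame per-voxel counts in a compressed array container.

    Writes ``<path>.npz`` (frames, times) plus a JSON sidecar ``<path>.json``
    echoing seed/parameters passed as keyword arguments.
    """
    import json
    from pathlib import Path

    p = Path(path)
    np.savez_compressed(p.with_suffix(".npz"), frames=np.asarray(frames),
                        times=np.asarray(times))
    p.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))
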