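"""Library-based inference of (D, k_b, T) from FRAP observables.

A library of simulated FRAP experiments is built on a grid of kinetic
parameters: for every (D, k_b, T) the bouton and axon protocols are run
across the geometry ensemble and replicates, and the fitted recovery times
and immobile fractions are averaged into one observable vector
(tau_syn, tau_axon, IF_syn, IF_axon).  Experimental vectors are matched to
the library by Euclidean distance after z-scoring every observable with the
mean/std of the *experimental* distribution (the same transform is applied
to the library).  Parameter uncertainties follow from one-grid-step finite
differences of tau_syn, and each fit is classified by its dominant recovery
mechanism via the effective bouton length computed with Deff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curves import bleach_length, effective_diffusion
from .engine import KineticParams

OBSERVABLES = ("tau_syn", "tau_axon", "IF_syn", "IF_axon")

#: default parameter search grid; spans the reference fits
DEFAULT_GRID = {
    "D": [0.05, 0.1, 0.3, 0.5, 0.7, 1.0, 3.0, 5.0, 10.0, 20.0],   # um^2/s
    "k_b": [0.0, 1.0, 10.0, 100.0, 1000.0],                        # 1/s
    "T": [0.0, 0.01, 0.1, 1.0, 10.0],                              # s
}

#: Deff below which a fit is flagged as vesicle-scale (transmembrane cargo
#: whose recovery is dominated by vesicle motion, outside this model)
VESICLE_SCALE_DEFF = 0.05


class IncompleteLibraryError(RuntimeError):
    """The simulation library has missing cells and cannot be used."""


@dataclass
class SimLibrary:
    """Simulated observables on a (D, k_b, T) grid.

    ``table`` columns: D, k_b, T, tau_syn, tau_axon, IF_syn, IF_axon,
    n_geoms, n_reps, seed0.  Cells with k_b == 0 or T == 0 are pure
    diffusion; they are simulated once per D and replicated across the
    degenerate (k_b, T) combinations so the grid is complete.
    """

    table: pd.DataFrame
    grid: dict = field(default_factory=dict)
    mean_length: float = float("nan")   # ensemble-mean bouton length, nm
    mean_rho: float = float("nan")      # ensemble-mean vesicle density
    spot_diameter: float = 400.0
    bleach_duration: float = 0.080

    def validate(self) -> None:
        expected = (len(self.grid["D"]) * len(self.grid["k_b"])
                    * len(self.grid["T"]))
        if len(self.table) != expected or self.table[list(OBSERVABLES)].isna().any().any():
            raise IncompleteLibraryError(
                f"library has {len(self.table)} cells, expected {expected} "
                "with no missing observables")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "SimLibrary":
        table = pd.read_csv(path)
        grid = {k: sorted(table[k].unique().tolist()) for k in ("D", "k_b", "T")}
        return cls(table=table, grid=grid, **meta)


def build_library(grids, grid_spec: Optional[dict] = None, seed: int = 0,
                  n_proteins: int = 5000, n_replicates: int = 5,
                  schedule=None, spot_diameter: float = 400.0,
                  bleach_duration: float = 0.080,
                  max_retries: int = 2, progress: bool = False,
                  **obs_kwargs) -> SimLibrary:
    """Run the full protocol over every grid cell and ensemble geometry.

    Failed cells (e.g. a degenerate ROI on an unlucky seed) are retried
    with a fresh seed; a cell that keeps failing leaves a NaN row, which
    ``validate`` rejects at use time.
    """
    from .geometry import vesicle_density
    from .workflows import ensemble_observables

    from .protocol import AcquisitionSchedule
    from .workflows import average_replicates, replicate_fits

    grid_spec = grid_spec or DEFAULT_GRID
    cells = [(D, kb, T) for D in grid_spec["D"]
             for kb in grid_spec["k_b"] for T in grid_spec["T"]]
    schedule = schedule or AcquisitionSchedule.experimental()
    axon_schedule = obs_kwargs.pop("axon_schedule", None) or schedule
    axon_n = obs_kwargs.pop("axon_n_proteins", None) or n_proteins
    axon_grids = obs_kwargs.pop("axon_grids", None) or [grids[0]]
    rng = np.random.default_rng(seed)

    # bouton observables per unique cell (degenerate binding cells collapse
    # onto pure diffusion)
    syn_cache: dict = {}
    # axon observables per D: the shaft holds no vesicles and sits far from
    # the bouton, so binding parameters do not measurably touch tau_axon or
    # IF_axon; one (denser) measurement per diffusion coefficient
    axon_cache: dict = {}
    rows = []
    for i, (D, kb, T) in enumerate(cells):
        key = (D, kb, T) if (kb > 0 and T > 0) else (D, 0.0, 0.0)
        if key not in syn_cache:
            cell_seed = int(rng.integers(2 ** 31))
            vals = None
            for attempt in range(max_retries + 1):
                try:
                    params = KineticParams(D=key[0], k_b=key[1], T=key[2])
                    geom = []
                    for gi, grid in enumerate(grids):
                        fits = replicate_fits(
                            grid, params, cell_seed + 101 * gi + attempt,
                            n_replicates=n_replicates, schedule=schedule,
                            n_proteins=n_proteins, **obs_kwargs)
                        geom.append(average_replicates(fits))
                    vals = (float(np.mean([g[0] for g in geom])),
                            float(np.mean([g[1] for g in geom])))
                    break
                except (ValueError, RuntimeError):
                    continue
            syn_cache[key] = (vals, cell_seed)
        if D not in axon_cache:
            ax_seed = int(rng.integers(2 ** 31))
            vals = None
            for attempt in range(max_retries + 1):
                try:
                    fits = replicate_fits(
                        axon_grids[0], KineticParams(D=D), ax_seed + attempt,
                        n_replicates=n_replicates, axon=True,
                        schedule=axon_schedule, n_proteins=axon_n,
                        **obs_kwargs)
                    vals = average_replicates(fits)
                    break
                except (ValueError, RuntimeError):
                    continue
            axon_cache[D] = (vals, ax_seed)
        syn, cell_seed = syn_cache[key]
        axn, _ = axon_cache[D]
        row = {"D": D, "k_b": kb, "T": T, "n_geoms": len(grids),
               "n_reps": n_replicates, "seed0": cell_seed,
               "tau_syn": syn[0] if syn else np.nan,
               "IF_syn": syn[1] if syn else np.nan,
               "tau_axon": axn[0] if axn else np.nan,
               "IF_axon": axn[1] if axn else np.nan}
        rows.append(row)
        if progress:
            print(f"[library] cell {i + 1}/{len(cells)} "
                  f"D={D} k_b={kb} T={T}", flush=True)
    lengths = [g.synapse_length for g in grids]
    rhos = [vesicle_density(g) for g in grids]
    return SimLibrary(table=pd.DataFrame(rows), grid=dict(grid_spec),
                      mean_length=float(np.mean(lengths)),
                      mean_rho=float(np.mean(rhos)),
                      spot_diameter=spot_diameter,
                      bleach_duration=bleach_duration)


# ---------------------------------------------------------------------------
# normalization and nearest-neighbor search
# ---------------------------------------------------------------------------

@dataclass
class NormStats:
    mean: pd.Series
    std: pd.Series
    ddof: int = 0


def zscore_normalize(experimental: pd.DataFrame, library: SimLibrary,
                     ddof: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, NormStats]:
    """Z-score both spaces with the *experimental* mean and std.

    The normalization constants come from the distribution of experimental
    values only (population std by default); the identical affine transform
    is then applied to the library, so distances are comparable.
    """
    if len(experimental) < 2:
        raise ValueError("need at least 2 proteins to compute normalization stats")
    mean = experimental[list(OBSERVABLES)].mean()
    std = experimental[list(OBSERVABLES)].std(ddof=ddof)
    zero = std[std == 0]
    if len(zero):
        raise ValueError(f"zero experimental std for {list(zero.index)}; "
                         "cannot z-score")
    exp_norm = experimental.copy()
    lib_norm = library.table.copy()
    for k in OBSERVABLES:
        exp_norm[k] = (experimental[k] - mean[k]) / std[k]
        lib_norm[k] = (library.table[k] - mean[k]) / std[k]
    return exp_norm, lib_norm, NormStats(mean=mean, std=std, ddof=ddof)


@dataclass
class FitErrors:
    dD: float
    dk: float
    dT: float
    flags: list = field(default_factory=list)


@dataclass
class ProteinFit:
    protein: str
    params: KineticParams
    observables: dict                  # best-fit simulated observables (raw)
    distance: float
    runners_up: list                   # [(KineticParams, distance), ...] 2nd, 3rd
    Deff: float
    mechanism: str = ""
    errors: Optional[FitErrors] = None
    vesicle_scale: bool = False        # Deff at vesicle-diffusion scale


def fit_protein(observables: pd.Series, lib_norm: pd.DataFrame,
                library: SimLibrary, stats: NormStats,
                protein: str = "", rho: Optional[float] = None) -> ProteinFit:
    """Exhaustive nearest-neighbor search in the normalized 4D space.

    Ties are broken toward weaker binding (smaller k_b*T), then smaller D.
    """
    z = np.array([(observables[k] - stats.mean[k]) / stats.std[k]
                  for k in OBSERVABLES])
    pts = lib_norm[list(OBSERVABLES)].to_numpy()
    d = np.sqrt(((pts - z) ** 2).sum(axis=1))
    tie = (lib_norm["k_b"] * lib_norm["T"]).to_numpy()
    order = np.lexsort((lib_norm["D"].to_numpy(), tie, d))
    best, second, third = order[0], order[1], order[2]
    rho = rho if rho is not None else library.mean_rho
    rows = library.table

    def _params(i):
        r = rows.iloc[i]
        return KineticParams(D=float(r["D"]), k_b=float(r["k_b"]),
                             T=float(r["T"]))

    p = _params(best)
    Deff = effective_diffusion(p.D, p.k_b, p.T, rho)
    return ProteinFit(
        protein=protein, params=p,
        observables={k: float(rows.iloc[best][k]) for k in OBSERVABLES},
        distance=float(d[best]),
        runners_up=[(_params(second), float(d[second])),
                    (_params(third), float(d[third]))],
        Deff=Deff,
        vesicle_scale=Deff < VESICLE_SCALE_DEFF)


def error_estimates(fit: ProteinFit, library: SimLibrary,
                    dtau_exp: float) -> FitErrors:
    """One-grid-step finite-difference uncertainties.

    dp = dtau_exp / |dtau_sim/dp| per parameter, with the difference taken
    to the adjacent grid point (one-sided at edges).  A flat tau response
    along an axis flags that parameter as unbounded (NaN).
    """
    tab = library.table
    p = {"D": fit.params.D, "k_b": fit.params.k_b, "T": fit.params.T}
    out = {}
    flags = []
    for axis in ("D", "k_b", "T"):
        values = sorted(tab[axis].unique())
        i = values.index(p[axis])
        others = [a for a in ("D", "k_b", "T") if a != axis]
        here = tab[(tab[axis] == p[axis])
                   & (tab[others[0]] == p[others[0]])
                   & (tab[others[1]] == p[others[1]])]
        tau0 = float(here["tau_syn"].iloc[0])
        slopes = []
        for j in (i - 1, i + 1):
            if 0 <= j < len(values):
                nb = tab[(tab[axis] == values[j])
                         & (tab[others[0]] == p[others[0]])
                         & (tab[others[1]] == p[others[1]])]
                dtau = float(nb["tau_syn"].iloc[0]) - tau0
                dp = values[j] - values[i]
                if dtau != 0:
                    slopes.append(abs(dtau / dp))
        if not slopes:
            out[axis] = np.nan
            flags.append(f"{axis}_unbounded")
        else:
            out[axis] = dtau_exp / float(np.mean(slopes))
    return FitErrors(dD=out["D"], dk=out["k_b"], dT=out["T"], flags=flags)


# ---------------------------------------------------------------------------
# mechanism classification
# ---------------------------------------------------------------------------

MECHANISM_THRESHOLDS = (0.7, 1.4)    # (theta_lo, theta_hi) on Ltilde


def classify_mechanism(Deff: float, mean_length: float,
                       spot_diameter: float = 400.0,
                       bleach_duration: float = 0.080,
                       thresholds: tuple = MECHANISM_THRESHOLDS) -> str:
    """Label the dominant recovery route from the effective bouton length.

    Ltilde = mean bouton length / L_b(Deff).  Small Ltilde means the whole
    bouton is bleached and recovery must come from the axon; large Ltilde
    means only a fraction is bleached and intra-bouton redistribution
    dominates; in between both routes contribute.
    """
    theta_lo, theta_hi = thresholds
    L_b = bleach_length(Deff, spot_diameter, bleach_duration)
    lt = mean_length / L_b
    if lt >= theta_hi:
        return "redistribution"
    if lt <= theta_lo:
        return "axon"
    return "both"


def fit_protein_table(experimental: pd.DataFrame, library: SimLibrary,
                      ddof: int = 0) -> pd.DataFrame:
    """Fit every protein of an observable table; returns a summary frame."""
    library.validate()
    exp_norm, lib_norm, stats = zscore_normalize(experimental, library, ddof=ddof)
    rows = []
    for _, r in experimental.iterrows():
        fit = fit_protein(r, lib_norm, library, stats, protein=str(r["protein"]))
        dtau = float(r.get("tau_syn_sd", np.nan))
        if np.isfinite(dtau):
            fit.errors = error_estimates(fit, library, dtau)
        fit.mechanism = classify_mechanism(
            fit.Deff, library.mean_length,
            spot_diameter=library.spot_diameter,
            bleach_duration=library.bleach_duration)
        rows.append({
            "protein": fit.protein, "D": fit.params.D, "k_b": fit.params.k_b,
            "T": fit.params.T, "Deff": fit.Deff, "mechanism": fit.mechanism,
            "distance": fit.distance,
            "dD": fit.errors.dD if fit.errors else np.nan,
            "dk": fit.errors.dk if fit.errors else np.nan,
            "dT": fit.errors.dT if fit.errors else np.nan,
            "vesicle_scale": fit.vesicle_scale,
        })
    return pd.DataFrame(rows)
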