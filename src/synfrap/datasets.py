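"""Reference data and synthetic stand-ins for the experimental inputs.

Two kinds of tabular input drive the fitting workflow: a geometry parameter
table describing an ensemble of presynaptic boutons (here sampled from the
built-in distributions, emulating an EM-derived 30-synapse set) and a FRAP
observable table per protein (recovery times and immobile fractions in
bouton and axon).  This module ships a small reference table of fitted
kinetic parameters for well-characterized synaptic proteins, used in
examples and as calibration anchors, plus generators for synthetic
observable tables produced by the simulator itself.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .geometry import EnsembleSpec

#: Published best-fit kinetic parameters for five synaptic proteins
#: (D in um^2/s, k_b in 1/s, T in s, Deff in um^2/s) together with the
#: dominant fluorescence recovery mechanism inferred for each.
_REFERENCE_FITS_CSV = """\
protein,category,D,k_b,T,Deff,mechanism
Intersectin 1-L,soluble,1.00,1000.0,1.0,0.021476,redistribution
alpha-Tubulin,cytoskeletal,0.30,0.0,0.0,0.300000,both
Synapsin 1A,soluble,0.70,10.0,0.1,0.669495,both
PIP5KI-gamma,soluble,3.00,10.0,0.1,2.869263,axon
Dynamin,soluble,5.00,100.0,0.1,3.434900,axon
"""


def reference_protein_fits() -> pd.DataFrame:
    """Reference (D, k_b, T, Deff, mechanism) rows for five synaptic proteins."""
    return pd.read_csv(io.StringIO(_REFERENCE_FITS_CSV))


def solve_vesicle_density(D: float, k_b: float, T: float, Deff: float) -> float:
    """Invert Deff = D/(1 + rho*T*k_b) for the vesicle density rho."""
    if k_b <= 0 or T <= 0:
        raise ValueError("rho is only identifiable when binding is active")
    if Deff <= 0 or Deff > D:
        raise ValueError("need 0 < Deff <= D")
    return (D / Deff - 1.0) / (T * k_b)


def implied_vesicle_density() -> float:
    """Ensemble-average vesicle density implied by the binding rows of the
    reference table (the three solved values agree to ~4 digits)."""
    df = reference_protein_fits()
    rows = df[(df["k_b"] > 0) & (df["T"] > 0)]
    rhos = [solve_vesicle_density(r.D, r.k_b, r.T, r.Deff)
            for r in rows.itertuples()]
    return float(np.mean(rhos))


def default_ensemble_spec(n_geometries: int = 30, seed: int = 0) -> EnsembleSpec:
    """The default heterogeneous bouton ensemble (EM-like distributions)."""
    return EnsembleSpec(n_geometries=n_geometries, seed=seed)


def synthetic_observable_table(params_table: pd.DataFrame, grids, seed: int,
                               n_proteins: int = 2000, n_replicates: int = 1,
                               noise_sd: float = 0.0,
                               **frap_kwargs) -> pd.DataFrame:
    """Simulate a per-protein FRAP observable table (stands in for real data).

    ``params_table`` needs columns protein, D, k_b, T.  Each row is run
    through the full bouton + axon FRAP pipeline over ``grids`` and
    summarized into (tau_syn, tau_axon, IF_syn, IF_axon) with per-geometry
    standard deviations.  Optional Gaussian noise (relative, ``noise_sd``)
    emulates experiment-to-experiment variability beyond geometry.
    """
    from .engine import KineticParams
    from .workflows import ensemble_observables

    rng = np.random.default_rng(seed)
    rows = []
    for i, r in enumerate(params_table.itertuples()):
        params = KineticParams(D=float(r.D), k_b=float(r.k_b), T=float(r.T))
        obs = ensemble_observables(grids, params, seed=seed + 1000 * (i + 1),
                                   n_proteins=n_proteins,
                                   n_replicates=n_replicates, **frap_kwargs)
        row = {"protein": r.protein}
        for key in ("tau_syn", "tau_axon", "IF_syn", "IF_axon"):
            val = obs[key]
            if noise_sd > 0:
                val *= 1.0 + noise_sd * rng.standard_normal()
            row[key] = val
        row["tau_syn_sd"] = obs["tau_syn_sd"]
        row["tau_axon_sd"] = obs["tau_axon_sd"]
        rows.append(row)
    return pd.DataFrame(rows)


def read_observable_table(path) -> pd.DataFrame:
    """Read a per-protein FRAP observable CSV (protein, tau_*, IF_*)."""
    df = pd.read_csv(path)
    required = {"protein", "tau_syn", "tau_axon", "IF_syn", "IF_axon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observable table missing columns: {sorted(missing)}")
    return df
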