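"""Recovery-curve fitting and the effective-diffusion / effective-length theory.

FRAP traces normalized to the pre-bleach intensity are fitted with

    I(t) = I(0+) + I0 * (1 - exp(-t / tau)),

where the post-bleach floor I(0+) is a fitted offset: spot bleaching leaves
a positive floor, so the classical zero-floor form is generalized and the
immobile fraction becomes IF = 1 - (I(0+) + I0) in normalized units.  A
two-timescale variant captures the redistribution + axon-influx regime.

Transient vesicle binding at equilibrium retards mobility to

    Deff = D / (1 + rho * T * k_b),

with rho the vesicle (voxel) density of the bouton.  The bleach length
scale L_b = d_b + 2*sqrt(2*D*t_b) measures how far a protein diffuses while
the laser is on; the effective bouton length Ltilde = L / L_b separates
whole-bouton bleaching (Ltilde < 1, recovery by axonal influx) from partial
bleaching (Ltilde > 1, recovery by intra-bouton redistribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

TAU_BOUNDS = (1e-2, 1e4)


@dataclass
class RecoveryTrace:
    """ROI intensity over time, normalized to the pre-bleach value."""

    times: np.ndarray          # s, relative to bleach start, strictly increasing
    intensity: np.ndarray      # normalized (pre-bleach == 1)
    pre_value: float = 1.0     # raw pre-bleach ROI sum
    protocol: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class RecoveryFit:
    """Fitted recovery parameters of one trace."""

    tau: float                     # recovery time, s
    I0: float                      # fitted recovery amplitude (normalized)
    immobile_fraction: float       # 1 - (floor + I0), clipped to [0, 1]
    floor: float                   # fitted I(0+)
    residual: float                # RMS of fit residuals
    model: str = "single_exp"
    tau_fast: Optional[float] = None
    tau_slow: Optional[float] = None
    amplitude_fast: Optional[float] = None
    amplitude_slow: Optional[float] = None
    flags: list = field(default_factory=list)


def _single_exp(t, floor, I0, tau):
    return floor + I0 * (1.0 - np.exp(-t / tau))


def _double_exp(t, floor, A1, tau1, A2, tau2):
    return floor + A1 * (1.0 - np.exp(-t / tau1)) + A2 * (1.0 - np.exp(-t / tau2))


def _tau_init(t, y, floor, amp):
    """Half-recovery heuristic for the initial tau."""
    if amp <= 0:
        return max(t[-1] / 3.0, TAU_BOUNDS[0] * 10)
    half = floor + 0.5 * amp
    above = np.nonzero(y >= half)[0]
    t_half = t[above[0]] if len(above) else t[-1]
    return float(np.clip(t_half / np.log(2.0), TAU_BOUNDS[0] * 10, TAU_BOUNDS[1] / 10))


def fit_single_exponential(trace: RecoveryTrace,
                           floor_mode: str = "fit") -> RecoveryFit:
    """Least-squares single-exponential fit of a post-bleach trace.

    ``floor_mode="fit"`` fits I(t) = I(0+) + I0*(1 - exp(-t/tau)) with the
    post-bleach floor as a free offset, which recovers tau and the immobile
    fraction exactly for traces of that form.  ``floor_mode="zero"`` is the
    classical form I(t) = I0*(1 - exp(-t/tau)) with no offset: when the
    trace opens with a rapid jump (partial bleaching of a bouton), the jump
    pins tau to the fast redistribution timescale, which is how the
    protocol-comparison recovery times are defined.
    """
    t, y = trace.times, trace.intensity
    if len(t) < 5:
        raise ValueError("need at least 5 post-bleach frames to fit")
    flags: list = []
    floor0 = float(np.clip(y[0], 0.0, 1.5))
    amp0 = float(np.clip(y[-5:].mean() - floor0, 0.0, 2.0))
    tau0 = _tau_init(t, y, floor0, amp0)
    try:
        if floor_mode == "zero":
            p0 = (max(float(y[-5:].mean()), 1e-3), tau0)
            bounds = ([0.0, TAU_BOUNDS[0]], [2.0, TAU_BOUNDS[1]])
            popt, _ = curve_fit(lambda tt, I0, tau: _single_exp(tt, 0.0, I0, tau),
                                t, y, p0=p0, bounds=bounds, maxfev=20000)
            popt = np.concatenate([[0.0], popt])
        elif floor_mode == "fit":
            p0 = (floor0, max(amp0, 1e-3), tau0)
            bounds = ([-0.5, 0.0, TAU_BOUNDS[0]], [1.5, 2.0, TAU_BOUNDS[1]])
            popt, _ = curve_fit(_single_exp, t, y, p0=p0, bounds=bounds,
                                maxfev=20000)
        else:
            raise ValueError(f"unknown floor_mode {floor_mode!r}")
    except RuntimeError as err:
        raise RuntimeError(f"single-exponential fit failed to converge: {err}") from err
    floor, I0, tau = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((_single_exp(t, *popt) - y) ** 2)))
    if tau <= TAU_BOUNDS[0] * 1.01 or tau >= TAU_BOUNDS[1] * 0.99:
        flags.append("tau_at_bound")
    recovery_span = float(y.max() - y.min())
    if I0 < 1e-3 or recovery_span < 1e-3:
        flags.append("tau_unidentifiable")
    imm = 1.0 - (floor + I0)
    if imm < 0.0 or imm > 1.0:
        flags.append("immobile_fraction_clipped")
    imm = float(np.clip(imm, 0.0, 1.0))
    return RecoveryFit(tau=tau, I0=I0, immobile_fraction=imm, floor=floor,
                       residual=resid, model="single_exp", flags=flags)


def fit_double_exponential(trace: RecoveryTrace) -> RecoveryFit:
    """Two-timescale fit; tau_fast < tau_slow enforced by sorting."""
    t, y = trace.times, trace.intensity
    if len(t) < 7:
        raise ValueError("need at least 7 post-bleach frames to fit")
    flags: list = []
    floor0 = float(np.clip(y[0], 0.0, 1.5))
    amp0 = float(np.clip(y[-5:].mean() - floor0, 0.0, 2.0))
    tau0 = _tau_init(t, y, floor0, amp0)
    p0 = (floor0, max(amp0 / 2, 1e-3), max(tau0 / 5, TAU_BOUNDS[0] * 10),
          max(amp0 / 2, 1e-3), min(tau0 * 5, TAU_BOUNDS[1] / 10))
    bounds = ([-0.5, 0.0, TAU_BOUNDS[0], 0.0, TAU_BOUNDS[0]],
              [1.5, 2.0, TAU_BOUNDS[1], 2.0, TAU_BOUNDS[1]])
    try:
        popt, _ = curve_fit(_double_exp, t, y, p0=p0, bounds=bounds, maxfev=40000)
    except RuntimeError as err:
        raise RuntimeError(f"double-exponential fit failed to converge: {err}") from err
    floor, A1, tau1, A2, tau2 = (float(v) for v in popt)
    if tau1 > tau2:
        A1, tau1, A2, tau2 = A2, tau2, A1, tau1
    resid = float(np.sqrt(np.mean((_double_exp(t, *popt) - y) ** 2)))
    total_amp = A1 + A2
    if total_amp > 0 and min(A1, A2) / total_amp < 1e-3:
        flags.append("degenerate_component")
    imm = float(np.clip(1.0 - (floor + total_amp), 0.0, 1.0))
    # headline tau: amplitude-weighted mean of the two timescales
    tau = (A1 * tau1 + A2 * tau2) / total_amp if total_amp > 0 else tau2
    return RecoveryFit(tau=tau, I0=total_amp, immobile_fraction=imm, floor=floor,
                       residual=resid, model="double_exp",
                       tau_fast=tau1, tau_slow=tau2,
                       amplitude_fast=A1, amplitude_slow=A2, flags=flags)


# ---------------------------------------------------------------------------
# effective diffusion / effective length
# ---------------------------------------------------------------------------

def effective_diffusion(D: float, k_b: float, T: float, rho: float) -> float:
    """Binding-retarded mobility Deff = D / (1 + rho*T*k_b).

    Valid when binding/unbinding equilibrate fast compared with the
    experiment; rho is the vesicle voxel density of the bouton.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    return D / (1.0 + rho * T * k_b)


def bleach_length(D: float, spot_diameter: float = 400.0,
                  bleach_duration: float = 0.0) -> float:
    """L_b = d_b + 2*sqrt(2*D*t_b) in nm (D in um^2/s, t_b in s)."""
    return spot_diameter + 2.0 * np.sqrt(2.0 * D * 1e6 * bleach_duration)


def effective_length(L: float, D: float, spot_diameter: float = 400.0,
                     bleach_duration: float = 0.0,
                     include_spot_diameter: bool = True) -> tuple[float, float]:
    """Return (L_b, Ltilde = L / L_b); pass Deff for D when binding is present.

    ``include_spot_diameter=False`` drops d_b from L_b (pure diffusive
    spread), an alternative reading of the binding-case rescaling.
    """
    if L <= 0 or D < 0 or spot_diameter <= 0 or bleach_duration < 0:
        raise ValueError("arguments must be positive (t_b may be 0)")
    d_b = spot_diameter if include_spot_diameter else 0.0
    L_b = d_b + 2.0 * np.sqrt(2.0 * D * 1e6 * bleach_duration)
    if L_b <= 0:
        raise ValueError("bleach length scale is zero; cannot rescale")
    return float(L_b), float(L / L_b)


def average_replicates(fits: Sequence[RecoveryFit]) -> tuple[float, float]:
    """Arithmetic mean of fitted tau and immobile fraction.

    The fitted values are averaged, not the traces: the mean of taus from
    replicate fits differs in general from the tau of the mean trace.
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    tau = float(np.mean([f.tau for f in fits]))
    imf = float(np.mean([f.immobile_fraction for f in fits]))
    return tau, imf


def plot_master_curve(df, ax=None, x="L_tilde", y="tau_syn", hue="D"):
    """Scatter recovery time against effective bouton length, colored by D."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(df[x], df[y], c=df[hue], cmap="viridis", s=18,
                    norm=None if df[hue].nunique() == 1 else "log")
    ax.set_xscale("log")
    ax.set_xlabel(r"effective bouton length $\tilde{L} = L / L_b$")
    ax.set_ylabel(r"$\tau_{syn}$ (s)")
    plt.colorbar(sc, ax=ax, label=r"$D$ ($\mu$m$^2$/s)")
    return ax
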