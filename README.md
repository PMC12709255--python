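# synfrap — in silico FRAP in synaptic boutons

Fluorescence recovery after photobleaching (FRAP) is the workhorse for
measuring protein mobility in synapses, but its readout — a recovery time
τ and an immobile fraction — is hard to interpret in a presynaptic bouton:
the confined geometry, the heterogeneity of bouton sizes, and transient
binding to the synaptic vesicle cluster all shape the recovery curve as
much as the diffusion coefficient does.  `synfrap` simulates the entire
measurement: stochastic reaction–diffusion of proteins on a voxelized
bouton+axon geometry, the photobleaching protocols, synthetic microscopy
images, ROI selection and curve fitting — and then inverts it, inferring a
protein's diffusion coefficient *D*, vesicle binding rate *k_b* and mean
retention time *T* from measured FRAP observables.

It is aimed at quantitative neurobiologists and biophysicists who want to
go from FRAP tables to kinetic parameters, and at modelers who need a fast
spatial-Gillespie sandbox for confined geometries.

## Model

* **Geometry** — the bouton is a prolate ellipsoid (rotationally symmetric,
  major axis collinear with a 200-nm-diameter, 5-µm-long axon) voxelized at
  25 nm.  Mitochondria and vacuoles are excluded volume; each synaptic
  vesicle occupies one voxel that stays accessible but allows binding.
  A built-in sampler draws heterogeneous 30-bouton ensembles.
* **Dynamics** — a reaction–diffusion master equation solved by the next
  subvolume method (event-driven spatial Gillespie).  Free proteins hop
  between face-adjacent voxels at rate D/a² per open face (6D/a² total); in
  vesicle voxels they bind at rate k_b and unbind at rate 1/T; bound
  proteins are immobile.  The axon ends are periodic, and bleached proteins
  crossing them re-enter unbleached — an infinite reservoir of fresh
  protein, as provided in reality by the rest of the axon.
* **Measurement** — three bleaching protocols (whole bouton instantaneous;
  400-nm spot instantaneous; 400-nm spot for 80 ms, flagging every protein
  that enters the beam), synthetic 128×128 images (2D projection convolved
  with a Gaussian PSF), difference-image ROI selection
  (I_D > ⟨I_D⟩ + 0.5·std, whole-image statistics), and single- or
  double-exponential fits I(t) = I₀(1 − e^(−t/τ)).
* **Theory** — transient binding retards mobility to
  D_eff = D / (1 + ρ·T·k_b) with ρ the vesicle density, and recovery
  regimes are organized by the effective bouton length
  L̃ = L / L_b, L_b = d_b + 2√(2·D·t_b): for L̃ < 1 the whole bouton is
  bleached and recovery is axonal influx; for L̃ > 1 only part of it is,
  and fast intra-bouton redistribution dominates.  τ(L̃) has a maximum
  near L̃ ≈ 1.
* **Inference** — a library of simulated (τ_syn, τ_axon, IF_syn, IF_axon)
  on a (D, k_b, T) grid is matched to experimental observables by Euclidean
  distance after z-scoring with the experimental statistics; uncertainties
  come from one-grid-step finite differences, and each fit is labeled with
  its dominant recovery mechanism (axon / redistribution / both).

## Worked example

```python
import numpy as np
from synfrap import (GeometryParams, KineticParams, build_geometry,
                     BleachSpec, AcquisitionSchedule, run_frap,
                     fit_single_exponential, effective_diffusion)
from synfrap.geometry import vesicle_density

bouton = build_geometry(GeometryParams(major_axis_length=500,
                                       aspect_ratio=1.4, n_vesicles=600,
                                       n_mitochondria=1, n_vacuoles=2,
                                       organelle_volume_fraction=0.1),
                        seed=7)
res = run_frap(bouton, KineticParams(D=0.1),
               BleachSpec(mode="spot_continuous"),
               AcquisitionSchedule.experimental(), seed=42,
               n_proteins=2000)
fit = fit_single_exponential(res.trace, floor_mode="zero")
print(f"tau = {fit.tau:.2f} s, immobile fraction = {fit.immobile_fraction:.2f}")
print(f"rho = {vesicle_density(bouton):.4f}")
```

prints (exact values depend on the seed):

```
tau = 3.36 s, immobile fraction = 0.38
rho = 0.0390
```

τ is the single-exponential recovery time of the ROI intensity after the
80-ms spot bleach — here a few seconds, set by redistribution of unbleached
protein inside the 1-µm bouton plus influx from the axon; the immobile
fraction is the part of the pre-bleach intensity not recovered at the fit
plateau within the 80-s recording.  ρ is the fraction of accessible bouton
voxels carrying a vesicle, the quantity that converts (k_b, T) into an
effective diffusion coefficient:

```python
print(effective_diffusion(D=0.70, k_b=10.0, T=0.1, rho=0.0456))  # 0.66947
```

A command-line interface mirrors the library
(`synfrap ensemble|geometry|frap|library|fit --help`).

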