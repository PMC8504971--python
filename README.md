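# tcrtilt

Analysis toolkit for structure ensembles of the membrane-embedded
TCR–CD3 complex — the eight-chain T-cell receptor machine whose
antigen-binding TCRαβ extracellular (EC) domain tilts and rotates over the
membrane while its CD3 signaling partners hold station.  Given an ensemble
of conformations (e.g. thousands of frames extracted from molecular-dynamics
trajectories, as multi-model PDB), `tcrtilt` quantifies that orientational
variability and everything coupled to it:

* **Orientation.**  Axis A connects the centres of mass of the constant
  dimer Cαβ and the variable dimer Vαβ; axis B connects the COMs of Vα and
  Vβ.  The *tilt angle* τ is the angle between axis A and the membrane
  normal; the *rotation angle* is the angle between axis B and the normal of
  the (axis A, membrane normal) plane, signed positive when Vα is the
  membrane-proximal variable domain.  TM-helix *inclinations* come from the
  line connecting the COMs of the two halves of each helix span.
* **Contacts.**  Two residues from different EC dimers (TCRαβ, CD3εδ,
  CD3εγ) are in contact when their minimum heavy-atom distance is < 0.45 nm.
  The toolkit builds ensemble contact-probability maps (reported above a
  0.5 % threshold), per-frame contact counts for Ig loop/strand elements
  (Cβ FG loop, Cα DE loop, Vα A′B loop, …), contact clusters, and
  cluster–cluster occupancy correlations.
* **Tilt-coupled statistics.**  Tilt-binned profiles with errors from five
  trajectory subsets, the 2D tilt × rotation density, distribution moments
  and KDE modes, and per-time convergence series with an explicit 0.5 µs
  equilibration gate.
* **Force–tilt model.**  A transversal force *f* on a bound receptor–ligand
  complex of extension *h* adds the energy −*f·h·*sin τ, so the tilt density
  reweights as  P_f(τ) ∝ P₀(τ)·exp(*f h* sin τ / k_B T).  The package
  computes reweighted densities, mode shifts, and the membrane-surface
  separation *h·*cos τ relevant to kinetic-segregation arguments.
* **Membrane.**  The annulus of POPC lipids in heavy-atom contact
  (< 0.5 nm) with the TM helices, and the bilayer thickness measured between
  the annulus headgroup COMs of the two leaflets.
* **Synthetic ensembles.**  A generator that samples frames from prescribed
  statistical laws (truncated-Gaussian tilt, tilt-coupled rotation and
  inclinations, logistic tilt-gated contact occupancies, toy bilayer) and
  builds coordinates realizing them exactly, so the whole pipeline is
  testable end to end without any download.

## Worked example

```python
from tcrtilt.force_model import gaussian_surrogate, reweight, mode_of, separation_change

# force-free tilt density from the equilibrated-ensemble moments
model = gaussian_surrogate(33.4, 8.9)          # degrees; h = 13 nm, T = 303 K
for f in (2.0, 5.0):
    print(f, mode_of(model.tau, reweight(model, f)))
print(separation_change(13.0, 34.0, 49.0))
```

prints

```
2.0 39.98359004013403
5.0 47.822615394577994
2.2487210663389465
```

— a 2 pN transversal force shifts the most probable tilt from ~33° to
~40°, 5 pN to ~48°, and a 34° → 49° tilt change of a 13 nm complex pulls
the membranes ~2.2 nm closer together.

The end-to-end drivers live under `analysis/` (run from the repo root):
`01_simulate.py` samples the stated-world synthetic ensemble,
`02_analyze_ensemble.py` builds its coordinates and runs the full pipeline
(orientations, contact maps, profiles, density, thickness, force model) into
`results/analysis/`, `03_equilibration.py` demonstrates the convergence
series and the 0.5 µs gate on a drifting ensemble, and `04_force_tilt.py`
tabulates force-dependent mode shifts.  The same pipeline is available from
a shell as `tcr-tilt analyze|force-tilt|synth`.

## Acceptance script

`scripts/acceptance.py` recomputes the force-tilt headline numbers from
scratch — it builds the truncated-Gaussian force-free density from the
reported moments, Boltzmann-reweights it at 2 pN and 5 pN
(h = 13 nm, T = 303 K), and writes the resulting density modes (degrees) as
JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
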