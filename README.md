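# budmorph

Image-based modelling toolkit for epithelial branching morphogenesis
driven by ligand–receptor signalling:

- **Reaction–diffusion model family (T1–T5)** — a receptor confined to the
  epithelium and a diffusible ligand produced in the surrounding
  mesenchyme, with cooperative complex formation and receptor
  up-regulation; variants disable one patterning ingredient at a time
  (T2: no up-regulation, T3: equal diffusivities, T4: non-cooperative),
  and T5 adds a second, tip-induced ligand that feeds back on ligand
  production.
- **Linear stability analysis** — necessary conditions (ligand faster
  than receptor, net positive feedback, cooperativity) and the full
  dispersion relation for diffusion-driven instability.
- **Finite-element solver** — P1 triangles on subdomain-labelled meshes
  of two-layer (epithelium + elliptical mesenchyme) domains;
  pseudo-transient continuation to steady state; signalling profiles
  `R^m L^n` extracted on the epithelium–mesenchyme interface.
- **Image pipeline** — segmentation of mask images, border extraction,
  periodic least-squares spline fits, normal-ray displacement fields
  between consecutive frames, outward-only growth fields, and 2D
  interbud minimal distances with image-edge discarding.
- **Model selection** — normalised signalling `C` vs normalised growth
  `E`, the boundary-integral deviation `Δ` and its sum over frames
  `Δ_g`, log-uniform parameter screening and variant ranking.
- **Free-boundary branching simulator** — interface advances along its
  outward normal at a speed saturating in the local signal, the outer
  mesenchyme expands at constant speed, the domain is re-meshed
  periodically; tips are detected by curvature and branch events
  (bifurcations/trifurcations) logged; includes the two-opposing-bud
  elongation classification (`Λ`) and ligand-source (uniform/bead)
  perturbations.
- **Tip-density statistics** — minimum-volume enclosing ellipsoid
  (Khachiyan), surface area per tip, neighbourhood median tip-to-tip
  distance, volume binning, and Welch's t-test from group summaries.
- **Synthetic data** — parametric bud shapes, growth-field time lapses
  with ground truth, rasterised noisy masks, Poisson-disk tip clouds on
  ellipsoid surfaces, and frozen stability-verified fixture parameter
  sets.

## CLI

```bash
budmorph solve  --domain domain.json --model T1 --h 1.0 --seed 0 --out state.npz
budmorph screen --frames frames.json --variants T1,T2,T3,T4 --n 200 --seed 0
budmorph branch --model T1 --t-end 400 --remesh-every 10 --seed 0
budmorph make-fixtures --outdir fixtures
```

Domains are serialised as JSON (`TwoLayerDomain.to_json`), boundary
curves as x,y CSV, meshes exportable to Gmsh v2 `.msh`.

## Layout

```
src/budmorph/
  geometry.py        boundary curves, moment-derived mesenchyme ellipse,
                     conforming two-subdomain meshing
  rd_models.py       parameter sets, model variants, stability analysis
  fem_solver.py      P1 steady-state solver, interface profiles,
                     mesh-convergence studies
  image_pipeline.py  segmentation, border extraction, displacement and
                     growth fields, interbud distances
  model_selection.py C/E normalisation, deviation Δ and Δ_g, parameter
                     sampling, model screening/ranking
  branching_sim.py   free-boundary growth, tip detection, event logging,
                     elongation classification, two-bud experiments
  tip_statistics.py  enclosing ellipsoid, tip-density metrics, Welch test
  synthetic_data.py  generators and frozen fixture parameter sets
  scenarios.py       canonical domains/growth laws shared by tests,
                     the CLI, and the acceptance script
  cli.py             click-based command-line interface
```
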