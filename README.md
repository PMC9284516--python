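# deeroligo

Tools for connecting pulsed-EPR DEER measurements of Cu²⁺-labeled
amyloid-beta oligomers to structural ensemble models of the underlying
tetramers.

DEER (double electron-electron resonance) measures the dipolar coupling
between unpaired electron spins — here the Cu²⁺ ions bound at the
peptide N-termini — and is sensitive to 1-8 nm separations.  Inverting
the dipolar trace gives the Cu-Cu distance distribution, which can then
be compared with the distance statistics of candidate oligomer models:
tetramers assembled from Cu-cross-linked dimers (Cub, one Cu bridging
Asp1/His6 of one chain and His13 of the other), from non-cross-linked
1:1 complexes (Cu1), or from 1:2 complexes with Cu on every other chain
(Cuh).  Cross-linked dimers hold their Cu centers ~2 nm apart, while
non-cross-linked dimers allow much shorter Cu-Cu contacts — so the
position and shape of the recovered distribution discriminates between
assembly models.

The package provides, as a library plus a `deeroligo` command line:

- **Forward model** — powder-averaged dipolar kernel
  K(t,r) = ∫₀¹ cos(2π ν₀ r⁻³ (1−3x²) t) dx with ν₀ = 52.04 MHz·nm³,
  form factor F(t) = ∫ p(r) K(t,r) dr, and exponential background for a
  homogeneous 3-D spin bath.
- **Inversion** — tail fit of background and modulation depth, Tikhonov
  regularization with a second-derivative penalty and non-negativity
  (NNLS on the stacked system), L-curve corner selection of α, and mode
  extraction: p̂ = argmin_{p≥0} ‖Kp − F‖² + α²‖Lp‖².
- **Ensemble geometry** — per-pair-class (intra- vs inter-dimer) Cu-Cu
  distance distributions and coordination-plane orientation statistics
  from multi-model PDB ensembles.
- **Compactness filter** — Shrake-Rupley SASA and the assembled-tetramer
  criterion SASA(ABCD)/(SASA(AB)+SASA(CD)) < 0.95; radius of gyration.
- **Statistics** — rank tests between distance samples and
  representative-configuration selection from 2-D structural histograms.
- **Synthetic data** — ensembles with controllable distance laws,
  plane-normal alignment, stoichiometry, and compactness, plus DEER
  traces with known ground truth, so the whole chain is testable.

## Worked example

Simulate a measurement whose true Cu-Cu distribution is Gaussian at
2.25 ± 0.2 nm on the experimental acquisition grid (first delay 100 ns,
10 ns steps, 200 points), then invert it:

```sh
$ deeroligo simulate-deer --mean 2.25 --sd 0.2 --seed 4 --out trace.dat
wrote trace to trace.dat (+ .truth sidecar)
$ deeroligo invert-deer --trace trace.dat --alpha AUTO --out dist.dat
mode = 2.225 nm (alpha 1); wrote dist.dat
```

The recovered mode, 2.225 nm, reproduces the simulated truth to within
one grid step (0.035 nm); `dist.dat` holds the full distribution and
the fit report (fitted modulation depth and background rate) in its
header.

The full model-vs-experiment loop on a synthetic cross-linked-dimer
world:

```sh
$ deeroligo gen-synthetic --out ens.pdb --n-configs 100 --intra-mean 2.1 --seed 1
wrote 100 configurations to ens.pdb
$ deeroligo compare-dists --pdb ens.pdb
mannwhitney: p = 2.962e-72 (n1=200, n2=400, effect -1.476 nm, significant=True)
$ deeroligo filter-tetramers --pdb ens.pdb
accepted fraction: 1.000 (100 models)
```

The intra-dimer distances (2.1 nm law) are significantly shorter than
the inter-dimer ones (3.6 nm law), and every generated configuration
passes the SASA compactness filter — the signatures of an assembled
tetramer of cross-linked dimers.  `deeroligo run-all --config cfg.json
--out report.txt` chains everything (ensemble statistics, trace
simulation, inversion, comparison) into one seeded, reproducible
report.

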