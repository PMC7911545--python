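# integrinkd

Live-cell quantification of integrin–RGD binding: from the composition of a
mixed PLL-g-PEG / PLL-g-PEG-RGD surface coating and single-cell adhesion
measurements to a two-dimensional equilibrium dissociation constant
K<sub>d</sub><sup>2D</sup> and its molar equivalent.

## The problem

Integrins are the transmembrane receptors through which mammalian cells grip
RGD (Arg-Gly-Asp) motifs on a surface. Because the reaction is confined to
the cell–substrate interface, its equilibrium is naturally described by a
*two-dimensional* dissociation constant — the RGD surface density (1/µm²) at
which half of the available receptors are bound. `integrinkd` implements the
complete analysis for two label-free, live-cell assays that measure it:

* **Micropipette detachment (CCMP).** Adhered cells are probed with a
  stepwise increasing negative pressure (six rounds, 0.07–0.22 atm by
  default); the remaining-cell counts per round give detachment curves,
  detachment-pressure histograms, and the weighted-average detachment
  pressure *W* — a scalar adhesion measure per coating condition.
* **Resonant waveguide grating (RWG) biosensor.** Each well's resonant
  wavelength shift Δλ(t) (pm) tracks adhesion kinetics; traces are fitted
  with the logistic model dλ/dt = rλ(1 − λ/λ<sub>max</sub>) and the plateau
  λ<sub>max</sub> is the steady-state adhesion response.

Either response is assumed proportional to the number of bound ligands *B*,
which at steady state follows the kinetic mass action law (KMAL)

    B(L0) = L0 · I0 / (L0 + Kd2D)

where L₀ is the RGD surface density, itself set by the coating mixture:

    rho_RGD = (Γ / M_pol) · (Q/100) · (N_Lys / g) · (P/100)

(Γ adsorbed mass density, M_pol copolymer weight, N_Lys lysines per
backbone, g grafting ratio, P functionalized fraction, Q the percentage of
RGD-bearing copolymer in the mixture). Fitting the KMAL curve across a Q
sweep yields K<sub>d</sub><sup>2D</sup>; dividing by the confinement-zone
thickness l<sub>c</sub> (≈100 nm cell–substrate separation) converts it to
a molar constant:

    Kd3D = Kd2D / lc        (reported in µM)

The package also decomposes each detachment histogram into weak (detached
in round 1), moderate, and strong (never detached) adhesion subpopulations,
and assembles density-ordered adhesion heat maps.

Because the raw instrument data are not publicly deposited, a first-class
synthetic-data generator reproduces both experiment designs from a known
ground-truth K<sub>d</sub><sup>2D</sup>, so the whole pipeline is validated
by parameter recovery.

## Worked example

Simulate a biosensor experiment with ground truth
K<sub>d</sub><sup>2D</sup> = 8400 µm⁻² and analyze it end to end:

```sh
integrinkd simulate rwg --kd2d 8400 --seed 7 --out demo/
integrinkd run --kinetics-csv demo/kinetic_traces.csv --out demo/summary.json
```

The summary reports (abridged):

```
kd_2d_per_um2   8414.8    se_kd_2d     58.7
kd_3d_uM         139.7    se_kd_3d_uM   0.97
```

i.e. the fitted plateau profile across the eight coating mixtures
(λ<sub>max</sub> rising from 9.9 pm at Q = 1% to 236.4 pm at Q = 100%)
recovers the generating constant to 0.2%, and the molar equivalent at
l<sub>c</sub> = 100 nm is ≈140 µM. Useful one-shot commands:

```sh
integrinkd density --q 100          # RGD density (1/µm²) and hexagonal spacing (nm)
integrinkd convert --kd2d 4503 --se 1673   # 2D -> molar Kd: 75 ± 28 µM
integrinkd detach --input counts.csv       # curves, histograms, W, subpopulations
```

All commands are thin wrappers over the library (`integrinkd.rgd_density`,
`fit_kmal`, `kd_2d_to_3d`, `run_pipeline`, ...).

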