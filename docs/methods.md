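# Methods

## Surface chemistry

The RGD molar surface density of a mixed PPR/PP coating is

    rho_RGD = (Γ / M_pol) · (Q/100) · (N_Lys / g) · (P/100)

with Γ the adsorbed mass density (ng/cm², default 97), M_pol the copolymer
molecular weight (kDa, default 107.76), N_Lys the mean lysines per PLL
backbone (136.82), g the grafting ratio (lysines per PEG chain, 3.5), P the
percentage of functionalized PEG chains (14.7) and Q the PPR percentage of
the mixture. Internally all conversions route through SI factors
(1 ng/cm² = 10⁻¹⁷ g/µm², 1 kDa = 10³ g/mol); densities are held in mol/µm²
and converted to number densities with the exact SI Avogadro constant
6.02214076 × 10²³ /mol. The mean ligand spacing assumes hexagonal packing,
d = sqrt((2/√3)/ν), reported in nm. Q and P are accepted as percentages
only; values above 100 are rejected rather than reinterpreted as fractions.
At the default composition the pipeline gives ν ≈ 3.115 × 10⁴ µm⁻² and
d ≈ 6.09 nm at Q = 100%, scaling as d ∝ Q^(−1/2).

## Micropipette detachment statistics

Counts x_n of cells remaining after round n (applied pressure p_n) are
reduced to remaining fractions either by **averaging** the per-replicate
ratios (R_a = mean of x_n/x_0; standard error = sample SD across replicates
/ √k) or by **pooling** (R_p = Σx_n / Σx_0, no error bar). The two agree
exactly when replicates start with equal cell counts. Differencing the
curve (with the implied round-0 value 1) gives the per-bin detachment mass;
the never-detached fraction forms a terminal bin.

The weighted-average detachment pressure is

    W = Σ_bins mass_b · midpoint_b ,

identical to the population mean of per-cell bin midpoints. Bins are
(p_{n−1}, p_n] with p_0 = 0 atm: a cell removed in round 1 is only known to
have a critical pressure below p_1, so it is represented by p_1/2. The
terminal bin has no upper edge in the protocol; we extrapolate the last
step symmetrically and use midpoint p_N + (p_N − p_{N−1})/2 (0.235 atm for
the default schedule; 1.5·p_1 for a one-round schedule). This treats the
terminal bin like an interior bin and is configurable by supplying a custom
schedule; any alternative convention changes W for strongly adherent
populations and should be reported alongside results.

The default schedule is six pressures from 0.07 to 0.22 atm in 0.03-atm
steps (25 ms pulses). Subpopulations: weak = mass of bin 1, strong =
terminal mass, moderate = remainder. The heat map stacks per-condition bin
masses as rows ordered by ligand density.

The proximity filter removes every cell with a neighbour strictly closer
than 70 µm (both members of a close pair), matching the pipette's probing
footprint; ties at exactly the threshold are kept. It is implemented with a
k-d tree and validated against an all-pairs check.

## KMAL fit and molar conversion

The saturation model B = L₀I₀/(L₀ + K_d^2D) is fitted by bounded nonlinear
least squares (both parameters positive) with a deterministic, scale-free
start: K_d₀ = median positive density, I₀ = 1.1 × max response, and a small
deterministic restart grid (K_d₀ × {0.1, 10}, I₀ × {0.5, 2}) on failure.
The fit is unweighted by default; per-point standard errors can be supplied
for 1/se² weighting. I₀ is treated purely as a fit amplitude. Standard
errors are sqrt of the diagonal of (JᵀJ)⁻¹s² with s² the residual variance
— the conventional curve-fit covariance. Flat responses leave K_d
unidentifiable; the fit then reports a `saturated` diagnostic instead of a
meaningful estimate.

The molar constant divides the areal constant by the confinement-zone
thickness l_c (default 100 nm, the typical cell–substrate separation):
K_d^3D = K_d^2D / l_c · 10¹⁵ / N_A mol/L, reported in µM and rounded to the
nearest µM in human-readable output. The relative standard error is
preserved exactly by the linear conversion. The anchors 4503 ± 1673 µm⁻² →
75 ± 28 µM and 8433 ± 1679 µm⁻² → 140 ± 28 µM pin the direction of the
conversion (division, not multiplication, by l_c).

## Logistic kinetics

Biosensor traces are fitted with the closed-form solution of
dλ/dt = rλ(1 − λ/λ_max),

    λ(t) = λ_max λ₀ / (λ₀ + (λ_max − λ₀) e^{−rt}),

written in the decaying-exponential form so large rt cannot overflow.
Fitting the closed form rather than integrating the ODE is exact, faster
and better conditioned. Starts are deterministic: λ_max from 1.05× the
trace maximum, λ₀ from the first positive shift floored at 1% of λ_max
(negative early samples from sensor noise are tolerated rather than
edited), r from the early-phase log-slope. Traces are fitted per well;
per-condition responses are the mean λ_max over wells with the standard
error across wells. A fitted plateau exceeding the observed maximum by more
than 50% flags the trace `plateau unresolved`. Baseline correction, when
requested, subtracts the mean over a user-declared window.

## Synthetic data generator

The generator emulates both experiment designs from a known ground truth
K_d^2D, mirroring the proportionality assumption the inference itself
makes: with saturation s = ρ/(ρ + K_d^2D),

* **Detachment:** each cell draws a critical pressure from a lognormal with
  median α·s and log-dispersion σ_cell; a fraction `weak_floor` instead
  draws from the component of the *lowest* simulated density, emulating a
  persistently weak-adhering phenotype present at every ligand density.
  Counts are obtained by thresholding against the schedule, so they are
  monotone by construction and per-cell tables agree exactly with count
  tables.
* **Biosensor:** per condition the plateau is λ_sat·s; each well's trace is
  the logistic solution (λ₀ = 2% of plateau) plus iid Gaussian noise.

Defaults are the experiment design itself: Q ∈ {1, 2, 3, 5, 10, 25, 50,
100}%, 3 replicates of 110 detected cells (within the 95–130 range a
filtered field of view yields), the 6-round 0.07–0.22 atm schedule, 1.5-h
traces sampled every 30 s. Free parameters were fixed once: α = 0.25 atm
places the median critical pressure of a fully saturated population at the
top of the pressure window; σ_cell = 0.2 keeps within-component dispersion
modest, because population heterogeneity is carried by the two-component
mixture; weak_floor = 0.3 reproduces a weak fraction of ≈1/3 at full PPR;
λ_sat = 300 pm, r = 0.002 s⁻¹ and 5 pm noise give plateaus and
signal-to-noise typical of cell-adhesion biosensor wells. All randomness
derives from one seed; identical configurations are bit-identical.

### What the simulator does and does not capture

It reproduces the qualitative signatures of the real assays: detachment
curves shifting right with Q, right-skewed histograms that widen with
density, a weak fraction that decays with Q yet persists near 1/3 at full
PPR, and saturating plateau profiles. It does **not** model hydrodynamics
of the aspiration flow, bond-rupture force kinetics, cell spreading, well
drift, or biological correlations between adhesion and position. At the
lowest densities the simulated weak fraction reaches ~100% rather than the
~80% a real population shows, a consequence of choosing a small σ_cell
(see below). Passing recovery tests therefore demonstrate correctness of
the analysis chain under its own model assumptions, not instrument-level
realism.

### A structural limit of the detachment chain

W is confined to [p₁/2, p_N + step/2] = [0.035, 0.235] atm — a 6.7× dynamic
range — while the saturation s across the default Q grid spans a 13.5×
range. No choice of α or σ_cell can make W proportional to s: the first-bin
floor acts as an additive offset that the offset-free KMAL model must
absorb, biasing the fitted K_d^2D low by roughly 30% even in the
large-sample limit (and more for wide σ_cell, which smears additional mass
into the floor and ceiling bins). The Monte-Carlo recovery tests document
this: across 20 simulated experiments the median recovered constant sits
near 3.2–3.4 × 10³ µm⁻² for a 4.5 × 10³ µm⁻² truth — inside a ±40% band
but systematically below it, with the truth outside the spread of the
estimator. The biosensor chain has no binning and recovers its generating
constant without bias. Practically: detachment-derived K_d^2D values should
be read as lower-bound-flavored estimates whose resolution is set by the
pressure schedule, which is one plausible contributor to the ~2×
difference between the constants the two assays report.

## Problem sizes and numerics

Monte-Carlo checks use 20 simulated experiments per chain (8 conditions ×
3 × 110 cells, or 24 wells × 181 samples), enough for stable medians while
keeping the full suite interactive. Fits use scipy's trust-region
reflective least squares with lower bounds at 10⁻¹²; histogram mass
conservation is enforced to 10⁻⁹ with negative round-off clipped at 10⁻¹²;
curve monotonicity tolerates 10⁻¹² of round-off. Degenerate inputs
(constant traces, flat saturation data, zero initial counts, empty files)
raise typed validation errors rather than returning quiet garbage.
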