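# Methods

## Measurement model

One Monte Carlo iteration simulates one complete TG-51 calibration session.
For a dependent quantity `Q(x_1, …, x_n)` the i-th iteration evaluates
`Q_i = Q(x_1 + Δx_1,i, …, x_n + Δx_n,i)` with every `Δx_j,i` drawn from that
source's declared law.  Two laws are supported:

* **normal**, untruncated, for Type A scatter and calibration-certificate
  uncertainties;
* **bounded uniform**, for manufacturer-stated accuracies and tolerance-type
  limits, with `σ = half-width/√3` and draws hard-limited to the bounds.

The simulated dose samples are normalized by the all-nominal dose, so the
output is a distribution of relative dose; its k=1 relative standard
deviation is the standard uncertainty and the "95 % CI" is reported as the
k=2 expanded interval `2σ` (the 1.96 σ value and the empirical 2.5–97.5
percentile half-width are reported alongside; for these nearly normal
distributions they agree to ~2 %).

Each uncertainty source draws from its own labelled sub-stream of the run
seed (`SeedSequence` keyed on a hash of the source name), so zeroing or
re-scaling one source never perturbs another source's draws.  This makes
contribution tables and sensitivity sweeps seed-stable and the whole run
bit-reproducible for a given seed.

## Photon chain

1. **Scan** — the %dd(10) scan error is the linearised expansion of
   `dd(d) ≈ ((SSD+d_m)/(SSD+d))² S_p TMR`: coefficients −0.032 / 0.0015 /
   0.010 cm⁻¹ for depth / SSD / field size at 6 MV (a surface-setting error
   shifts d and d_m together).  Propagating the default uniform ±1 mm depth,
   ±2 mm SSD and ±2 mm field errors gives σ(%dd(10)) ≈ 0.22 %.
2. **Beam quality** — below 10 MV, %dd(10)x = %dd(10); above, the interim
   formula `1.267·%dd(10) − 20` is used with its own uniform ±2 %-point
   accuracy source.  `k_Q = A + B·10⁻³·ddx + C·10⁻⁵·ddx²` (PTW N30013:
   A = 0.9652, B = 2.141, C = −2.623) plus intrinsic (normal 0.4 %;
   0.45 % in the 18 MV scenario) and fit-rms (normal 0.07 %) relative
   perturbations.  Samples leaving the fit's 63–86 validity window are
   flagged and kept — discarding them would bias the tails.
3. **Environment** — `P_TP = (p_ref/p)·(273.2+T)/295.2`, reference pressure
   in the caller's declared unit (760 mmHg ≡ 1013.25 mbar).  Temperature
   composes a normal Type A (0.25 °C) and uniform Type B (0.23 °C) term;
   pressure is uniform ±8 mbar (worst-case digital barometer).  Together:
   σ(P_TP) ≈ 0.48 %.
4. **Readings** — the correlated part of the raw-reading error (setup depth
   / SSD / field via the measurement coefficients, chamber-calibration
   stability, extracameral current) is shared by all readings of the
   iteration; each reading (M_raw ≡ M_H ≡ M⁻, the opposite-polarity M⁺,
   and the low-voltage M_L) adds an independent repeatability draw
   (normal 0.04 %).  M_L is constructed so that the nominal two-voltage
   formula returns the configured nominal P_ion.  Because the user measures
   M_raw once and reuses it inside P_pol and P_ion, a repeatability
   fluctuation propagates along three correlated pathways; this is why the
   repeatability row of the budget table contributes ≈0.075 % although the
   assigned σ is 0.04 %.
5. **P_ion** — `P = −1/(M_H/M_L − 2)` at voltage ratio exactly 2, plus a
   formula-accuracy term.  The formula term is modelled as normal with
   σ = 0.2 % of P_ion, and the result is clamped at its physical bound:
   values below 1.000 are set to exactly 1.000 (a point mass whose weight
   matches the pre-clamp tail probability), values above the protocol limit
   1.05 are counted but kept.  With nominal P_ion = 1.003 the clamp engages
   for ≈7 % of iterations and σ(P_ion) ≈ 0.19 %.
6. **Dose** — `D_i ∝ M_raw·P_ion·P_TP·P_elec·P_pol·k_Q·N_D,w·(1+Δ_hum)`
   with N_D,w normal 0.75 %, P_elec normal 0.1 % and humidity uniform
   ±0.15 %.  Leakage is assumed perfectly subtracted by the electrometer;
   off-axis and gantry-angle effects are neglected for flattened beams
   (OAR and S_c treated as exactly 1).

## Electron chain

1. `I50_i = I50 + ΔI50` (uniform, σ 0.087 cm);
   `R50_i = 1.029·I50_i − 0.06 + ΔR50` (uniform ±0.04 cm formula accuracy);
   the reference-depth displacement is `0.6·(R50_nom − R50_i) + Δd_set`
   (uniform ±1 mm depth setting) — an overestimated R50 leaves the chamber
   effectively shallow.
2. The charge is measured once, at `d_ref + 0.5 r_cav`; the ratio defining
   P_gr cancels exactly, so P_gr is never sampled (P_ion and P_pol are
   assumed equal at the two depths).  Depth errors convert to reading
   errors through the local relative DI gradient, obtained by fitting a
   cubic to the shifted DI curve around the measurement depth; SSD errors
   enter as −0.02 per cm from the virtual-source inverse square.
3. `k'R50 = 0.9905 + 0.071·exp(−R50/3.67)` (cylindrical chambers,
   2 ≤ R50 ≤ 9 cm) times a uniform ±0.2 % formula term; `k_ecal` carries a
   normal 0.5 % relative uncertainty (its nominal value, 0.897 by default,
   cancels in the normalized dose).  The shared R50 draw feeds both the
   displacement and k'R50; the two pathways partially cancel, which the
   simulation preserves and a dedicated test asserts.
4. Environment, readings, P_pol, P_ion, N_D,w, P_elec and humidity are
   handled exactly as for photons (chamber-stability σ is 0.3 % for the
   electron budget vs 0.4 % for photons, following the respective budget
   tables).

## Synthetic beams

The package is self-contained: scanned curves are emulated, not shipped.

* **Photon PDD** — inverse square × `exp(−μΔd − νΔd²)` beyond d_m, with
  (μ, ν) solved so %dd(10) and the −0.032 cm⁻¹ depth coefficient are hit
  simultaneously; a smooth parabolic buildup below d_m.  Fitting the
  generated curve recovers the pinned coefficients within 5 %.
* **Electron DI** — a Gaussian falloff with (d_max, width) solved so that
  the depth of 50 % ionization equals the nominal I50 and the relative
  gradient at the measurement depth equals ≈0.8 %/mm for the 6 MeV-like
  beam and roughly half that for 18 MeV-like.

These emulate the features the uncertainty chain actually consumes (local
gradient, %dd(10), I50).  They do **not** model buildup-region realism,
bremsstrahlung tails, scan noise, or energy spectra — so passing tests
validate the propagation machinery under the stated sensitivities, not any
particular linac's beam data.  Real scans can be supplied as
`depth_cm,value` CSV files via `read_curve_csv` /
`PhotonBeamGeometry.from_curve` / `ElectronBeamGeometry(di_curve=...)`.

## Reference scenarios and defaults

| scenario | key nominals |
|---|---|
| 6MV  | %dd(10)x = 67.74, interim formula inactive |
| 18MV | %dd(10) = 78.02 → %dd(10)x = 78.85 via interim formula (±2 % source active), k_Q intrinsic σ 0.45 %, 6 MV sensitivity coefficients reused (18 MV values are not pinned anywhere; a documented approximation) |
| 6MeV | I50 = 2.40 cm → d_ref = 1.346 cm, DI gradient −0.08 cm⁻¹ |
| 18MeV| I50 = 7.50 cm, DI gradient −0.042 cm⁻¹ |

Nominal I50 values and the nominal P_ion = 1.003 are the package's own
choices of typical clinical values (configurable); the total uncertainty is
insensitive to the exact P_ion nominal except through the clamp fraction.
Session conditions default to T = 20.7 °C, p = 990.1 mbar.

## Numerical choices

* Uniform draws use `rng.uniform(center−a, center+a)`; the truncation
  invariant |draw − center| ≤ a is exact.
* The P_ion formula-term distribution is normal σ 0.2 % with the 1.000
  clamp.  The two printed descriptions of this term disagree (a uniform
  ±0.2 % accuracy band vs a normal 0.2 % clamped row); the normal + clamp
  model is adopted because it reproduces both the published per-row
  contribution (0.18 %) and σ(P_ion) ≈ 0.2 %, and the distribution remains
  configurable through the budget document.
* Cubic gradient fits use a ±0.75 cm window (≥4 points required); on an
  exactly cubic curve the analytic derivative is recovered to 1e-6.
* Contribution tables group Type A + Type B temperature into one row and
  use the same per-source streams as the full run, so the decomposition's
  quadrature total matches the full-run σ to a few 0.001 pp in the
  near-linear regime.
* Degenerate inputs: zero-width sources return their center exactly; an
  all-zero budget yields every sample ≡ 1.

## Known limitations

* Only random (Type A/B-style) uncertainties are simulated; systematic
  choices such as the 0.38·r_cav vs 0.5·r_cav effective-point shift
  (≈0.2 % at 6 MeV) or a 1.2 mm vs 1.8 mm photon scan shift are documented
  but not sampled.
* The electron R50-formula row of the published budget (0.27 %) exceeds
  what first-order propagation of its stated σ (0.023 cm) through the
  implemented pathways produces (≈0.09 %); the pipeline reports its
  computed value rather than tuning to the printed one.
* Flattened beams only: FFF lateral-gradient effects, lead-foil %dd(10)_Pb
  measurements, plane-parallel chamber cross-calibrations and other
  protocols (TRS-398, DIN 6800-2) are out of scope.
* Default problem size is 10⁶ iterations (σ estimate stable to ~0.001 pp);
  tests use 10⁵–10⁶ depending on the tolerance being checked.
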