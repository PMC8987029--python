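# Methods

## Scope and model

`metalswitch` implements the computational side of engineering reversible,
metal-gated activity switches into conformationally dynamic enzymes.  Two
chelating side chains (bipyridinylalanine, BpyAla) placed on opposite domains
can be cross-linked by a divalent metal ion into a bis-bidentate M(BpyAla)₂
complex; if the two Cβ anchor points sit at the complex-compatible spacing
only in one conformational state, metal binding traps that state and switches
catalysis off, while chelator addition (EDTA) reverses the linkage.  The
package makes no attempt to model the chemistry itself — coordination
geometry enters only as a distance constant — and treats the conformational
states as given structures (crystal forms or MD snapshot ensembles converted
to multi-model PDB).

## Site selection

**Reference points.**  Each residue is represented by its Cβ atom.  Glycines
(and residues whose CB record is missing) get an ideal-geometry virtual Cβ
reconstructed from N/CA/C (1.52 Å bond, tetrahedral angles); if backbone
atoms are missing too, the Cα is used, and residues with neither Cα nor Cβ
are dropped with a warning.  Author (PDB) residue numbering is preserved
verbatim; insertion codes are rejected; altloc conformers resolve to the
highest occupancy, ties to the first encountered.

**Predicates.**  A pair (i, j) is a candidate iff

1. closed-state mean Cβ–Cβ distance ∈ [center − halfwidth, center + halfwidth].
   The default window is 10.5 ± 0.5 Å (the spacing measured between the C-5
   substituents of a Zn(Bpy)₂ crystal structure); the screening preset widens
   it to ±1.0 Å, i.e. 9.5–11.5 Å.
2. both residues have relative SASA ≥ 0.20 in the closed state (the state in
   which the complex must form; optionally required in both states).
3. |d_open − d_closed| ≥ 2.0 Å (default).  The source workflow ranks by
   Δ-distance but publishes no cutoff; a minimum change is needed to make
   "cross-link impossible in the other state" operational, and 2 Å is small
   against the ~0.3 Å coordinate noise of typical structures while excluding
   conformationally silent pairs.  Both |Δ| and the signed value are
   reported.
4. the residues lie on different (user-defined) domains.

Candidates are sorted by descending Δ-distance, ties broken lexicographically
on (chain, residue number), and ranked 1..k.  With multi-frame states,
distances and exposures are frame means, emulating MD-averaged screening;
with single representatives the same code path reduces to a plain two-
structure comparison (which of the two the original screen used is not
documented; both are supported).

**SASA.**  Shrake–Rupley with a Fibonacci-lattice point set (default 960
points, probe 1.4 Å, Bondi-type vdW radii; heavy atoms only).  Per-atom
accessible area is 4π(r+probe)² times the accessible point fraction;
residue SASA is the atom sum; relative SASA divides by the residue's
Gly-X-Gly tripeptide maximum (Tien et al. theoretical scale).  The isolated
sphere is exact by construction, and a two-sphere configuration agrees with
the analytic spherical-cap area within 2% at 960 points.  The exposure
metric and 0.20 cutoff are package choices (the source workflow does not
state either); both are configurable.

## Plate screening

Raw kinetics come as a `time_s` × wells CSV plus a descriptor CSV
(`well, variant, metal, conc_uM, edta, replicate, blank`).  Each well's rate
is the **maximum OLS slope over a sliding window of five timepoints**,
regressed on the actual time values (robust to uneven sampling; whether the
original script used times or indices is unstated).  Non-finite points and
points at/above a saturation ceiling (default 3.5 AU) are dropped first;
slope ties resolve to the earliest window, so on concave traces the statistic
is the classic initial rate.  Slopes are stored per second and reported per
minute.  Replicates aggregate to mean ± sample SD (n−1).

Classification per variant × metal, on replicate-mean rates:

* *inactive* if the apo (0 metal) rate is below an activity floor,
* else *inhibited* if rate(highest conc)/rate(apo) < 0.5,
* *activated* if the ratio > 1.5,
* *unresponsive* otherwise.

The 0.5/1.5 thresholds are fixed (they encode "less than 50% apo activity"
and ">50% increase").  The floor is deliberately a parameter, defaulting to
5% of a wild-type reference rate: "displayed activity" is a qualitative call,
and the right floor depends on the noise level of the max-slope statistic.
For a window of w points at spacing Δt, the per-window slope SD is
σ_noise/(Δt·√(w(w²−1)/12)); relative to a true rate spanning the full read,
this is (σ_noise/range)·(n−1)/√10 for w = 5 — so with noise at 5% of the
signal range and n = 9 timepoints the slope noise floor is ~13% of the true
rate per well, and taking the max over windows biases near-zero wells
upward by a further ~1σ.  Under those conditions a 5% floor is below the
noise floor and a floor of ~30% of the reference separates truly silent
variants cleanly; the noisy-screen tests use exactly that setting, chosen
from this analysis.

Reversibility: recovery = (rate_afterEDTA − rate_metal)/(rate_apo −
rate_metal), 1 for complete reversal, 0 for none (the Fe(II)-like case);
undefined-with-flag when the metal rate is within 5% of apo (non-responder).

## Saturation kinetics

Absorbance slopes convert to µM/s via slope/(ε·ℓ), ε₄₁₀ = 7,126 M⁻¹cm⁻¹
(p-nitroaniline), path length in cm.

Michaelis–Menten (v = V·S/(K_M+S)) and the canonical uncompetitive
substrate-inhibition law (v = V·S/(K_M + S(1+S/K_i))) are fitted by bounded
nonlinear least squares (`scipy.optimize.curve_fit`, xtol/ftol/gtol 1e-14)
with data-driven initialization (V₀ = max rate, K_M,0 interpolated at
half-max, K_i,0 = max S) and five seeded log-normal multi-starts to avoid
local minima.  The SI form was chosen because the source analysis names only
"a Michaelis–Menten equation that accounts for inhibition at increasing
substrate concentrations": the uncompetitive law is the field's default, it
nests MM (K_i → ∞) and its optimum S* = √(K_M·K_i) gives a closed-form test
point.  Standard errors come from the Jacobian covariance; k_cat = V/[E]
when the enzyme concentration is known.  K_M is flagged indeterminate when
the estimate exceeds 10× the highest tested concentration or its 95% CI
spans more than two orders of magnitude — the "NA" situation of a variant
whose saturating substrate concentration is unreachable.  SI-vs-MM model
choice uses corrected AIC, ties to the simpler model.

Switching series normalize rates so the maximum relative rate is 1, then
report mean(on)/mean(off) as the dynamic range (arithmetic means; a
geometric-mean option exists) and the OLS slope of on-round rates versus
round index as a degradation check.  All 24 rounds enter the means (whether
the original figure excluded a first cycle is unstated).

## Synthetic data

The generators define the study conditions for every test; all are seeded
`numpy.random.Generator` code paths and bit-reproducible.

* **Hinge toy**: two rigid pseudo-domains (poly-alanine with explicit CB, so
  no virtual-Cβ logic is exercised unless asked for) of ~100 residues each,
  Cβ points placed ≥4 Å apart in 18×22×22 Å boxes, full residues attached
  with per-residue random orientations.  The open state rotates domain B
  about a hinge axis 20 Å below the interface (default 20°), which moves
  every B residue away from domain A by several Å with a natural spread of
  Δ-distances.  Planted pairs are constructed at their target closed-state
  distance (validated to 0.1 Å on the noise-free geometry, with an error if
  the hinge would shrink them); optional per-frame coordinate jitter stands
  in for MD fluctuation.  A ground-truth table of all pair distances
  (computed from the written, 3-decimal-rounded coordinates) accompanies
  every structure.
* **Plates**: rates follow apo_rate × response(conc) with Hill-form
  occupancy θ = c^h/(EC50^h+c^h) (h = 2, motivated by the 2:1 Bpy:metal
  stoichiometry — a fixture choice, not a fitted binding model);
  response = 1 − θ(1−residual) for inhibited (residual 5%), 1 + θ for
  activated, 1 for unresponsive, 0 for inactive.  Defaults: 0–100 µM metal
  grid, EC50 1 µM, triplicates, apo rate 0.02 AU/min on a 0.05 AU baseline,
  nine timepoints 900 s apart (a two-hour read), 0.005 AU read noise.
  EDTA wells revert to apo when the variant is reversible.  Signals are
  strictly linear in time: the simulator does not model substrate depletion,
  lag phases, or well-position effects, so passing tests demonstrate the
  analysis logic, not robustness to those real-plate artifacts.
* **Saturation/switching**: direct evaluation of the chosen rate law (plus
  Gaussian noise and replicate averaging) and alternating on/off rounds with
  optional multiplicative drift.

## Problem sizes and numerical choices

Tests run the pair-selection oracle on twenty ~200-residue hinge toys
against exhaustive C(n,2) enumeration, the noisy screening recovery on 50
seeded 28-variant plates, and the fit-recovery properties on 100 seeded
simulations each; these sizes give stable statistics while keeping the whole
suite around a minute.  Noiseless round trips assert 1e-6 (MM) / 1e-4 (SI)
relative recovery; the SASA two-sphere check allows 2% at 960 points; exact
arithmetic identities (distance matrices, dynamic range 20 on the synthetic
alternating series) assert to float precision.

## Known limitations

* No mmCIF or trajectory formats; frames must arrive as multi-model PDB.
* Exposure and Δ-distance cutoffs are package conventions, not published
  values; published pair lists from MD-based screens are not reproducible
  without the underlying trajectories.
* The SI functional form is an assumption; other inhibition-aware laws
  (e.g. product inhibition) are not fitted.
* The dose-response classifier assumes a monotone response to the metal
  series and judges only the endpoints (apo and highest concentration).
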