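# metalswitch

Tools for engineering **metal-responsive conformational switches** into
enzymes, and for analyzing the high-throughput kinetics used to screen them.

The idea: genetically encode a pair of metal-chelating bipyridinylalanine
(BpyAla) residues so that a divalent metal ion (Ni²⁺, Cu²⁺, Co²⁺, Zn²⁺ …)
cross-links them as a bis-bidentate M(BpyAla)₂ complex, trapping one
conformational state of the enzyme — e.g. the closed form of a two-domain
hinged protease — and switching activity off.  A competing chelator (EDTA)
strips the metal and switches activity back on.  `metalswitch` covers the
computational half of that workflow:

* **Site selection** — given open- and closed-state structures (single
  representatives or multi-model frame ensembles), rank residue pairs that
  (i) sit at the M(Bpy)₂-compatible Cβ–Cβ spacing in the closed state
  (10.5 ± 0.5 Å geometric constraint; 9.5–11.5 Å screening window),
  (ii) are solvent exposed (Shrake–Rupley relative SASA), (iii) change
  Cβ–Cβ distance between states (ranked by Δ-distance) and (iv) span the
  two domains.
* **Plate screening** — rebuild kinetic traces from a raw time × wells CSV
  plus a well-descriptor CSV, extract each well's rate as the maximum
  ordinary-least-squares slope over a sliding window of five timepoints,
  average replicates, and classify each variant × metal dose series as
  *inhibited* (<50% of apo activity at the highest metal concentration),
  *activated* (>50% increase), *unresponsive* or *inactive*, plus
  EDTA-rescue reversibility (fractional recovery of apo activity).
* **Kinetic fitting** — convert absorbance slopes to rates
  (ε₄₁₀ = 7,126 M⁻¹cm⁻¹ for p-nitroaniline), fit v = V·S/(K_M+S)
  (Michaelis–Menten) and the uncompetitive substrate-inhibition form
  v = V·S/(K_M + S(1+S/K_i)) with multi-start nonlinear least squares and
  AICc model comparison, and compute on/off switching dynamic ranges.
* **Simulation** — seeded generators for hinge-motion toy structures with
  planted candidate pairs, screening plates with planted phenotypes,
  saturation curves and switching series; every downstream test is driven
  by these.

The fitters are scikit-learn-compatible regressors
(`MichaelisMentenRegressor`, `SubstrateInhibitionRegressor`); everything
else is plain functions plus a `metalswitch` command-line tool
(`design`, `rates`, `classify`, `reversibility`, `fit`, `switch`,
`simulate`).

## Worked example

```python
import numpy as np
from metalswitch import *

# 1) pick linker-group sites on a synthetic two-domain hinge protein
spec = HingeToySpec(residues_per_domain=40,
                    planted_pairs=[(1, 1, 10.5), (2, 2, 10.2)], seed=11)
toy = make_hinge_toy(spec, "scratch/hinge")
ens = load_two_state(toy.closed_path, toy.open_path)
domains = [DomainDefinition("propeller", [("A", 1, 40)]),
           DomainDefinition("peptidase", [("B", 1, 40)])]
pairs = select_pairs(ens, domains, DesignConfig.paper_window())
print(f"{len(pairs)} candidate pairs; top 3 by distance change:")
for p in pairs[:3]:
    print(f"  rank {p.rank}: {p.site_i.label}-{p.site_j.label}  "
          f"closed {p.d_closed:.2f} A, open {p.d_open:.2f} A, delta {p.delta_distance:.2f} A")

# 2) refit a noiseless Michaelis-Menten curve (KM 335 uM, kcat 172 /s, 20 nM enzyme)
grid = np.array([15.625, 31.25, 62.5, 125, 250, 375, 500, 1000.0])
series = simulate_saturation(MMParams(K_M=335.0, V_max=172 * 0.02,
                                      K_M_se=0, V_max_se=0), grid)
fit = fit_michaelis_menten(series, enzyme_conc_nM=20.0)
print(f"Michaelis-Menten fit: KM = {fit.K_M:.0f} uM, kcat = {fit.k_cat:.0f} /s")

# 3) dynamic range of 24 alternating metal/EDTA activity rounds
sw = switching_dynamic_range(simulate_switching(n_rounds=24, on_rate=1.0, off_rate=0.05))
print(f"switching: dynamic range {sw.dynamic_range:.1f}-fold, "
      f"trend slope {sw.trend_slope:.1e} per round")
```

prints

```
24 candidate pairs; top 3 by distance change:
  rank 1: A:8-B:32  closed 10.35 A, open 20.26 A, delta 9.91 A
  rank 2: A:3-B:3  closed 9.95 A, open 19.16 A, delta 9.21 A
  rank 3: A:36-B:3  closed 10.42 A, open 19.37 A, delta 8.95 A
Michaelis-Menten fit: KM = 335 uM, kcat = 172 /s
switching: dynamic range 20.0-fold, trend slope -7.7e-18 per round
```

The 24 ranked pairs all satisfy the four selection predicates (the planted
pairs among them); the noiseless saturation curve returns exactly the
parameters it was generated from, confirming the fitter is unbiased; and the
alternating series with full on-activity and 5% residual off-activity gives a
20-fold dynamic range with no degradation trend across cycles.

The same steps are available from the shell, e.g.

```bash
metalswitch simulate plate --include-edta --outdir out/plate
metalswitch classify --raw out/plate/plate_raw.csv \
    --descriptor out/plate/plate_descriptor.csv --outdir out/classify
```

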