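# emulsiphase

Where does a water-soluble antioxidant sit in an oil-in-water nanoemulsion,
and does that placement make it effective?  `emulsiphase` answers this for
the canonical case of gallic acid in a polysorbate-80-stabilized olive-oil
nanoemulsion, combining three desk-scale analyses behind one API:

1. **Pseudophase partitioning** (`emulsion_model`).  The emulsion is treated
   as three notional phases — oil (Φ_O), interfacial (Φ_I) and aqueous (Φ_W),
   with Φ_O + Φ_I + Φ_W = 1.  An oil-insoluble antioxidant distributes
   between water and interface according to a single partition constant

   P_W^I = (AO_I) / (AO_W),

   where parentheses denote effective concentrations (moles per litre of
   *that region's* volume).  The observed rate constant of a chemical probe
   reaction measured at several surfactant volume fractions obeys

   k_obs = [AO_T] · k_I · P_W^I / (Φ_I · P_W^I + Φ_W),

   which is fitted (nonlinearly, or linearly on 1/k_obs) to estimate P_W^I
   and k_I.  From P_W^I follow the interfacial percentage
   %AO_I = 100·Φ_I·P / (Φ_W + Φ_I·P) and the effective interfacial
   concentration (AO_I) = [AO_T]·(%AO_I/100)/Φ_I.

2. **Droplet geometry** (`trajectory_analysis` + `synthetic_data`).  A
   seeded generator builds spherical droplet configurations — dense oleic
   core, surfactant shell represented by its three reference sites
   (sorbitan ring / ethylene-oxide hydroxyl termini / oleate tail), bulk
   water, and rigid gallic-acid placements with prescribed radial and
   orientation laws.  The analysis layer recovers radial probability
   profiles, core/interface/water boundaries, per-region occupancy,
   per-oxygen insertion depths, and the α/β/γ orientation angles between
   the radial vector and the molecule's para axis, COM→C6 vector and
   aromatic plane.

3. **Oxidative stability** (`oxidation_kinetics`).  Conjugated-diene
   accumulation curves (simulated from a mass-action
   initiation/propagation/termination/inhibition scheme, or read from CSV)
   are reduced to an induction time τ_IND by least-squares two-line
   intersection, and antioxidant efficacy is the ratio
   τ_IND(antioxidant)/τ_IND(control).

## Worked example

```python
import numpy as np
from emulsiphase import (EmulsionComposition, distribution, fit_partition,
                         generate_kobs_series, percent_interfacial)

# a 1:9 (v/v) oil-in-water formulation, bracketing surfactant levels
for phi_i in (0.005, 0.04):
    comp = EmulsionComposition.from_phi(0.10, phi_i)
    pct = percent_interfacial(93.0, comp)
    conc = distribution(93.0, 1e-4, comp).effective_conc_interfacial
    print(f"phi_I={phi_i:<6} %interfacial={pct:5.1f}  (AO_I)={conc:.2e} M")

# recover the partition constant from a noiseless synthetic series
series = generate_kobs_series(93.0, 100.0, 1e-4, 0.10,
                              np.linspace(0.005, 0.04, 8), noise_cv=0.0)
print("fitted P_W^I =", round(fit_partition(series).p_wi, 3))
```

prints

```
phi_I=0.005  %interfacial= 34.2  (AO_I)=6.84e-03 M
phi_I=0.04   %interfacial= 81.2  (AO_I)=2.03e-03 M
fitted P_W^I = 93.0
```

Reading: at the lowest surfactant loading only a third of the antioxidant
is interfacial, but its local concentration there is ~70-fold the
stoichiometric 1e-4 M; raising Φ_I to 0.04 pulls 81% of it into the
interface while diluting the local concentration 3.4-fold — the classic
dilution trade-off of surfactant-rich formulations.

A complete pipeline run (generate → analyze → fit → extract τ_IND, with a
checksummed manifest) is a one-liner:

```sh
emulsiphase run --seed 1 --out results/demo
```

See `emulsiphase --help` for the individual `synth`, `analyze`,
`fit-partition`, `distribution-table`, `induction-time` and `effectiveness`
commands.

## Documentation

`docs/methods.md` describes the model equations, the generator's design and
its deliberate simplifications, numerical conventions (binning, boundary
thresholds, tie-breaks) and known limitations.
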