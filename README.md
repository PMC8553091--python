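# lamelliflow

Filament-level Brownian dynamics of a lamellipodial actin network
undergoing retrograde flow past a focal adhesion.

The lamellipodium — the thin, sheet-like actin network at a crawling
cell's leading edge — flows rearward ("retrograde flow") as
polymerization pushes against the membrane and molecular motors pull the
network inward. Focal adhesions act as a *molecular clutch*: where the
network engages an adhesion, friction brakes the flow and polymerization
is converted into protrusion instead. `lamelliflow` models a 2 µm
periodic strip of this system at the level of individual actin
filaments: bead–spring chains (segment length l₀ = 0.1 µm ≙ 37 monomers)
with bending rigidity κ = k_BT·l_p (l_p = 17 µm), permanent and dynamic
crosslinkers, excluded volume, constant pushing at the leading edge
(1.5 pN per filament), motor pulling (uniform, rear-biased, or
membrane-bound), and a capsule-shaped adhesion zone where beads bind and
unbind and feel a drag elevated by the viscosity ratio κ_FA. Each bead
evolves by overdamped Langevin dynamics,

    ζᵢ dr_i/dt = F^spring + F^bend + F^crosslink + F^excluded
                 + F^leading + F^motor + F^thermal ,

integrated with explicit Euler–Maruyama steps of 10⁻⁵ s. The network
remodels continuously: filaments are inserted near the leading edge at a
fixed rate, crosslinks form and decay, and aged bonds sever. Scenario
drivers reproduce clutch-strength sweeps, cytochalasin-D inhibition,
transverse-arc and microspike formation, Arp2/3-style branching, and a
clamp-and-strain rig that measures the network's elastic moduli from the
virial stress. The model and its parameter values are described in
`docs/methods.md`.

Intended users: cytoskeletal biophysicists and modelers who want a
transparent, scriptable filament-scale clutch model rather than a
continuum approximation.

## Worked example

A scaled-down clutch sweep (short filament lifetimes; see the methods
note for what the desk preset does and does not preserve):

```python
from lamelliflow.protocols import desk_config, run_steady_state

cfg = desk_config(seed=3, kappa_list=(1.0, 500.0))
for kappa in cfg.kappa_list:
    res = run_steady_state(cfg, kappa)
    print(f"kappa_FA={kappa:5g}  mean retrograde speed "
          f"{res.mean_speed * 1e3:6.1f} nm/s   "
          f"({res.state.n_beads} beads)")
```

Output (a few minutes on one core):

```
kappa_FA=    1  mean retrograde speed  213.9 nm/s   (1896 beads)
kappa_FA=  500  mean retrograde speed   60.7 nm/s   (1893 beads)
```

Raising the adhesion/cytoplasm viscosity ratio κ_FA from 1 (no adhesion)
to 500 brakes the flow between three- and fourfold — the clutch
engaging. At the reference scale (130 s filament lifetimes, ~10 µm
lamellipodium) the same sweep runs at ~50 down to ~15 nm/s, but that is
a cluster-scale computation.

The command line exposes the same drivers:

```bash
lamelliflow print-defaults                # reference parameter set
lamelliflow run config.toml --out out/   # scenario from a TOML config
lamelliflow mechtest --mode extension    # clamp-and-strain on a patch
```

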