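# rigiperc

Rigidity-percolation analysis of cell-contact networks in early embryonic
tissue.

During zebrafish blastoderm spreading the tissue's viscosity drops by more
than an order of magnitude within minutes and then slowly recovers. This
package implements the structural explanation: the tissue's cell-contact
network undergoes a **rigidity percolation transition**. Treating cells as
nodes and adhesive contacts as bonds of a diluted 2D triangular lattice,
the network is rigid — and the tissue viscous/solid-like — only while a
giant rigid cluster percolates; when the mean connectivity ⟨C⟩ drops below
a critical fraction of its maximum (⟨k⟩c = 2/3 in the infinite-size limit,
≈ 0.68–0.72 at experimental sizes), the giant cluster collapses and the
tissue fluidizes at essentially unchanged cell density.

It is written for quantitative biologists and biophysicists who have
cell-contact maps (node coordinates plus an undirected contact list) or
tissue-rheology recordings and want the topological, statistical and
mechanical readouts of the transition.

## What is inside

| module | contents |
| --- | --- |
| `rigiperc.lattice` | triangular patches with N = L² − ⌊L/2⌋ nodes; random and spatially correlated bond dilution; normalized connectivity ⟨k⟩ = ⟨C⟩/⟨C⟩Max,N with ⟨C⟩Max,N ≈ 6 − 8/√N; JSON/CSV I/O |
| `rigiperc.rigidity` | the (2,3) pebble game for generic 2D rigidity: independent/redundant edges, maximal rigid clusters, giant-cluster fraction gc = S_GC/N, floppy modes F = 2N − 3 − \|independent edges\| |
| `rigiperc.criticality` | ensemble sweeps over ⟨k⟩: gc universal curves, finite-cluster size statistics p(s), variance-peak and gc-crossing critical points, discrete power-law MLE, Jensen–Shannon fitting of the bond-loss correlation strength λ |
| `rigiperc.mechanics` | overdamped spring networks under shear: elastic transmitted force F₀, bond-turnover viscosity η ≈ F₀/v with η ∝ τK above the transition |
| `rigiperc.adhesion` | surface-tension contact model: α = γ_cc/(2γ_cf) = cos(θe/2); the 4-cell rhombus whose contact topology rigidifies at α* ≈ 0.87 |
| `rigiperc.tissue_metrics` | contact-map connectivity, cell fraction, MSRD, shape index, division-heterogeneity SHC with binomial null, micropipette-aspiration viscosity η = R_p ΔP / (3π(L̇asp + L̇ret)) |
| `rigiperc.synthetic_data` | seeded generators for contact-map cohorts (wild-type-like and correlated Chk1-like), aspiration traces, and division maps, all carrying ground truth |
| `rigiperc.cli` | `rigiperc {lattice,rigidity,crit,mech,adh,metrics,synth,pipeline}` |

## Worked example

```python
import numpy as np
from rigiperc import lattice as lt, rigidity as rg, criticality as cr, adhesion as adh

full = lt.build_full_lattice(10)           # N = 95 cells, like one field of view
for k in (0.80, 0.60):
    dil = lt.dilute_random(full, k * full.mean_connectivity, seed=42)
    dec = rg.rigid_clusters(dil)
    rep = lt.connectivity_report(dil)
    print(f"k = {k:.2f}: <C> = {rep.mean_connectivity:.2f}, "
          f"gc = {dec.gc_fraction:.2f}, floppy modes = {dec.floppy_modes}")

ens = cr.sweep_ensemble([95], np.linspace(0.55, 0.90, 36), replicas=300, seed=0)
print(f"variance-peak k_c (N = 95): "
      f"{cr.find_critical_k(ens, 'variance-peak').k_c:.3f}")

alpha_star, _ = adh.rhombus_rigidity_threshold(np.arange(1.0, 0.5, -0.005))
print(f"rhombus rigidity threshold alpha* = {alpha_star:.3f}")
```

prints

```
k = 0.80: <C> = 4.17, gc = 0.82, floppy modes = 3
k = 0.60: <C> = 3.12, gc = 0.12, floppy modes = 39
variance-peak k_c (N = 95): 0.727
rhombus rigidity threshold alpha* = 0.865
```

At 80% bond occupation (⟨C⟩ ≈ 4.2 contacts per cell) the giant rigid
cluster covers 82% of the network — a rigid, viscosity-supporting tissue.
At 60% (⟨C⟩ ≈ 3.1, the fluidization regime) the same patch fragments into
small clusters with 39 zero-energy deformation modes. The variance of the
finite-cluster sizes peaks at ⟨k⟩ ≈ 0.73 for 95-cell networks — the
finite-size critical point, drifting toward 2/3 as N grows. In the
adhesion model, lowering the relative cell-cell tension α past ≈ 0.87
merges neighbouring contacts into tricellular junctions and snaps the
floppy 4-cell rhombus into a rigid 5-contact topology.

The same analyses run from the shell:

```sh
rigiperc lattice build --L 35 --out net.json
rigiperc lattice dilute --in net.json --target-c 3.9 --seed 7 --out dil.json
rigiperc rigidity analyze dil.json --out decomp.json
rigiperc adh threshold --out rhombus.json
```

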