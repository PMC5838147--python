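# sapsa

Tools for two questions that decide whether a cyclic peptide can become an
oral drug:

1. **How much polarity does a conformer ensemble actually expose to
   solvent?**  The package computes the ensemble-averaged
   **solvent-accessible polar surface area (SAPSA)** — the accessible
   (probe-center) surface summed over N, O and their bonded hydrogens,
   averaged over a trajectory of 3D conformers — and classifies expected
   membrane permeability (for cyclic hexapeptides: `< 80 Å²` high,
   `> 150 Å²` low).  Unlike the topological PSA, SAPSA sees intramolecular
   hydrogen bonding and steric shielding of backbone amides by apolar side
   chains.  A truncation tool edits a terminal group (e.g. CH₃ → H,
   Abu → Ala) on a trajectory *in place*, splitting a SAPSA difference into
   a **direct shielding** component and a **conformational** component.
2. **What happens to the absorbed dose in vivo?**  A non-compartmental
   pharmacokinetics module computes AUC, C_max/T_max, λ_z, t½, MRT, CL and
   V_ss from concentration–time profiles (LLOQ-aware), absolute oral
   bioavailability from dose-normalized AUCs, and the **hepatic first-pass
   effect** from paired portal-vein/jugular-vein sampling:
   `first-pass % = 100·(1 − AUC_jugular/AUC_portal)`.

Both halves come with seeded synthetic generators — a torsional
Metropolis conformer sampler plus a two-state shielded/exposed fixture, and
a one-compartment PK simulator with a hepatic extraction ratio — so every
result can be tested against closed forms.  See `docs/methods.md` for the
model details and assumptions.

## Worked example

```python
from sapsa import (classify_permeability, decompose_side_chain_effect,
                   ensemble_sapsa, make_two_state_fixture, TruncationSpec)
from sapsa.conformer_synth import make_decomposition_pair

# Ensemble-averaged SAPSA of a two-state (shielded/exposed) ensemble
ens = make_two_state_fixture(p_exposed=0.7, n_frames=2000, seed=1)
stats = ensemble_sapsa(ens, block_size=500)
print(stats.summary())
print("class:", classify_permeability(stats.mean))
```

```
Ensemble SAPSA
  frames      : 2000
  mean        :    64.58 A^2
  sd (frames) :     8.35 A^2
  block size  : 500
  blocks      : 4  (sd of block means: 0.52 A^2)
class: high
```

The mean sits at the 70/30 mixture of the exposed (≈70 Å²) and shielded
(≈52 Å²) state areas, and 64.6 Å² < 80 Å² classifies as highly permeable.
The frame sd reflects the two-state spread; the block-mean sd is the
trajectory-convergence measure usually drawn as error bars.

```python
# Why does an extra methyl group lower SAPSA? Edit it away on A's own
# trajectory (geometry frozen) and compare with B's own ensemble.
ens_a, ens_b, target = make_decomposition_pair(n_frames=200, seed=2)
report = decompose_side_chain_effect(ens_a, ens_b,
                                     TruncationSpec(target_atom=target),
                                     block_size=50)
print(report.summary())
```

```
Side-chain SAPSA decomposition (A^2)
  mean SAPSA A            :    44.84
  mean SAPSA A, truncated :    45.36
  mean SAPSA B            :    56.14
  direct shielding        :     0.51
  conformational          :    10.79
  total (B - A)           :    11.30
```

The edited trajectory (A, truncated) sits only slightly above A and well
below B: of the 11.3 Å² difference, 0.5 Å² is direct steric shielding by
the methyl and 10.8 Å² comes from its influence on the conformer
distribution — the fixture is built to emulate exactly that regime.

```python
# Hepatic first pass from a portal/jugular AUC pair (nM·h)
from sapsa.pk import first_pass_from_aucs
print(first_pass_from_aucs(449.0, 104.0).summary())
```

```
Hepatic first-pass analysis (oral dose, simultaneous sampling)
==============================================================
  AUC portal vein   :        449
  AUC jugular vein  :        104
  liver first pass  :       76.8 %
  implied hepatic CL 69.2 vs hepatic blood flow 90 mL/min/kg (E_H=0.77, high extraction)
```

77% of the absorbed compound is cleared by the liver before reaching the
systemic circulation — a high-extraction compound (implied hepatic
clearance close to hepatic blood flow).

### Command line

```bash
sapsa compute  --pdb ensemble.pdb --out report.json   # per-frame SAPSA + class
sapsa ensemble --pdb ensemble.pdb --block 1000 --blocks-csv blocks.csv
sapsa truncate --pdb A.pdb --target CG --out A_trunc.pdb
sapsa decompose --a A.pdb --b B.pdb --target CG
sapsa sample   --pdb start.pdb --frames 1000 --seed 1 --torsion 0,4 --out ens.pdb

pk simulate  --eh 0.77 --noise-cv 0.1 --out profiles.csv
pk nca       --csv profiles.csv --out nca.json
pk firstpass --csv profiles.csv --subject sim-1
```

Reports are JSON with a config echo, package version and input checksums;
re-running with identical inputs and seeds is byte-identical.

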