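# opepdock

Coarse-grained rescoring of rigid-body protein–protein docking decoys.

Grid-based docking searches (ZDOCK-style FFT scans) produce thousands of
candidate poses per complex, of which only a handful are near-native.
`opepdock` re-ranks such decoy sets with a continuous, OPEP-style
coarse-grained energy function: each residue is reduced to five backbone
beads (N, H, Cα, C′, O) plus one side-chain bead at the side-chain centre
of mass (glycine: no side-chain bead; proline: one bead per heavy
side-chain atom), decoys are relaxed by a short restrained minimization,
and the binding energy between the two partners is evaluated with a
*softened* scoring function

```
E86 = E_VDW86 + E_SS86 + E_HB + E_SB
```

summed over inter-partner bead pairs only.  The side-chain–side-chain term
E_SS and the backbone 12-6 van der Waals term are replaced by broader 8-6
Lennard-Jones curves

```
E(r) = ε′ [ (σ′/r)^8 − (σ′/r)^6 ],    σ′ = 0.866 σ,   |ε′| = 9.481 |E_SS(σ)|
```

chosen so the softened and unsoftened curves share their minimum position
(σ) and depth, while tolerating the bead overlap typical of decoys produced
with a soft-surface grid search.  Backbone H-bonds (E_HB) and the tabulated
salt-bridge free-energy profiles (E_SB, one minimum for Arg/Asp and
Arg/Glu, two for Lys/Asp and Lys/Glu) are not softened.

On top of scoring, the package implements

* **IRMSD evaluation** — interface = reference residues with any bead
  within 10 Å of the partner; IRMSD = RMSD over interface Cα beads after
  proper-rotation superposition; a *hit* has IRMSD < 4 Å; CAPRI-style
  accuracy tiers (high ≤ 1 Å, medium ≤ 2 Å, acceptable < 4 Å) and
  top-N success-rate curves;
* **contact-potential training** — decoys are classified TP/FN/FP/TN by
  crossing hit status with rank ≤ 20; residue-type pairs more frequent in
  near-native (TP, FN) than misdocked (FP, TN) contact maps are deepened by
  `−k ln(FN_ij/FP_ij)` with k = 0.2, iterated 30 times, with 4-fold
  cross-validation of the iteration count;
* **synthetic benchmarks** — deterministic toy complexes and ZDOCK-regime
  decoy ensembles (fixed receptor, grazing misdocked poses, a controllable
  near-native fraction, plantable residue-pair contact signals), so every
  pipeline stage is testable without external data.

All force-field numbers live in an editable text parameter file
(`src/opepdock/data/default.ff`).  The shipped defaults are documented
stand-in values built from residue size/stickiness scales — not the
original OPEPv5 parameter set, which is not publicly tabulated — and can be
replaced wholesale without touching code.

## Worked example

Score a 200-decoy synthetic ensemble around a small two-chain complex:

```python
import opepdock as od
from opepdock.synthetic import (ToyComplexSpec, DecoyGenSpec,
                                make_toy_complex, generate_rigid_decoys)

config = od.load_default()
soft = od.soften_parameters(config.pair_table, config)

spec = ToyComplexSpec(receptor_seq="ASAHSASSTASA", ligand_seq="SSAHASAS",
                      fold="extended", interface_pairs=((3, 3),), seed=11)
pdb_text, native = make_toy_complex(spec)
decoys = generate_rigid_decoys(
    native, DecoyGenSpec(n_decoys=200, fraction_near_native=0.05, seed=1))

scores = [od.score_e86(decoys.decoy_complex(i), soft, config).total
          for i in range(decoys.n_decoys)]
ranking, best = od.rank_and_best_hit(decoys.decoy_ids, scores, decoys.irmsd)
print(f"hits: {int(ranking.hit.sum())} / {decoys.n_decoys}")
print(f"best-hit rank: {best}")
```

prints

```
hits: 10 / 200
best-hit rank: 61
```

i.e. 10 of the 200 poses are within 4 Å interface RMSD of the native, and
the best of them ranks 61st under the untrained E86 — the situation the
iterative trainer is designed to improve.  Training on a 20-target
benchmark with an enriched His/His interface contact
(`opepdock.synthetic.make_recovery_benchmark` +
`opepdock.training.train`) deepens that pair's well and moves the mean
best-hit rank from ~70 into the top 3 (see `tests/test_acceptance.py`).

The same pipeline is scriptable from the shell:

```
cgdock synth --out fx --n-decoys 200 --seed 3
cgdock score fx/native.pdb --receptor A --ligand B \
       --decoys fx/decoys.cgpdb --out scores.tsv
cgdock evaluate fx/native.pdb --receptor A --ligand B \
       --decoys fx/decoys.cgpdb --scores scores.tsv --out ranking.tsv
```

## Documentation

`docs/methods.md` describes the model, the parameterization, the harmonic
scaffold used during minimization, the synthetic-benchmark design and the
package's known limitations.
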