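# enseval

Evaluation toolkit for protein conformational ensembles.

Machine-learned ensemble generators (diffusion models, flow matching,
AlphaFold-derived samplers) promise cheap alternatives to molecular-dynamics
sampling, but their output has to be scored against reference ensembles:
do they reproduce residue fluctuations, side-chain rotamer statistics and
foldedness, are their structures stereochemically sound, and do
temperature-conditioned models show sensible melting behavior?  `enseval`
implements that scoring battery for structural-bioinformatics practitioners,
plus the restrained relaxation step used to clean steric clashes out of
generated structures, and seeded synthetic-ensemble generators so every
score is testable against known ground truth without any external data.

## Scores

For a generated ensemble measured against a reference ensemble and a native
(initial) structure `x0`:

* **Cα RMSF / PCC** — per-residue root-mean-square fluctuation after
  superposition onto the initial structure; ensembles are compared by the
  Pearson correlation of their profiles.
* **initRMSD, Rg, contact maps, PCA landscapes** — per-frame Cα RMSD to
  `x0`, heavy-atom radius of gyration, Cα–Cα contact frequencies (9 Å
  cutoff), and 2D landscapes from PCA on non-adjacent Cα–Cα distances with
  free energies `G = −RT ln P` on a 50×50 grid.
* **chiJSD** — mean Jensen–Shannon divergence (natural log) between 9-bin
  joint histograms of consecutive side-chain torsion pairs (χ1,χ2), (χ2,χ3),
  (χ3,χ4), binned on the torus with edges at −120°/0°/120°.  0 for identical
  rotamer statistics, ln 2 ≈ 0.693 for disjoint ones.
* **Q and FSF** — soft fraction of native contacts
  `Q(x) = (1/N) Σ 1/(1+exp(β(d_ij − λ d⁰_ij)))` with β = 5 Å⁻¹, λ = 1.2 over
  residue pairs ≥ 3 apart in sequence with native shortest heavy-atom
  distance d⁰ ≤ 10 Å; the folded-state fraction is the fraction of frames
  with Q > 0.6.
* **SSEP** — ensemble-average fraction of natively helical/strand residues
  (DSSP, 3-state) that retain their native state.
* **Integrity counters** — heavy-atom clashes (non-adjacent residues,
  d < ½·(r_i+r_j) with Bondi vdW radii) and peptide-bond violations
  (|b − 1.348 Å| / 0.029 Å ≥ 3) per snapshot.
* **Melting points** — an observable series f(T) (FSF or SSEP across
  temperature-labelled ensembles) is fitted with
  `f(T) = y_min + (y_max − y_min)/(1 + exp(−(T − Tm)/k))`, y-range fixed to
  the series extremes, giving the apparent melting temperature Tm.
* **Restrained relaxation** — per-frame minimization of an idealized bonded
  energy plus a soft nonbonded repulsion, with φ/ψ/χ torsions and adjacent
  Cα–Cα distances tethered to their input values, removing clashes while
  leaving backbone and rotamers essentially untouched.

## Worked example

```python
import numpy as np
from enseval import chijsd, folded_state_fraction, native_contacts, rmsf_pcc, rmsf_profile
from enseval.synthetic import build_ideal_chain, torsion_jitter_ensemble, two_state_ensemble
from enseval.thermal import MeltCurveModel, build_melt_series

base = build_ideal_chain("AKLSEVFAKLSEVFAK", "helix")   # ideal-geometry native
topo, native = base.topology, base.frames[0]

# a "reference" and a "generated" ensemble with different torsion noise
ref = torsion_jitter_ensemble(topo, native, 50, sigma_deg=5.0, seed=1)
gen = torsion_jitter_ensemble(topo, native, 50, sigma_deg=9.0, seed=2)
print("rmsf_pcc:", round(rmsf_pcc(rmsf_profile(ref, native), rmsf_profile(gen, native)), 3))
print("chijsd(jitter):", round(chijsd(ref, gen), 4))

# chiJSD reacts to rotamer-population shifts, not to in-bin jitter
from enseval.synthetic import rotamer_ensemble
t_ref = np.array([[0.7, 0.1, 0.0], [0.1, 0.1, 0.0], [0.0, 0.0, 0.0]])
t_gen = np.array([[0.3, 0.1, 0.0], [0.1, 0.5, 0.0], [0.0, 0.0, 0.0]])
pairs = [(1, 2), (2, 3), (3, 4)]
a = rotamer_ensemble("GKG", {(1, p): t_ref for p in pairs}, 500, seed=3)
b = rotamer_ensemble("GKG", {(1, p): t_gen for p in pairs}, 500, seed=4)
print("chijsd(shifted rotamers):", round(chijsd(a, b), 4))

# melting curve from a temperature sweep of two-state ensembles (true Tm 400 K)
ensembles = [
    two_state_ensemble(topo, native, T, true_tm=400.0, true_k=20.0,
                       n_frames=100, seed=10 + k)[0]
    for k, T in enumerate(np.arange(300.0, 460.0, 20.0))
]
series = build_melt_series(ensembles, native, "FSF")
print(MeltCurveModel(series).fit().summary())
```

Output:

```
rmsf_pcc: 0.916
chijsd(jitter): 0.0
chijsd(shifted rotamers): 0.1437
Melting-curve sigmoid fit
=========================================
observable        FSF
n temperatures    8
T range (K)       300.0 - 440.0
y_min / y_max     0.1100 / 1.0000  (fixed to series)
Tm (K)            393.77
k_slope (K)       -17.29
RSS               1.063e-02
converged         True
```

The RMSF profiles of the two noise levels correlate strongly (0.92).  The
chiJSD is exactly 0 for the jittered pair — both sample the same rotamer
wells, and small in-bin angle noise is invisible to the 120° binning by
design — whereas a genuine rotamer-population shift registers clearly
(0.14 against the 0–0.693 range).  The fitted melting point recovers the
generator's true 400 K transition to within a few Kelvin, with a negative
slope because foldedness decreases with temperature.

The same battery is available from the shell:

```bash
enseval synth AKLSEVFAK --mode two_state --n-frames 100 \
    --param temperature=380 --param true_tm=400 --out T380.pdb
enseval compare ref.pdb gen.pdb --native native.pdb --out report.json
enseval melt manifest.txt --native native.pdb --out fit.json
enseval relax generated.pdb --out relaxed.pdb --diagnostics diag.tsv
```

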