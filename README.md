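# membranescatter

Analysis pipeline for studying how cationic antimicrobial peptides (AMPs) —
including designs carrying the unnatural residues norvaline (`U`) and
1,2,3,4-tetrahydroisoquinoline-3-carboxylic acid, Tic (`X`) — interact with
lipid model membranes. It bundles the five computational stages such a study
needs, each usable from Python (scikit-learn-style fitter classes) or from a
command line:

| stage | what it computes |
|---|---|
| `peptides` | net charge, mean hydrophobicity *H* and helical hydrophobic moment *μH* of a sequence |
| `cd` | mean residue ellipticity (MRE) conversion and four-motif secondary-structure deconvolution of CD spectra |
| `laxs` | bending modulus *K*<sub>C</sub> and compression modulus *B* from the lateral falloff of diffuse X-ray scattering of oriented bilayer stacks |
| `waxs` | acyl-chain order parameter *S*<sub>xray</sub> from a Maier–Saupe fit of the wide-angle angular profile |
| `sdp` | scattering-density-profile (SDP) modelling of bilayer form factors \|F(q<sub>z</sub>)\|: area per lipid *A*<sub>L</sub>, headgroup spacing *D*<sub>HH</sub>, hydrocarbon thickness 2*D*<sub>C</sub>, and the peptide's location (headgroup vs hydrocarbon) selected by χ² |
| `synthetic` | seeded ground-truth generators for every stage, with recorded provenance bundles |

## The models

**Hydrophobic moment.** For residues with hydrophobicities *h<sub>k</sub>*
placed every δ = 100° around an ideal helical wheel,
μH = (1/N)·|Σ<sub>k</sub> h<sub>k</sub> (sin kδ, cos kδ)| (Eisenberg
convention, Fauchère–Pliska scale, full-sequence window).

**Smectic elasticity.** A stack of N fluid bilayers with free energy

    F = Σ_n ∫ d²r [ K_C/2 (∇²u_n)² + B/2 (u_{n+1} − u_n)² ]

fluctuates by equipartition; the height-difference correlations
⟨[u<sub>n</sub>(r) − u<sub>m</sub>(0)]²⟩ damp the interlayer interference and
turn Bragg sheets into diffuse lobes. *K*<sub>C</sub> is fitted from the
q<sub>r</sub> falloff of the lobes with counting-statistics weighting.

**Chain order.** Chains are long thin rods tilted by β with density
∝ exp(m cos²β) sinβ; the projected angular intensity reduces to
I(φ) ∝ e^a I₀(a) with a = m cos²φ / 2, and
S<sub>xray</sub> = ⟨(3cos²β − 1)/2⟩.

**SDP.** Component groups (Phos, CG, CH₂, CH₃, Water, peptide) occupy
volume-conserving profiles; ρ(z) = Σ (e/V)·P(z), F(q<sub>z</sub>) =
∫(ρ − ρ<sub>w</sub>) cos(q<sub>z</sub>z) dz. The peptide envelope is placed in
the headgroup, the hydrocarbon core, or both, and hypotheses are ranked by χ².

## Worked example

```bash
$ membranescatter props --seq RRVWRWVRRVWRWVRR --name E2-35 --out out/
$ cat out/props.csv
name,n_residues,charge,muH,H,muH_over_H
E2-35,16,+8,0.736,0.363,2.03
```

The 16-residue peptide carries eight arginines (charge +8); its mean
Fauchère–Pliska hydrophobicity is 0.363 and its helical hydrophobic moment
0.736 — a strongly amphipathic helix (μH/H ≈ 2). Sequences containing `U`/`X`
report charge only until you supply `--h-nva`/`--h-tic`, because no published
hydrophobicity values exist for those residues.

A full synthetic elasticity round trip:

```bash
$ membranescatter simulate laxs --seed 7 -p kc=20 -p b=5e-6 --out out/
$ membranescatter laxs-fit --map out/diffuse_map.csv \
      --form-factor out/form_factor.csv --init-kc 10 --out out/
$ python -c "import json; d=json.load(open('out/laxs_fit.json')); print(round(d['kc'],2))"
21.29
```

i.e. the bending modulus used by the generator (20 k<sub>B</sub>T) is
recovered from the noisy (5% peak counting noise) map within ~6%, with the
95% confidence interval [20.3, 22.3] k<sub>B</sub>T reported alongside.

In Python the same stages are estimator classes:

```python
from membranescatter import ChainOrderFitter, gen_waxs_profile
prof, truth = gen_waxs_profile(m=6.0, noise_sd=0.02, seed=1)
fit = ChainOrderFitter().fit(prof)
fit.m_, fit.s_xray_          # ~6.0, ~0.71
```

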