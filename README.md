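# hemedist

Proton-to-heme-iron distances from NMR paramagnetic relaxation
enhancement, for cytochrome P450 / ligand systems.

## The problem

When a substrate binds in the active site of a ferric (Fe³⁺,
paramagnetic) P450, the unpaired electron spins of the heme iron relax
nearby ligand protons faster than they would relax on their own.  If
ligand exchange between the free and bound pools is fast, the observed
longitudinal relaxation time T₁ of each proton is a population-weighted
average, and the *extra* relaxation caused by the iron encodes the
proton–iron distance through the Solomon–Bloembergen dipolar
interaction.  Measuring T₁ per proton in the paramagnetic ferric enzyme
and again in the diamagnetic ferrous-CO complex therefore yields a set
of distance restraints that report how the substrate sits over the
heme — e.g. whether the site of metabolism is the closest approach.

This package implements the complete quantitative chain for such a
study (here: human CYP1A2 wild type and active-site mutants with
phenacetin):

1. **T₁ fitting** — nonlinear least squares of inversion-recovery peak
   heights, `H(d₂) = H∞·(1 − 2B·e^(−d₂/T₁))`, with the inversion
   efficiency B ∈ (0.4, 1.1] free (`hemedist.relaxation`).
2. **Spectral binding** — the one-site isotherm
   `ΔA = B_max·[S]/(K_s + [S])` fitted to difference-absorbance
   titrations, plus type I / type II difference-spectrum classification
   (`hemedist.binding`).
3. **Spin-state deconvolution** — three Gaussian bands (δ ~360 nm,
   high-spin ~392 nm, low-spin ~417 nm) fitted to the 320–500 nm Soret
   region; `f_HS` is the high-spin area fraction of the two Soret bands
   (`hemedist.spinstate`).
4. **Distance engine** — the paramagnetic relaxation time
   `1/T₁P = 1/T₁(Fe³⁺) − 1/T₁(Fe²⁺–CO)`, the bound fraction
   `α_m = [P450]/(K_s + [S])`, the spin factor
   `S(S+1) = 8.75·f_HS + 0.75·f_LS`, and finally

   ```
   r = [9.78×10¹⁶ · T₁P · α_m · S(S+1) · τ_c]^(1/6)   (Å)
   ```

   with first-order error propagation from the T₁ standard errors and a
   Monte-Carlo cross-check; plus the fast-exchange diagnostic
   (1/T₁P vs 1/T must have positive slope, R² ≥ 0.95)
   (`hemedist.distance`).
5. **Pipeline and synthetic data** — per-enzyme orchestration and
   ranking (`hemedist.pipeline`), and generators that simulate every
   input modality with known ground truth (`hemedist.simulate`).

The measured inputs of the CYP1A2/phenacetin study (T₁ pairs,
concentrations, K_s, bound-state spin fractions, τ_c = 3.38×10⁻¹⁰ s)
ship in `hemedist.datasets`; distances are always recomputed.

## Worked example

```python
>>> import hemedist as hd
>>> report = hd.run_study(hd.cyp1a2_phenacetin_study())
>>> wt = report.enzyme("CYP1A2 WT")
>>> print(wt.table[["proton_label", "t1p_s", "r_A", "r_se_A"]].round(2))
  proton_label  t1p_s   r_A  r_se_A
0          2,6  11.02  6.76    0.29
1          3,5  10.52  6.71    0.12
2       -OCH2-   9.19  6.56    0.83
3       -COCH3  27.54  7.88    1.36
4         -CH3  10.17  6.68    0.53
```

The `-OCH2-` row is the site of metabolism: T₁P = 9.19 s is the purely
paramagnetic relaxation time for the methylene protons, and r = 6.56 Å
(± 0.83 Å) is their distance from the heme iron.  Ranking the enzymes
by that proton:

```python
>>> hd.compare_site_of_metabolism(report, "-OCH2-")
         enzyme_label    r_A  r_se_A  delta_to_previous_A  delta_se_A
0        CYP1A2 L382V   5.93    0.18                  NaN         NaN
1  CYP1A2 L382V/N312L   5.97    0.20                 0.04        0.27
2           CYP1A2 WT   6.56    0.83                 0.59        0.85
3        CYP1A2 N312L   7.87    1.06                 1.30        1.35
```

i.e. the L382V substitution pulls the site of metabolism ~0.6 Å closer
to the iron than in the wild type, while N312L pushes it ~1.3 Å away —
consistent with the mutants' faster / slower O-deethylation.

The numbered scripts under `analysis/` rerun each stage as a narrative
(synthetic-input generation, T₁ recovery, K_s/spin recovery, the
distance table above, fast-exchange diagnostics) and write their tables
under `results/`.  A `hemedist` console script exposes the same stages
(`fit-t1`, `fit-ks`, `spin`, `classify-spectrum`, `check-exchange`,
`distance`, `pipeline`, `simulate`).

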