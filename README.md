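# multitrophic

Simulation and mean-field theory for random consumer-resource ecosystems with
trophic structure: plants (primary producers), herbivores (primary consumers)
and carnivores (secondary consumers), plus a generalization to food chains of
arbitrary depth.

The package is for theoretical ecologists and statistical physicists who want
to ask how diversity, competition and energy flow interact across trophic
levels — e.g. when a community is limited from below (bottom-up control, by
plant carrying capacities) versus from above (top-down control, by predator
mortality) — without fitting any empirical data: all inputs are ensemble
parameters and seeds.

## Model

A community has `M_R` plants with abundances `R_P`, `M_N` herbivores `N_i` and
`M_X` carnivores `X_a`, coupled by consumer preference matrices `c` (herbivore
on plant, `M_N x M_R`) and `d` (carnivore on herbivore, `M_X x M_N`):

    dX_a/dt = X_a ( eta_X sum_j d_aj N_j - u_a )
    dN_i/dt = N_i ( eta_N sum_P c_iP R_P - m_i - sum_b d_bi X_b )
    dR_P/dt = R_P ( K_P - R_P - sum_j c_jP N_j )

with conversion efficiencies `eta_X, eta_N` in [0, 1], carrying capacities
`K_P`, and death rates `m_i`, `u_a`.  Preference entries are i.i.d. with mean
`mu/M_prey` and standard deviation `sigma/sqrt(M_prey)` (Gaussian by default;
a strictly-positive uniform dialect with identical first two moments is also
provided), and `K, m, u` are Gaussian with means `k, m, u` and spreads
`sigma_K, sigma_m, sigma_u`.

In the large-pool limit (fixed ratios `r1 = M_X/M_N`, `r2 = M_N/M_R`) the
zero-temperature cavity method closes the statistics of the steady state: a
typical species at each level is a rectified Gaussian

    B = max(0, (g_eff + sigma_g_eff z) / D_eff),   z ~ N(0, 1),

where `D_eff` is an *emergent competition* coefficient — self-limitation that
the bare dynamics of the consumer levels do not contain, generated by
feedbacks through adjacent levels.  The six level means and second moments
satisfy six self-consistency equations built from the truncated-Gaussian
integrals `w_n`; survival fractions are `phi = w_0(g_eff/sigma_g_eff)`, and
the level-averaged susceptibilities `chi = <dX/du>`, `nu = <dN/dm>`,
`kappa = <dR/dK>` have closed forms in the survival fractions.

Three order parameters quantify top-down versus bottom-up control; the
species-packing one is simply `M_X*/M_N*`, the fraction of realized
herbivore-level niches occupied by surviving carnivores, with 0.5 separating
the two regimes.

## Worked example

```python
>>> import multitrophic as mt
>>> p = mt.ModelParams3()        # 50 carnivores, 56 herbivores, 62 plants;
...                              # k=4, m=u=1, sigma_c=sigma_d=0.5, eta_X=0.8, eta_N=0.6
>>> st = mt.solve(p, seed=1)     # cavity solution
>>> print(f"means:  X={st.mean_X:.4f}  N={st.mean_N:.4f}  R={st.mean_R:.4f}")
means:  X=0.8868  N=0.9443  R=2.7710
>>> print(f"phis:   X={st.phi_X:.4f}  N={st.phi_N:.4f}  R={st.phi_R:.4f}")
phis:   X=0.3653  N=0.4585  R=0.9999
>>> print(f"D_eff:  X={st.D_eff_X:.4f}  N={st.D_eff_N:.4f}  R={st.D_eff_R:.4f}")
D_eff:  X=0.2004  N=0.4576  R=1.1357
>>> print(f"packing OP = {mt.packing_order_parameter(st):.4f}")
packing OP = 0.7114
```

Reading: about 37% of the carnivore pool and 46% of the herbivore pool
survive competitive sorting, while essentially every plant persists.  The
emergent competition on plants exceeds their bare logistic value
(`D_eff_R = 1.14 > 1`), and the packing order parameter 0.71 > 0.5 classifies
the community as top-down controlled: surviving carnivores fill 71% of the
realized niches in the herbivore level.

The theory cross-validates against direct integration of the same random
communities:

```python
>>> stats = mt.ensemble_statistics(p, 20, seed=3)   # 20 simulated systems
>>> po = stats.pooled
>>> print(f"sim(20): meanN={po.mean_N:.4f} phiN={po.survival_fractions[1]:.4f}")
sim(20): meanN=0.9620 phiN=0.4625
```

which matches the cavity values (0.9443, 0.4585) within the ensemble's
standard error.

A command-line interface mirrors the library (`multitrophic simulate|cavity|
nlevel|scan|toy|finite-size CONFIG.yaml`), reading YAML/JSON configs and
writing CSV/JSON artifacts together with the fully resolved configuration and
a run log.

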