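# reefres

Quantitative analysis of seabird-driven coral-reef recovery after mass
bleaching, for reef ecologists and biostatisticians studying nutrient
subsidies and reef resilience.

On remote Indo-Pacific atolls, rat-free islands host dense seabird colonies
whose guano subsidizes adjacent reefs with nitrogen (traced by elevated
symbiont δ¹⁵N in corals), while rat-infested islands receive almost none.
`reefres` implements the full analysis chain linking that subsidy to reef
recovery:

1. **Synthetic survey generator** — tagged *Acropora* colonies (natural and
   reciprocally transplanted between seabird/rat island pairs) with annual
   planar areas and symbiont δ¹⁵N, zero-inflated recruit quadrat counts,
   point-intercept benthic surveys over nine functional groups, and
   per-island cover endpoints.  Defaults are calibrated to the study's
   headline effects (2.0× transplant and 2.4× natural growth folds, 2.1×
   growth per ‰ δ¹⁵N, 0.9 ‰ treatment difference, 0.52/0.68 recruits
   m⁻² yr⁻¹), so the whole pipeline is testable without field data.
2. **Hierarchical contrasts** — a Gibbs-sampled normal model with random
   intercepts (island within atoll, colony, year) and a Metropolis step for
   the half-normal-prior standard deviations, reporting fold-changes on the
   log scale and δ¹⁵N differences on the raw scale.
3. **Gompertz reconstruction** — the island-scale recovery model.  Monthly
   *Acropora* cover C follows a truncated-normal Markov process

       C[t+1] ~ N(Cμ[t+1], 1/Cτ) T(0, 100)
       Cμ[t+1] = M_t · exp(−ln(M_t/C₁) · e^(−G_t (t+1))) + R_t

   anchored at the 2018 cover C₁ and approaching the 2021 cover M, with
   monthly draws M_t ~ N(Mμ, 1/Mτ), G_t ~ N(Gμ, 1/Gτ), R_t ~ N(Rμ, 1/Rτ)
   and gamma hyperpriors Cτ ~ Γ(16, 6), Mτ ~ Γ(25, 1), Gτ, Rτ ~ Γ(1975, 1.77).
   G is mean colony growth × colony density (11.2 and 4.9 cm²/month × 3.6
   m⁻² → 0.4032 and 0.1764 month⁻¹); R converts annual recruit density at
   4 cm² per recruit to a monthly cover increment (0.173 and 0.227).
   Recovery time is the first month a draw reaches 90 % of its final cover;
   total recovery adds the 36 months from bleaching to the first survey.
4. **Benthic community statistics** — pooled category proportions,
   Bray-Curtis distance to the pre-bleaching baseline
   (1 − 2·Σmin(aᵢ,bᵢ)/Σ(aᵢ+bᵢ)), and recruit densities with a two-stage
   hierarchical bootstrap.

## Worked example

```python
import reefres as rr
from reefres.colony import transplant_growth_contrast

cfg = rr.CalibrationConfig()
islands = rr.generate_islands(cfg)

# colony scale: growth fold-change by transplant treatment
colonies, isotopes = rr.generate_colonies(islands, cfg, "experimental", seed=1)
est = transplant_growth_contrast(colonies, seed=1)
print(f"transplant effect: {est.point:.2f}-fold "
      f"(95% CI {est.interval_lo:.2f}-{est.interval_hi:.2f})")

# island scale: reconstructed recovery of Acropora cover
endpoints = rr.generate_cover_endpoints(islands, cfg)
posts = rr.simulate_posterior(
    endpoints, rr.study_rate_params(), rr.GompertzPriors(), seed=1
)
for treatment, rec in rr.pooled_recovery(posts).items():
    print(f"{treatment}: {rec.months_to_threshold:.0f} months "
          f"[{rec.ci_lo:.0f}, {rec.ci_hi:.0f}], "
          f"total {rec.total_years:.2f} years")
```

prints

```
transplant effect: 2.06-fold (95% CI 1.55-2.73)
seabird: 8 months [7, 10], total 3.67 years
rat: 18 months [14, 22], total 4.50 years
```

Corals moved to seabird islands grow about twice as fast as those moved to
rat islands, and modeled *Acropora* cover regains 90 % of its final value 8
months after the 2018 survey around seabird islands versus 18 months around
rat islands — total recovery times of 3.67 versus 4.50 years from the
bleaching event.

The same stages are available from the shell:

```sh
reefres run --out runs/demo --seed 1          # full pipeline with manifest
reefres simulate --out data --seed 1          # just the synthetic tables
reefres reconstruct --endpoints data/endpoints.csv --seed 1
```

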