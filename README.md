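# necropop

Biocultural population structure of Iron Age necropolises: strontium-isotope
provenance, dental non-metric biodistance, and statistics of grave-good
assemblages, in one tested pipeline.

## The problem

When a cemetery preserves skeletons *and* grave goods, three independent
lines of evidence can be brought to bear on the same question — who were
these people, and did newcomers arrive?

1. **⁸⁷Sr/⁸⁶Sr isotopes.** Enamel fixes the strontium signature of the
   region where each tooth crown mineralized.  Comparing the
   earliest-forming sampled tooth of each individual against the local
   bioavailable range `[lower, upper]` (built as the union-span of human-bone
   and faunal baseline intervals) classifies individuals as local or
   non-local; the earliest/latest tooth pair types residential mobility
   (stable, arrived in childhood, outbound-and-returned, distinct origin).
2. **Dental biodistance.** Heritable crown/root traits (ASUDAS grades,
   dichotomized at standard breakpoints) give group divergences via the
   Freeman–Tukey-corrected Mean Measure of Divergence
   `MMD = (1/r) Σ [(θ_A − θ_B)² − (1/n_A + 1/n_B)]` with
   `θ(k,n) = ½[asin(1−2k/(n+1)) + asin(1−2(k+1)/(n+1))]`,
   `SD = √[(2/r²) Σ (1/n_A + 1/n_B)²]`, and the `MMD > 2·SD` significance
   rule, followed by classical MDS and Ward clustering.
3. **Mortuary statistics.** Binary individual × grave-good matrices are
   compared by Jaccard distance and complete linkage, tested for group
   structure by chi-square and by distance-matrix AMOVA (permutation Φ_ST),
   ordinated by correspondence analysis, and screened for sex- or
   origin-linked goods by Random-Forest Gini importance and stepwise VIF
   selection.

A synthetic-necropolis generator (`necropop.simulate`) reproduces the
statistical structure these analyses assume — isotope mixtures, group-linked
trait probabilities, sex/age-structured goods — so every stage is testable
end to end without restricted data.  See `docs/methods.md` for formulas,
defaults and caveats.

## Worked example

The package ships the reference isotope table (49 measurements on 23
individuals plus 5 bone baselines) and the 19-group × 14-trait frequency
table.  Classify provenance:

```python
from necropop import (classify_provenance, group_by_individual,
                      read_isotope_table, summarize_ratios)
from necropop.io import packaged_data
from necropop.isotopes import LocalRange

samples = read_isotope_table(packaged_data("table2_isotopes.csv"))
bone = [s.ratio for s in samples if s.material == "bone"]
print(summarize_ratios(bone))           # (0.7087272, 0.000116502...)
calls = classify_provenance(group_by_individual(samples),
                            LocalRange(0.7086, 0.7090))
print(sum(c.status == "nonlocal" for c in calls), "/", len(calls))  # 11 / 23
```

The bone baseline summarizes to 0.7087 ± 0.0001 (2σ); 11 of the 23 sampled
individuals have their earliest tooth outside the inclusive local range —
they spent early childhood on different geology.  Biodistance:

```python
from necropop import mmd_matrix, read_frequency_table

groups, panel = read_frequency_table(packaged_data("table4_frequencies.csv"))
m = mmd_matrix(groups, panel)           # 19x19 over the 10 retained traits
print(round(m.mmd.loc["MVNL", "BRIT"], 3))   # 0.046
print(round(m.mmd.loc["MV", "LAA"], 3))      # -0.016
print(m.significant.loc["MVL", "BRIT"])      # True
```

The non-local subsample (MVNL) sits close to the Yorkshire Celts (small,
non-significant MMD of 0.046) while the pooled sample is indistinguishable
from the Italic groups (negative MMD to the Archaic Latini); the local
subsample diverges significantly from all three Celtic samples.  Mortuary
structure on a synthetic necropolis:

```python
from necropop import SyntheticConfig, amova, generate_dataset, jaccard_matrix

data = generate_dataset(SyntheticConfig(scenario="A"), seed=101)
dist = jaccard_matrix(data.artifacts)
meta = data.artifacts.metadata
sex = meta["sex"].where(meta["sex"].isin(["male", "female"]))
origin = meta["origin_code"].map({0: "local", 2: "nonlocal"})
print(round(amova(dist, sex, n_permutations=999, seed=1).phi_st, 3))  # 0.215
print(amova(dist, origin, n_permutations=999, seed=1).permutation_p)  # 0.281
```

Sex structures the grave goods strongly (Φ_ST = 0.21, p = 0.001) while
origin does not (Φ_ST ≈ 0.005, p = 0.28) — the generator's scenario-A truth,
recovered.

There is also a CLI: `necropop isotopes`, `necropop biodistance`,
`necropop mortuary --input <csv>`, `necropop simulate --scenario A`, and
`necropop all`, each writing JSON/TSV/Newick reports plus a run log with
every threshold and seed.

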