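"""Generate a synthetic multi-cohort study with planted effects.

Five two-arm microarray-like cohorts (4 control + 4 treated each), 1000
genes, 50 of which carry a standardized up-shift of 2 within-arm SDs in
the treated arm, 3 probes per gene.
"""

from plasmameta import SyntheticConfig, generate_multicohort

sim = generate_multicohort(SyntheticConfig(seed=7))

print(f"cohorts: {len(sim.cohorts)}")
for cohort in sim.cohorts:
    n_c = len(cohort.samples_in("control"))
    n_t = len(cohort.samples_in("treated"))
    print(f"  {cohort.cohort_id}: {cohort.matrix.data.shape[0]} probes, "
          f"{n_c} control + {n_t} treated samples")
print(f"planted signature genes: {len(sim.truth.signature_genes)}")
print(sim.truth.per_cohort_effects.head(3).to_string(index=False))
# true_effect is the realized standardized shift (in SD units) of that
# gene's treated arm in that cohort; every unlisted gene has effect 0.
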