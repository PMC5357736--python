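"""Bootstrap significance of spectral variables and metabolite calls.

Within each MCCV model, training subjects are resampled with replacement
and the PLS-DA fit repeated; pooled coefficients give each spectral
variable a p-value, converted to Benjamini-Hochberg q-values.  Variables
are aggregated to metabolite calls at q <= 0.01 and compared with the
planted ground truth.
"""

import numpy as np

import metabodiet as md

signatures = md.default_signature_library()
design = md.CohortDesign(n_subjects=19, days=3, n_points=2000, seed=1)
matrix, annotations, truth = md.generate_cohort(design, signatures)
normalised, _ = md.normalise_cohort(matrix)
day3 = normalised.select_where(day=3)

ensemble, _ = md.run_mccv(day3, md.MCCVConfig(n_models=100, seed=1))
table = md.attach_qvalues(
    md.bootstrap_coefficients(ensemble, day3, n_boot=10)
)

n_sig = int((table["q"] <= 0.01).sum())
print(f"{n_sig} of {len(table)} spectral variables significant at q <= 0.01")

vmap = md.variable_map(signatures, ensemble.ppm)
calls = md.call_metabolites(table, vmap, q_cutoff=0.01)
called = [c for c in calls if c.called]
up = sorted(c.metabolite for c in called if c.direction == "diet1-elevated")
down = sorted(c.metabolite for c in called if c.direction == "diet4-elevated")
print(f"metabolites called diet-1-elevated: {len(up)} "
      f"(planted {len(truth['diet1_elevated'])})")
print(f"metabolites called diet-4-elevated: {len(down)} "
      f"(planted {len(truth['diet4_elevated'])})")
print("example diet-1 markers:", ", ".join(up[:5]))
print("example diet-4 markers:", ", ".join(down[:3]))

# Manhattan-style summary: strongest signed -log10(q) peaks
top = table.reindex(table["signed_logq"].abs()
                    .sort_values(ascending=False).index).head(3)
for _, row in top.iterrows():
    print(f"  delta {row['ppm']:.3f} ppm: signed -log10(q) = "
          f"{row['signed_logq']:+.1f}")
# Positive signed values mark resonances elevated after diet 1, negative
# after diet 4 - the two coloured peak sets of a discriminant Manhattan plot.
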