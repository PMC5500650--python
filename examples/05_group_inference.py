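"""Group inference on a synthetic cohort's planted fALFF table.

Covariate-adjusted F-tests per network, the outlier/normality-gated
partial correlation between practice intensity and default-mode fALFF,
and the printed-summary two-sample t.
"""
import numpy as np

from netfalff import generate_cohort, two_sample_t
from netfalff.stats import (
    ancova_group_f,
    encode_covariates,
    flag_outliers,
    normality_gate_log_transform,
    partial_correlation,
)

cohort = generate_cohort(n_tcc=22, n_ctr=18, seed=5, n_vertices=200)
table = cohort.table
z = encode_covariates(table, ("age", "sex", "education"))
g = table["group"].to_numpy()

print("covariate-adjusted group F per network (planted deficits: ICN03/05/08/10):")
for net in ("ICN03", "ICN05", "ICN08", "ICN01"):
    y = cohort.planted_falff[net].to_numpy()
    res = ancova_group_f(y, g, z, covariate_names=("age", "sex", "education"), network=net)
    print(f"  {net}: F={res.t_or_f:6.2f}, p={res.p:.4f}")

tcc = table[table["group"] == "TCC"]
hours = tcc["tcc_hours_per_week"].to_numpy()
rep = flag_outliers(hours)
print(f"\npractice-intensity outliers flagged: {rep.flags.sum()} "
      f"(fence {rep.hi_fence:.1f} h/week)")
keep = ~rep.flags
tr = normality_gate_log_transform(hours[keep])
print(f"log transform applied: {tr.transformed} "
      f"(Shapiro-Wilk p {tr.shapiro_p_before:.3f} -> {tr.shapiro_p_after})")
z_tcc = encode_covariates(tcc, ("age", "sex", "education"))
pc = partial_correlation(
    tr.values, cohort.planted_falff.loc[tcc["subject_id"], "ICN03"].to_numpy()[keep],
    z_tcc[keep], names=("log_intensity", "ICN03"),
)
print(f"partial r(intensity, DMN fALFF | age,sex,edu) = {pc.r:.3f} "
      f"(p={pc.p:.3f}, n={pc.n}; planted 0.473)")
print("  (at n=21 the sampling SE of r is ~0.2 — single-cohort estimates scatter widely)")

t, p = two_sample_t((12.2, 2.9, 22), (11.8, 2.9, 18))
print(f"\ntwo-sample t from printed education summaries: t={t:.3f}, p={p:.3f}")
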