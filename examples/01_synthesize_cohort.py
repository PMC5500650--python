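"""Generate a two-group synthetic cohort and inspect its ground truth.

The generator plants per-network fALFF levels for 22 practitioners and 18
controls (with deficits in the default-mode and frontoparietal networks),
demographics, practice exposure with one 30 h/week outlier, and
covariate-adjusted correlations.
"""
import numpy as np

from netfalff import generate_cohort

cohort = generate_cohort(n_tcc=22, n_ctr=18, seed=1, n_vertices=500)

print(cohort.table.head(5).to_string(index=False))
print()
gap = (
    cohort.planted_falff.loc[cohort.table["group"].values == "CTR", "ICN08"].mean()
    - cohort.planted_falff.loc[cohort.table["group"].values == "TCC", "ICN08"].mean()
)
print(f"planted left-FPN (ICN08) fALFF gap, control minus practitioner: {gap:.3f}")
print(f"practice intensity range (h/week): "
      f"{np.nanmin(cohort.table['tcc_hours_per_week']):.1f} - "
      f"{np.nanmax(cohort.table['tcc_hours_per_week']):.1f} (30.0 is the planted outlier)")
# One subject's scan: 243 acquired volumes, the first 5 are equilibration
scan = cohort.subject_scan(0)
print(f"scan shape (T x V): {scan.ts.data.shape}, TR = {scan.ts.tr} s")
print("the gap and the outlier are what the downstream stages must recover")
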