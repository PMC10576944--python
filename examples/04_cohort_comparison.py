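"""Replicate the two-group cohort analysis on a simulated study.

Simulates 8 thin (T1+T2) and 75 thick (T3+T4) melanoma cores whose
generator targets put the group mean H-scores at 0.95 and 0.57, scores
every core through the full image pipeline, and compares the groups by
mean, SEM, fold change, and a two-tailed unpaired t-test.
"""

from pathlib import Path

from dabquant import (
    ImageSpec,
    cohort_report,
    compare_groups,
    melanoma_study_cohort,
    score_sample,
    simulate_cohort,
)

cohort = melanoma_study_cohort(
    seed=1, template=ImageSpec(width=96, height=96, tissue_fraction=0.75)
)
samples = simulate_cohort(cohort)
records = [
    score_sample(s.image, sample_id=s.sample_id, t_stage=s.t_stage)
    for s in samples
]
cmp = compare_groups(records)

a, b = cmp.group_a, cmp.group_b
print(f"{a.label}:  n={a.n:2d}  mean H = {a.mean_h:.3f}  SEM = {a.sem_h:.3f}")
print(f"{b.label}: n={b.n:2d}  mean H = {b.mean_h:.3f}  SEM = {b.sem_h:.3f}")
print(f"fold change = {cmp.fold_change:.3f} ({cmp.direction})")
print(f"t = {cmp.t_statistic:.3f}, df = {cmp.df:.0f}, p = {cmp.p_value:.3g} "
      f"-> {'significant' if cmp.significant else 'not significant'} "
      f"at alpha = {cmp.alpha}")

out = Path("example_output")
csv_path, chart_path = cohort_report([cmp], out)
print(f"wrote {csv_path} and {chart_path}")
# A fold change near 1.6-1.7 with p well below 0.05 reproduces, on
# synthetic data, the downregulation pattern the pipeline is built to
# quantify: lower H-scores in thick (>2 mm) than thin (<=2 mm) tumors.
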