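"""Neurological-score cohorts and group statistics.

Draws two 11-rat cohorts at the published group means (conscious 5.9,
anesthetized 4.6 on the 0-18 scale), totals each rat over 3 examiners x 3
trials, and compares the groups: mean ± SEM, Welch t-test, and the relative
difference in percent of the anesthetic-group mean.
"""

from speckleflow import compare_groups, make_nss_cohort, nss_total, percent_difference

cohorts = {}
for name, mean in (("conscious", 5.9), ("anesthetic", 4.6)):
    records = make_nss_cohort(mean, group_sd=1.0, n_rats=11, seed=42, id_prefix=name)
    rat_ids = sorted({r.rat_id for r in records})
    cohorts[name] = [nss_total([r for r in records if r.rat_id == rid]) for rid in rat_ids]

gc = compare_groups(cohorts["conscious"], cohorts["anesthetic"])
print(f"conscious : {gc.mean_a:.2f} ± {gc.sem_a:.2f} (n=11)")
print(f"anesthetic: {gc.mean_b:.2f} ± {gc.sem_b:.2f} (n=11)")
print(f"Welch t = {gc.t_stat:.3f}, p = {gc.p_value:.4f}, significant: {gc.significant}")
print(f"relative difference: {gc.percent_diff:.1f}% of the anesthetic mean")

print("\nworked example on the published group means themselves:")
print(f"  MRI lesion  63.7 vs 40.1 mm^3 -> {percent_difference(63.7, 40.1)}%")
print(f"  NSS          5.9 vs  4.6     -> {percent_difference(5.9, 4.6)}%")
print(f"  TTC infarct 47   vs 32  mm^3 -> {percent_difference(47.0, 32.0)}%")
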