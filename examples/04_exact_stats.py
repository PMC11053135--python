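"""The exact nonparametric statistics behind the site-specificity claims.

Runs the package's enumerated tests on the published per-animal
percent-of-background table (five cats): a one-sided paired Wilcoxon
signed-rank test per channel (rostral vs caudal), the exact Mann-Whitney
limits for completely separated latency groups, and Kruskal-Wallis with
Dunn's post-hoc on a small example.
"""

import eesmap as em

table = em.load_cohort_percentages()
print("paired Wilcoxon signed-rank (exact, n = 5 animals):")
for channel in ("CYST", "Detr", "EUS"):
    grp = table[table.channel == channel]
    if channel == "EUS":
        res = em.wilcoxon_exact(grp.caudal_pct, grp.rostral_pct,
                                alternative="greater")
        direction = "caudal > rostral"
    else:
        res = em.wilcoxon_exact(grp.rostral_pct, grp.caudal_pct,
                                alternative="greater")
        direction = "rostral > caudal"
    print(f"  {channel:>4} ({direction}): W = {res.statistic:g}, "
          f"p = {em.round_half_up(res.p_value, 4):.4f}")

print("\nexact two-sided Mann-Whitney under complete separation:")
for n1, n2 in ((4, 5), (3, 5)):
    x = list(range(n1))
    y = [v + 10 for v in range(n2)]
    res = em.mannwhitney_exact(x, y)
    print(f"  sizes ({n1}, {n2}): U = {res.statistic:g}, "
          f"p = {em.round_half_up(res.p_value, 4):.4f}")

print("\nKruskal-Wallis + Dunn on three ordered pairs:")
groups = [[1, 2], [3, 4], [5, 6]]
kw = em.kruskal_wallis(groups)
print(f"  H = {kw.statistic:.3f}, p = {kw.p_value:.4f} (chi-square, 2 df)")
for d in em.dunn_posthoc(groups):
    print(f"  Dunn {d.pair}: z = {d.statistic:+.3f}, p = {d.p_value:.4f}")
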