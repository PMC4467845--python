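"""Do activity concentrations differ between landing sites?

One-way ANOVA across the three locations for each nuclide in the
bundled fish survey, followed by Tukey's HSD to identify which pairs of
sites differ at alpha = 0.05.
"""

from seadose import oneway_anova, tukey_hsd
from seadose.datasets import load_malacca_activity

records = load_malacca_activity()
for chain in ("Ra-226", "Th-232", "K-40"):
    groups: dict[str, list[float]] = {}
    for rec in records:
        if rec.matrix == "fish":
            groups.setdefault(rec.location, []).append(rec.activities[chain].value)
    anova = oneway_anova(groups)
    verdict = "significant" if anova.p_value < 0.05 else "not significant"
    print(
        f"{chain}: F({anova.df_between},{anova.df_within}) = "
        f"{anova.f_statistic:.2f}, p = {anova.p_value:.2g} ({verdict})"
    )
    for comp in tukey_hsd(groups, alpha=0.05).pairwise:
        mark = "*" if comp.significant else " "
        print(
            f"   {mark} {comp.group_a} vs {comp.group_b}: "
            f"diff {comp.mean_difference:+.2f}, critical {comp.critical_difference:.2f}"
        )
print()
print("A '*' marks location pairs whose mean activities differ by more than")
print("the Tukey honestly-significant difference at the 5% level.")
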