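"""Full study emulation: 15 subjects, 60 MVCs, 7 measurement points.

Generates the default calibrated cohort, extracts every metric from the
rendered signals, and prints the study-style results: absolute values,
mean per-subject relative changes at exercise end, and the
repeated-measures inference per quantity.
"""

from myofatigue import GeneratorConfig, analyze_cohort, generate_cohort

config = GeneratorConfig()
cohort = generate_cohort(config, seed=1)
summary = analyze_cohort(cohort)

print("absolute values, mean +/- SD (control -> exercise end):")
for q, unit in (("mvc", "Nm"), ("db_pot", "Nm"), ("tw_pot", "Nm"),
                ("mu", "kPa")):
    sub = summary.absolute[summary.absolute["quantity"] == q] \
        .set_index("timepoint")
    c, e = sub.loc["Ctrl"], sub.loc["MVC60"]
    print(f"  {q:7s} {c['mean']:7.1f} +/- {c['sd']:5.1f} -> "
          f"{e['mean']:6.1f} +/- {e['sd']:5.1f} {unit}")

print("\nmean per-subject change at exercise end (ANOVA on absolute values):")
anova = summary.anova.set_index("quantity")
for q in ("mvc", "db_pot", "tw_pot", "emd", "ct", "mrtd", "mu"):
    a = anova.loc[q]
    p = "<0.001" if a["p"] < 1e-3 else f"{a['p']:.3f}"
    print(f"  {q:7s} {summary.end_change(q):+6.1f}%   "
          f"F({a['df1']:.0f},{a['df2']:.0f}) = {a['f']:7.1f}, p {p}")

lsd = summary.lsd
first_sig = {}
for q in ("mvc", "mu"):
    sub = lsd[(lsd["quantity"] == q) & (lsd["p"] < 1e-3)]
    first_sig[q] = sub["timepoint"].iloc[0] if len(sub) else "none"
print(f"\nfirst time point significantly below control (LSD, p<0.001): "
      f"MVC from {first_sig['mvc']}, modulus from {first_sig['mu']}")
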