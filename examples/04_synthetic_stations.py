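"""Synthetic station tables and the observational statistics pipeline.

Generates the four-site suite, summarizes each station, and recovers the
multi-site mean anomaly that drives the budget.
"""

from trioxy import generate_four_site_suite, multi_site_average, site_summary

suite = generate_four_site_suite(seed=0)
means = []
print(f"{'site':<10} {'n':>4} {'mean D17O':>10} {'mean d18O':>10} {'RMA slope':>16}")
for name, table in suite.items():
    s = site_summary(table)
    cap = s.stats.loc["D17O_permil", "mean"]
    d18 = s.stats.loc["d18O_permil", "mean"]
    means.append(cap)
    print(f"{name:<10} {s.n:>4} {cap:>10.4f} {d18:>10.2f} "
          f"{s.regression.slope:>8.4f} +/- {s.regression.slope_se:.4f}")

mean, se = multi_site_average(means)
print(f"\nfour-site mean Delta-17O: {mean:.4f} +/- {se:.4f} permil")
print("(each station counts once; the published analysis averages the four "
      "site means to 0.326 +/- 0.005 permil)")
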