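"""Sample-size planning for detecting a minimally relevant correlation.

Converts a standardized mean difference of 0.24 (a clinically relevant
depression effect) to a correlation and asks how many participants a
confirmatory study needs to detect it with 80% power.
"""

from phenoframe import PowerQuery, correlation_power, required_n_correlation, smd_to_r

d = 0.24
r = smd_to_r(d)
print(f"standardized mean difference d = {d} corresponds to r = {r:.4f} (~{r:.2f})")

query = PowerQuery(target_r=round(r, 2), power=0.80, alpha=0.05, sides=2)
n = required_n_correlation(query)
print(f"required N for 80% power (two-sided alpha = 5%): {n}")
print(f"power at N=107 (an exploratory-study scale): {correlation_power(107, query.target_r):.3f}")
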