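"""Creatinine clearance for unstable renal function.

Estimates CRCL from two serum creatinine values via the mass-balance
equation, with the adjusted daily creatinine production derived from age,
body weight and sex, and shows how the covariate enters elimination.
"""

from quasipk import RenalInput, adjusted_production, effective_K, jelliffe_crcl
from quasipk.covariates import hours_to_days

age, weight, sex = 65.0, 78.0, "M"
c1, c2 = 1.1, 1.4           # serum creatinine rising, mg/dL
interval_h = 24.0           # time between the two samples

p_adj = adjusted_production(age, weight, sex, mean_scr=0.5 * (c1 + c2))
print(f"adjusted creatinine production: {p_adj:.0f} mg/day")

inp = RenalInput(
    body_weight=weight, c1=c1, c2=c2,
    interval_T=hours_to_days(interval_h), p_adj=p_adj,
)
crcl = jelliffe_crcl(inp)  # mL/min
print(f"creatinine clearance: {crcl:.1f} mL/min")

# Steady-state comparison: with the same mean creatinine but no rise, the
# clearance estimate is higher — accumulation signals falling function.
steady = jelliffe_crcl(RenalInput(weight, 1.25, 1.25, inp.interval_T, p_adj))
print(f"steady-state equivalent: {steady:.1f} mL/min")

# The covariate drives elimination linearly: K = KI + KS * CRCL.
k = effective_K(KI=0.05, KS=0.003, crcl=crcl)
print(f"effective elimination rate constant: {k:.3f} 1/h")
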