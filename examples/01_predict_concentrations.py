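"""Closed-form concentration predictions under the study regimen.

Builds the 4 g q6h / 3-h-infusion piperacillin regimen, predicts serum
concentrations at the six post-infusion sampling times with a one- and a
two-compartment model, and prints both curves side by side.
"""

from quasipk import Params1C, Params2C, predict_1c, predict_2c
from quasipk import study_regimen, study_sampling_times

regimen = study_regimen()          # 4 pre-sampling doses + the sampled infusion
times = study_sampling_times()     # 0.25 ... 2.5 h after the infusion ends

one_cmt = Params1C(K=0.4, V=40.0)                      # K 1/h, V litres
two_cmt = Params2C(K=0.8, KCP=1.0, KPC=0.5, Vc=12.0)   # micro-constants 1/h, Vc litres

c1 = predict_1c(one_cmt, regimen, times)
c2 = predict_2c(two_cmt, regimen, times)

print("time (h)  1-cmt (mg/L)  2-cmt (mg/L)")
for t, a, b in zip(times, c1, c2):
    print(f"{t:7.2f}  {a:12.2f}  {b:12.2f}")

# Both models describe washout after the infusion: concentrations fall
# monotonically over the sampling window.  The two-compartment curve starts
# higher (smaller central volume) and falls faster (distribution phase).
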