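"""Fit receptor-kinetics descriptors from simulated whole-cell currents.

Generates noisy current traces with known parameters (GluA1/A2-like
values) and recovers the time constant of desensitization, the recovery
time course via the Hodgkin-Huxley equation, and the steady-state
fraction of non-desensitized receptors.
"""

import amparcore as ac

# desensitization: tau from a 1-s glutamate application
des = ac.make_current_trace("desensitization", {"tau": 7.64}, noise_sd=0.02, seed=7)
fit = ac.fit_exponential_decay(des.trace)
print(f"tau_des    : {fit.tau:6.2f} ms   (generated with 7.64 ms, 2% noise)")

# recovery from desensitization: two-pulse envelope + Hodgkin-Huxley fit
env = ac.make_current_trace(
    "recovery_envelope",
    {"tau_recdes": 75.0, "m": 1.02, "i_max": 30.0},
    noise_sd=0.02,
    seed=7,
)
t, points = ac.build_recovery_envelope(env.traces)
rec = ac.fit_recovery(t, points, normalized_to="conditioning")
print(f"tau_recdes : {rec.tau_recdes:6.1f} ms   (generated with 75 ms)")
print(f"m          : {rec.m:6.2f}      (generated with 1.02)")

# steady-state fraction of non-desensitized receptors
ssp = ac.make_current_trace("steady_state_pair", {"ratio": 0.032}, noise_sd=0.01, seed=7)
ratio = ac.steady_state_ratio(ssp.traces[0], ssp.traces[1])
print(f"I_SS/I_max : {ratio.ratio:6.3f}      (generated with 0.032)")
print()
print("tau_des sets how fast the response sags during sustained glutamate;")
print("tau_recdes sets how long the receptor stays refractory; m indexes the")
print("number of rate-determining transitions on the recovery pathway.")
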