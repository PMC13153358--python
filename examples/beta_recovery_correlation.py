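"""Correlate LBD-dimer asymmetry (β) with recovery kinetics (τ_RecDes).

Simulates a panel of receptor complexes whose desensitized-state dimers
carry increasing asymmetry, assigns each a recovery time constant lying on
a noisy line in β, measures β back from the structures, and reports the
Pearson correlation — the cross-complex analysis that links symmetry
breaking to slow recovery from desensitization.
"""

import numpy as np

import amparcore as ac

rng = np.random.default_rng(5)
records = []
for k, dev in enumerate(np.linspace(0.0, 14.0, 8)):
    fx = ac.make_c2_dimer(25, float(dev), "parallel", seed=200 + k)
    tau = max(60.0 * fx.beta_oracle + 30.0 + rng.normal(0, 60.0), 1.0)
    records.append(
        ac.ComplexRecord(f"complex-{k}", tau_recdes=tau, structure=fx.model)
    )

table = ac.build_complex_table(records)
corr = ac.correlate_beta_recovery(table)

print(table[["complex", "beta_deg", "tau_recdes_ms", "beta_provenance"]]
      .round(1).to_string(index=False))
print()
print(f"Pearson r = {corr.r:.3f}  (n = {corr.n}, p = {corr.p_value:.2g})")
print(f"fitted line: tau_recdes = {corr.slope:.1f} * beta + {corr.intercept:.1f}")
print()
print("A strong positive r means complexes whose LBD dimers lose two-fold")
print("symmetry most severely are also the slowest to recover from")
print("desensitization.")
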