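"""Transcription-factor activities by network component analysis.

Builds a small identifiable TF→gene topology, generates expression data
E = A·P + noise with one TF's activity genuinely shifted between conditions,
recovers the hidden activities by support-constrained alternating least
squares, and tests each TF's activity change by bootstrap.
"""

import numpy as np
import pandas as pd

from acidstress import nca, synth

topology = synth.demo_topology()
print(f"topology: {len(topology.tfs)} TFs, {len(topology.genes)} genes, "
      f"{len(topology.edges)} signed edges")
report = nca.check_identifiability(topology, n_conditions=6)
print(f"identifiable: {report.passed}")

rng = np.random.default_rng(7)
# non-responding TFs keep the same true activity in both conditions
base = rng.normal(0.0, 1.0, size=len(topology.tfs))
true_p = pd.DataFrame(
    {"control": base, "treated": base.copy()}, index=topology.tfs
)
true_p.loc["TF1", "treated"] += 3.0  # the responding regulator

study, truth = synth.gen_expression(topology, true_p, noise_sd=0.05,
                                    n_replicates=3, seed=7)
result = nca.nca_decompose(study.matrix, topology, seed=7)
print(f"ALS converged: {result.converged}, "
      f"final relative residual {result.residuals[-1]:.2e}")

changes = nca.delta_tfa(result.P, study.conditions.loc[result.P.columns],
                        n_boot=1000, seed=7)
print(f"\n{'TF':<5} {'dTFA':>8} {'dir':>4} {'p':>8}  significant")
for c in changes:
    print(f"{c.tf:<5} {c.delta:>8.3f} {c.direction:>4} {c.p:>8.4f}  {c.significant}")

print(
    "\nReading: only the TF whose activity was actually shifted between "
    "conditions is flagged (p < 0.05); activity magnitudes are in the "
    "gauge where each TF's strongest regulatory weight is +1."
)
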