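"""Validate the triallelic-singleton estimator against simulation truth.

Runs one desk-scale estimator-validation scenario: simulates a genealogy,
counts triallelic singletons and doubletons, estimates the recurrent
proportion with its multinomial-bootstrap 95% CI, and compares against the
exact recurrent count extracted from the recorded mutation events.
"""

import doubrcr as d
import doubrcr.coalescent_validation as cv

cfg = d.ESTIMATOR_SCENARIOS["panmictic_constant"]
rep = cv.validate_estimator(cfg, seed=7, bootstrap_reps=1500)

print(f"scenario: {rep['scenario']} "
      f"({cfg.n_samples} diploids, {cfg.genome_length/1e6:.1f} Mb)")
print(f"doubletons observed:            {rep['n_doubletons']:,}")
print(f"estimated recurrent proportion: {rep['estimated_recurrent_proportion']:.4f}")
print(f"bootstrap 95% CI:               ({rep['ci_low']:.4f}, {rep['ci_high']:.4f})")
print(f"true recurrent proportion:      {rep['true_recurrent_proportion']:.4f}")
print(f"truth inside the CI:            {rep['covered']}")
print("\nReading: the estimator sees only the genotype matrix; the truth"
      "\ncomes from the simulator's recorded mutation events. Agreement"
      "\nvalidates using triallelic singleton rates to quantify recurrence.")
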