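"""Generate a paired train/test cohort with ground truth.

The generator emulates the structure of paired immunotherapy trial
cohorts: NB counts, ~23% responders, a minority of response-informative
genes, a subset of genes whose distribution shifts between cohorts (and
whose association does not transfer), and expression-linked survival.
"""
import numpy as np

from logitda import SimulationConfig, simulate_cohorts

cfg = SimulationConfig(
    n_genes=1000, n_train=150, n_test=80,
    n_informative=30, n_shifted=20, frac_informative_shifted=0.5,
    n_survival_genes=3, seed=42,
)
sim = simulate_cohorts(cfg)

print(f"train: {sim.train_counts.n_genes} genes x {sim.train_counts.n_samples} samples")
print(f"test:  {sim.test_counts.n_genes} genes x {sim.test_counts.n_samples} samples")
print(f"train responder fraction: {sim.train_clinical.response.mean():.3f} "
      f"(configured prevalence {cfg.prevalence})")
print(f"informative genes: {len(sim.truth.informative_genes)} "
      f"(log2 effect sizes {min(sim.truth.informative_genes.values()):+.2f} "
      f"to {max(sim.truth.informative_genes.values()):+.2f})")
print(f"domain-shifted (non-transferable) genes: {len(sim.truth.shifted_genes)}")
print(f"survival-linked genes: {sorted(sim.truth.survival_genes)}")
print(f"censoring fraction: {1 - sim.train_clinical.table['os_event'].mean():.2f}")
# The responder fraction fluctuates binomially around the prevalence; the
# truth record is what every downstream benchmark is scored against.
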