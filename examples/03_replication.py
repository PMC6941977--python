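"""Replicate discovery pQTMs in an independent (multi-ethnic) cohort.

The replication cohort redraws samples with the same planted effects and
adds genetic/proteomic PC covariates.  A discovery pair replicates when its
replication p-value passes 0.05/N (N = discovery count at that step); power
is estimated by sampling the discovery effect and propagating it through a
noncentral-t tail at the replication sample size.
"""

from pewas import SimulationConfig, simulate_cohort
from pewas.pipeline import preprocess_bundle
from pewas.replication import add_power_flags, directionality_consistency, replicate_step
from pewas.stepwise import bonferroni_threshold, ewas_scan

config = SimulationConfig(n_samples=500, n_cpgs=400, n_proteins=40, seed=19)
discovery = preprocess_bundle(simulate_cohort(config, "discovery"))
replication = preprocess_bundle(simulate_cohort(config, "replication"))

threshold = bonferroni_threshold(0.05, [400, 40])
disc_scan = ewas_scan(discovery.meth, discovery.prot, threshold)
rep_scan = ewas_scan(replication.meth, replication.prot, threshold)

result = replicate_step(disc_scan.records, rep_scan)
table = add_power_flags(result, 500, replication.meth.n_samples, disc_scan.records, seed=1)

print(f"discovery pairs: {result.n_discovery}; replication threshold 0.05/N = {result.threshold:.3g}")
print(f"replicated: {int(table['replicated'].sum())}; "
      f"sign-consistent among replicated: {int((table['replicated'] & table['sign_consistent']).sum())}")
print(f"directionality consistency (nominal p<0.05): {directionality_consistency(result):.2f}")
print(f"pairs with >=95% replication power: {int(table['powered_95'].sum())}")
# Sign-consistent replication at the per-step Bonferroni level is the
# criterion for a pQTM to enter the final catalog.
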