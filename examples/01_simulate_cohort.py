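"""Generate a synthetic two-group cohort with a planted connectivity deficit.

Builds a 22-vs-22 cohort of 68-node ROI time series (150 frames, TR = 2 s)
where seven edges of the patient group's latent correlation network are
attenuated by 80%, and prints what was planted. The printed edges are the
ground truth every downstream example tries to recover.
"""

from attnet import CohortSpec, generate_cohort

spec = CohortSpec(effect_size=0.8, seed=7)
series, design, truth = generate_cohort(spec)

print(f"subjects: {len(series)} ({spec.n_per_group} per group)")
print(f"nodes x frames: {series[0].n_nodes} x {series[0].n_frames}, TR {spec.tr_seconds}s")
print(f"planted edges (latent correlation x{1 - spec.effect_size:.1f} in patients):")
for i, j in truth.planted_edges:
    print(f"  {series[0].node_ids[i]} -- {series[0].node_ids[j]}"
          f"  (control rho = {truth.covariance_control[i, j]:.2f},"
          f" patient rho = {truth.covariance_patient[i, j]:.2f})")
print(design.table.groupby("group")[["age", "iq", "dsm_total"]].mean().round(1))
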