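"""Run the automatic dose-volume plan on the built-in prostate-like phantom.

Builds the default 64x64 phantom (central PTV, crescent rectum, anterior
bladder, normal-tissue ring), computes the dose-influence matrix for five
coplanar beams, and lets the automatic loop tune the importance factors.
"""

import autofmo as af

phantom = af.generate_phantom(af.default_prostate_spec())
A = af.compute_influence_matrix(phantom, af.default_beam_spec())
prescription = af.default_prostate_prescription()

result = af.run_automatic(phantom, A, prescription, model="dv")
dose = result.plan.dose

print(f"acceptable plan: {result.acceptable}")
print(f"inner FMO solves used: {result.history.n_solves} (budget 5*(1+10)=55)")
print(f"PTV V(74 Gy) = {result.evaluation.ptv_coverage_pct:.1f}%  (must reach 95%)")
for c in result.evaluation.criteria:
    print(
        f"  {c['structure']:8s} V{c['dose_gy']:.0f} = {c['value_pct']:5.1f}% "
        f"(guideline < {c['volume_pct']:.0f}%)"
    )
ci = af.conformity_index(dose, phantom.masks["ptv"], phantom.body_mask, 74.0)
hi = af.homogeneity_index(dose, phantom.masks["ptv"])
print(f"conformity index CI = {ci:.2f} (1 = reference isodose matches the PTV)")
print(f"homogeneity index HI = {hi:.3f} (1 = perfectly uniform PTV dose)")
print("final importance factors:", ", ".join(f"{w:.3f}" for w in result.weights))
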