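"""Watch the compensation stage engage on an unachievable criterion.

An extra evaluation rule demands that almost no rectum voxel receives even
1 Gy — impossible with beams that must traverse it.  The loop escalates the
compensation coefficient k on an arithmetic schedule (k0=1, step 1 for the
dose-volume model) until the budget N_max=10 is exhausted, then returns the
best plan found, flagged unacceptable.
"""

import autofmo as af

phantom = af.generate_phantom(af.default_prostate_spec())
A = af.compute_influence_matrix(phantom, af.default_beam_spec())
pres = af.default_prostate_prescription()
pres = pres.model_copy(
    update={
        "evaluation_criteria": pres.evaluation_criteria
        + [af.EvaluationCriterion(structure="rectum", dose_gy=1.0, volume_pct=0.5)]
    }
)

result = af.run_automatic(phantom, A, pres, model="dv")
print(f"acceptable: {result.acceptable} (expected False: criterion is unachievable)")
print(f"final compensation coefficient k = {result.k_final:g} (= k0 + 9*steplength)")
print(f"FMO solves used: {result.history.n_solves} = 5 adjustment iters x (1 + 10 comp iters)")
ks = sorted({rec["k"] for rec in result.history.records})
print("k values visited:", ks)
print(
    "\nThe returned plan is still the best one evaluated; its PTV coverage is "
    f"{result.evaluation.ptv_coverage_pct:.1f}%."
)
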