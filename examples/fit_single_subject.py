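"""Fit one synthetic subject with the four-stage hierarchical pipeline.

Generates a subject with known ground truth, runs homogenized ->
regional -> initial-condition -> connectivity fitting with homotopy
regularization, and prints held-out accuracy plus recovered global scalars.
Takes a minute or two.
"""

from adbc import FitConfig, fit_subject, score_recovery
from adbc.synthetic import CohortSpec, generate_cohort

spec = CohortSpec(n_subjects=1, n_regions=8, seed=7, missing_fraction={})
pop, (subject,) = generate_cohort(spec)
print(f"subject with {len({r.age for r in subject.records})} visit ages, "
      f"{len(subject.records)} observations")

config = FitConfig(seed=7)
result = fit_subject(subject.records, pop, config, stages=(1, 2, 3, 4))

print("\nheld-out accuracy per biomarker (%):",
      {k: round(v, 1) for k, v in result.test_accuracy.items()})
print("homogeneous-stage held-out accuracy:",
      round(result.stage_accuracies["H"].get("overall", float("nan")), 1))

sc = score_recovery(result, subject)
print("\nglobal scalar    truth    fitted   rel.err")
for nm, err in sc["global_rel_err"].items():
    print(f"{nm:<15} {getattr(subject.params, nm):7.3f}  "
          f"{getattr(result.params, nm):7.3f}   {100 * err:6.1f}%")
print()
print("Accuracy is 100*(1 - relative L2 error) pooled over held-out visits.")
print("Capacities anchor well (the end-stage penalty and the data plateau agree),")
print("but the diffusivities and cascade couplings are weakly identified from a")
print("handful of visits -- their loss profiles are nearly flat or degenerate --")
print("so good trajectory accuracy does not imply point recovery of every scalar.")
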