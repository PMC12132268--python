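"""How much is an extra MRI worth?  The imaging-frequency study, reduced.

Calibrates the digital twin under daily, weekly and fortnightly imaging of
the same virtual patient, then pushes prior and posterior samples through a
prediction window and compares the distributions of two clinical quantities
of interest: the relative error in measurable tumor volume and the
concordance correlation coefficient against the ground truth.  More frequent
imaging yields larger Hessian eigenvalues (more informed directions) and
tighter, more accurate predictive distributions; every calibrated posterior
beats the uncalibrated prior at p < 0.001 (Mann-Whitney location,
Levene spread).

Reduced scale (~3 min). The full-scale run is scripts/acceptance.py.
"""

from gliomatwin.pipeline import RunConfig, run_imaging_frequency_study

config = RunConfig(
    seed=1, n_samples=40, eig_rank=15, eig_oversampling=8,
    grad_rtol=1e-4, max_newton=30,
    spec_overrides=dict(
        radius_mm=45.0, h_fine_mm=3.0, h_coarse_mm=4.5, voxel_mm=4.0,
        pre_days=14, therapy_days=21, post_days=14, prediction_days=14,
    ),
)
results = run_imaging_frequency_study(config)

print(f"{'schedule':>12} {'eig_1':>10} {'relTV prior':>12} {'relTV post':>11} "
      f"{'CCC post':>9} {'MW p(TV)':>10} {'MW p(CCC)':>10}")
for imaging, r in results.items():
    pred = r["prediction"]
    print(f"{imaging:>12} {r['eigenvalues'][0]:>10.2e} "
          f"{pred['prior'].rel_error_volume.mean():>+12.3f} "
          f"{pred['posterior'].rel_error_volume.mean():>+11.3f} "
          f"{pred['posterior'].ccc.mean():>9.3f} "
          f"{pred['tests']['rel_error_volume']['mannwhitney_p']:>10.1e} "
          f"{pred['tests']['ccc']['mannwhitney_p']:>10.1e}")
print("eig_1 grows with imaging frequency: more data, more information;"
      " posterior volume errors shrink toward zero while the prior overgrows")
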