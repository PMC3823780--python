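"""Effect of the dose-calculation grid size on spiral-plane pass rates.

For seeded VMAT-like plans, the analytic dose on the spiral surface is
the reference and the calculation is the same field sampled onto 3D
grids at 2 mm and 1 mm and resampled back.  The finer grid tracks the
truth more closely; the paired pass rates are compared with the exact
Wilcoxon signed-rank test.
"""

from spiralfilm import run_grid_size_experiment

report = run_grid_size_experiment(
    {"n_plans": 3, "seed": 7, "spacings_cm": (0.2, 0.1), "pitch_mm": 1.5,
     "n_beams": 24}
)

for plan in report["plans"]:
    print(f"plan {plan['plan']}: pass 2 mm {plan['pass_rate_2mm']:6.2f}%  "
          f"1 mm {plan['pass_rate_1mm']:6.2f}%   "
          f"max deviation from truth 2 mm {plan['max_dev_cGy_2mm']:.2f} cGy, "
          f"1 mm {plan['max_dev_cGy_1mm']:.2f} cGy")

comp = report["comparison_coarse_vs_fine"]
print(f"\nmean pass rate: 2 mm {comp['condition_a']['mean']:.2f}%  "
      f"1 mm {comp['condition_b']['mean']:.2f}%")
print(f"exact Wilcoxon p = {comp['p_value']:.4g} "
      f"({'significant' if comp['significant'] else 'not significant'} at 5%)")
print("Under 3 mm/3% both grids verify the smooth synthetic fields; the "
      "1 mm grid's smaller deviation from the analytic truth shows the "
      "grid-size effect directly.")
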