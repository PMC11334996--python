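"""A full simulated same/different viewpoint-discrimination experiment.

Generates the 13-object regular suite, simulates 50 observers whose
P("different") follows a Weibull function of the model dissimilarity,
applies the reaction-time and performance exclusions, and then asks the
headline questions: is discrimination better around cardinal axes, and
does the flow-curve gradient difference predict the per-object size of
that advantage?
"""

import numpy as np

from viewflow import (
    apply_exclusions,
    cardinal_axis_effects,
    curve_gradient,
    flow_curve,
    paired_t_cohens_d,
    psychometric_table,
    simple_regression,
)
from viewflow.synthetic import (
    design_from_curve,
    familiar_like_suite,
    simulate_discrimination,
)

suite = familiar_like_suite(n_objects=13, master_seed=2026)
curves = {label: flow_curve(mesh) for label, mesh in suite}
designs = {o: design_from_curve(c) for o, c in curves.items()}

trials = simulate_discrimination(curves, designs=designs,
                                 n_participants=50, seed=2026)
kept, report = apply_exclusions(trials)
print(f"simulated {report.n_input} trials; "
      f"{report.n_rt_excluded} excluded by reaction time "
      f"({100 * (1 - report.n_retained / report.n_input):.2f}% lost)")

table = psychometric_table(kept)
pooled = kept.assign(rotation_level=kept.rotation_level.abs())
by_level = pooled.groupby("rotation_level")["response"].apply(
    lambda r: (r == "different").mean()
)
print("group P('different') by |rotation|:",
      {int(k): round(v, 3) for k, v in by_level.items()})

effects = cardinal_axis_effects(table).set_index("object")["effect"]
print(f"cardinal axis effect: mean {effects.mean():+.4f} per degree, "
      f"positive for {(effects > 0).sum()}/{len(effects)} objects")

grad_diff = {}
for obj, curve in curves.items():
    g = {"cardinal": [], "non-cardinal": []}
    for _, (idx, axis) in designs[obj].items():
        g[axis].append(abs(curve_gradient(curve, idx)))
    grad_diff[obj] = np.mean(g["non-cardinal"]) - np.mean(g["cardinal"])

reg = simple_regression([grad_diff[o] for o in effects.index], effects)
print(f"gradient difference -> effect regression: "
      f"F(1,{len(effects) - 2}) = {reg.stat.value:.2f}, p = {reg.stat.p:.2g}, "
      f"R^2 = {reg.r_squared:.2f}")
print("objects whose non-cardinal views sit on steeper curve regions show "
      "a larger cardinal discrimination advantage.")
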