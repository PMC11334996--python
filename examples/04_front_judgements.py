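"""Simulated "which view is the front?" judgements on novel objects.

Generates 10 irregular novel objects, simulates 50 observers whose front
choices concentrate where the flow curve is locally flat, summarizes the
angular responses with circular statistics, and tests whether chosen
fronts sit on flatter curve regions than never-chosen views.
"""

from viewflow import flow_curve, front_vs_nonfront_gradient
from viewflow.front_judgements import summarize
from viewflow.synthetic import novel_like_suite, simulate_front_responses

suite = novel_like_suite(n_objects=10, master_seed=2026)
curves = {label: flow_curve(mesh) for label, mesh in suite}

responses = simulate_front_responses(curves, n_participants=50, seed=2026)
summaries = summarize(responses)
print("per-object circular summaries of chosen 'front' angles:")
for _, row in summaries.iterrows():
    print(f"  {row.object}: mode {row.circular_mode:5.0f}°, "
          f"concentration R-bar = {row.mean_resultant_length:.2f} "
          f"(n = {row.n})")

per_object, stat = front_vs_nonfront_gradient(responses, curves)
lower = (per_object.front_mean_abs_gradient
         < per_object.nonfront_mean_abs_gradient).sum()
print(f"\nchosen fronts have lower mean |gradient| for "
      f"{lower}/{len(per_object)} objects")
print(f"paired Wilcoxon across objects: W = {stat.value:.0f}, "
      f"p = {stat.p:.4g}, effect size r = {stat.effect_size:.2f}")
print("front responses cluster at the peaks and troughs of the flow "
      "curve, where the gradient magnitude is small.")
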