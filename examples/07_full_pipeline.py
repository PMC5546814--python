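"""Run the whole analysis over a synthetic preparation in one call.

run_pipeline chains every stage -- rates, embedding, recurrence, attractor
estimation, manifold comparisons, decoding, participation -- over the three
programs of a preparation, isolating per-stage failures, and returns a
JSON-serialisable report.

(A reduced preparation is used here so the example runs in ~1 minute; the
acceptance script runs the full-size conditions.)
"""

import json

from spiralscope import make_synthetic_preparation, run_pipeline
from spiralscope.config import synthetic_run_config

bundle = make_synthetic_preparation(seed=1, n_neurons=80, post_s=70.0,
                                    with_nerve=False)
cfg = synthetic_run_config()
cfg.shuffles = 25
cfg.drift.n_perm = 1000
cfg.seed = 1

report, results = run_pipeline(bundle, cfg, out_dir="scratch_report")

for prog in report["programs"]:
    att = prog.get("attractor", {})
    print(f"program {prog['index']}: d={prog['embedding_dims']}, "
          f"period {prog['period_s']:.2f} s, "
          f"coalescence {prog['coalescence_s']:.1f} s, "
          f"{att.get('classification', 'n/a')}")
for comp in report["cross"]["comparisons"]:
    print(f"pair {comp['pair']}: Hausdorff {comp['hausdorff']:.1f} vs "
          f"shuffle control {comp['control_mean']:.1f} "
          f"(normalized {comp['normalized']:.2f})")
part = report["participation"]
print(f"strongly variable neurons: {len(part['strongly_variable'])}")
print(f"failures: {len(report['failures'])}")
print()
print("normalized < 1 for every pair: repeated programs land on the same")
print("manifold, closer than shuffled projections -- the attractor signature.")
print("full report written to scratch_report/report.json")
print("keys:", ", ".join(sorted(report.keys())))
print("provenance:", json.dumps(report["provenance"]))
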