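"""Operating characteristics of borrowing designs across scenarios.

Runs a reduced-replication simulation of the five benchmark scenarios
for the independent conjugate analysis and the calibrated power prior,
calibrating each design's posterior-probability threshold to a 5% type I
error under the global null, and prints rejection %, MSE and prior ESS
grouped by whether an arm is truly null ("N") or alternative ("A").
"""

from basketess import (
    IndependentDesign,
    PowerPriorDesign,
    StudySpec,
    builtin_scenarios,
    run_operating_characteristics,
    summarize_by_truth,
)

spec = StudySpec(
    scenarios=builtin_scenarios(),
    designs=[IndependentDesign(), PowerPriorDesign()],
    reps=400,
    seed=3,
    phi="calibrate",
)
results = run_operating_characteristics(spec)
table = summarize_by_truth(results)
print(table.to_string(index=False,
                      float_format=lambda v: f"{v:.3g}"))

print("\nReject % on 'A' rows is power, on 'N' rows type I error. "
      "The power prior buys power in homogeneous scenarios (Scenario 2) "
      "at the cost of inflated type I error for null arms sitting next "
      "to effective ones (Scenarios 3-5); its prior ESS quantifies that "
      "trade in patients.")
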