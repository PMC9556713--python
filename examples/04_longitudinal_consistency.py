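"""Track symptom clusters across repeated assessments.

A longitudinal design samples the same patients at three correlated time
points; each time point is analysed independently, communities are named by
overlap with anchor symptom sets, and the consistency table reports what
fraction of each named cluster's members recur per time point.
"""

import symptomnet as sn
from symptomnet.synthetic import LongitudinalDesign

model = sn.make_planted_model(
    9, 3, 1.5, 0.0, (-3.0, -1.0), seed=5,
    node_labels=["Worry", "Sad", "Nervous",
                 "Sob", "Difbreath", "Chest",
                 "Nausea", "Vomit", "Appetite"])
design = LongitudinalDesign(["T1", "T2", "T3"], [model] * 3,
                            carryover=0.5, missingness_rate=0.02)
mats, _ = sn.generate_longitudinal(design, n=1200, seed=6)

complete, report = sn.complete_case_filter(mats)
print(f"complete cases: {report.retained} of {report.retained + report.dropped} "
      "patients observed at all three time points")

anchors = {"psychological": {"Worry", "Sad", "Nervous"},
           "respiratory": {"Sob", "Difbreath", "Chest"},
           "gastrointestinal": {"Nausea", "Vomit", "Appetite"}}
parts = {}
for X in complete:
    net = sn.estimate_network(X)
    parts[X.time_point] = sn.walktrap(net)
names = sn.match_and_name_clusters(parts, anchors)
table = sn.consistency_table(parts, names)
print("\ncluster consistency (% of the cluster's across-time union present):")
print(table)
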