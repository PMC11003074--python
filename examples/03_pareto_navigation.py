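"""Calibrate a protocol by navigating a two-dimensional Pareto dataset.

Generates a grid of plans over two trade-off dimensions (rectum mean-dose
weighting factor x external fall-off weighting factor), explores positions in
parameter space by multilinear dose interpolation — no re-optimisation — and
commits a navigated position back into the protocol as its calibration.
"""

import paretoplan as pp
from paretoplan.metrics import MetricSpec
from paretoplan.pareto import NavigationDimension

geo = pp.build_ptvs(pp.generate_patient(seed=1, grid_shape=(32, 32, 32)))
protocol = pp.load_builtin_protocol("instA")

dims = [
    NavigationDimension("rectum", "mean_dose", "weighting_factor",
                        (0.584, 5.84, 58.4)),
    NavigationDimension("external", "dose_falloff_external", "weighting_factor",
                        (102.0, 204.0, 408.0)),
]
dataset = pp.generate_dataset(geo, protocol, dims,
                              pp.BeamConfig(n_beams=8),
                              pp.PBAIOConfig(inner_iterations=15, outer_loops=2))
print(f"dataset: {len(dataset.plans)} plans over dimensions {dataset.labels}")

specs = [MetricSpec("Dmean", "rectum"), MetricSpec("HI", "PTV60"),
         MetricSpec("CI", "PTV48", reference_dose=45.6)]
for rect_wf in (0.584, 5.84, 20.0, 58.4):
    pos = {dataset.labels[0]: rect_wf, dataset.labels[1]: 204.0}
    vals = pp.navigate_metrics(dataset, pos, specs)
    print(f"rectum WF {rect_wf:6.2f}: " +
          ", ".join(f"{k} = {v:.3f}" for k, v in vals.items()))

# sliding the rectum weight up spares the rectum at the cost of homogeneity
# and conformality; commit the preferred balance into the protocol
chosen = {dataset.labels[0]: 20.0, dataset.labels[1]: 204.0}
calibrated = pp.commit_calibration(dataset, chosen, protocol)
print("committed rectum Dmean WF:",
      calibrated.find_goal("rectum", "mean_dose").weighting_factor)
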