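"""Dorsal-collapse sweep: image error of the three solvers.

Simulates 25 levels of dorsal atelectasis (0% to 50% of each lung's
anterior-posterior extent collapsed) and prints the l1 image error of the
masked-DCT, Tikhonov and Laplace reconstructions against the ground truth.
"""

from eitdct.pipeline import StudyConfig, build_suite, run_atelectasis_study

suite = build_suite(StudyConfig())
table = run_atelectasis_study(suite=suite, n_levels=25, max_fraction=0.5)
wide = table.pivot(index="atelectasis_fraction", columns="method",
                   values="l1_error").round(1)
print(wide.to_string())
best = (wide["dct"] < wide[["laplace", "tikhonov"]].min(axis=1)).all()
print(f"\nDCT error lowest at every collapse level: {best}")
print("Lower l1 = reconstruction closer to the simulated ground truth; the")
print("shape-constrained basis wins because it cannot blur conductivity")
print("change into non-lung tissue.")
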