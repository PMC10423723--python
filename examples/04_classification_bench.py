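"""Nested cross-validated classification of a small synthetic cohort.

Simulates 6 controls + 8 patients, extracts features and runs the
leave-one-out bench with the kNN classifier on each feature group.
(The full four-classifier bench on a 35-participant cohort is the same
call with default arguments; the RBF-SVM and random-forest grids take
substantially longer.)
"""

import numpy as np

import stereovr as sv
from stereovr.classify import run_bench
from stereovr.pipeline import extract_cohort_features

cohort = sv.simulate_cohort(n_control=6, n_postcovid=8, seed=4)
vecs, labels = extract_cohort_features(cohort)
names = list(next(iter(vecs.values())).values)
X = np.array([vecs[p.id].as_array(names) for p in cohort])
y = np.array([p.label for p in cohort], dtype=object)
tags = {n: vecs[cohort[0].id].groups[n] for n in names}

report = run_bench(X, y, names, tags, groups=["stereo", "pupil", "gaze", "all"],
                   classifiers=["knn"], seed=0)
print(f"{len(y)} participants; LOOCV accuracy step = "
      f"{report['accuracy_granularity_pct']:.1f} % per participant\n")
for key, cell in report["cells"].items():
    print(f"{key:12s} accuracy {cell['accuracy']:.2f}  confusion {cell['confusion']} "
          f"(rows true control/postcovid)")
print("\ntop-5 features by leave-one-out forest importance:")
for entry in report["top_features"][:5]:
    print(f"  {entry['name']:32s} [{entry['group']}] {entry['importance']:.4f}")
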