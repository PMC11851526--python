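"""Train the frame-wise AU detector and score held-out subjects.

Landmarks are Procrustes-normalized, flattened to 3-Ns vectors, and fed
to the two-layer fully-connected detector (128 hidden units, 8 logistic
outputs). Per-AU F1 on subjects never seen in training shows how well AU
presence is recoverable from anonymized geometry alone.
"""

import numpy as np

import painmesh as pm
from painmesh.evaluation import f1_precision_recall

config = pm.SimulationConfig(n_subjects=12, segment_seconds=6.0,
                             topology_id="bp4d83", noise_sd=0.005, seed=1)
segments = pm.simulate_dataset(config)
template = pm.make_template("bp4d83", seed=config.seed)

X, Y, _, subjects = pm.collect_frames(segments, template, stride=2)
train = np.isin(subjects, [f"subj_{i:04d}" for i in range(8)])

detector_cfg = pm.AUDetectorConfig(input_size=X.shape[1], max_epochs=40, seed=0)
model = pm.train_au_detector(X[train], Y[train], detector_cfg)

pred = pm.binarize(model.predict_scores(X[~train]))
print("held-out per-AU F1:")
for j, au in enumerate(pm.DETECTION_AU_IDS):
    f1, p, r = f1_precision_recall(Y[~train][:, j], pred[:, j])
    print(f"  AU{au:<3} F1 {f1:.3f}  precision {p:.3f}  recall {r:.3f}")
macro = np.mean([f1_precision_recall(Y[~train][:, j], pred[:, j])[0]
                 for j in range(8)])
print(f"macro-F1 {macro:.3f}")
# Values near 1.0 mean the AU's displacement field is cleanly recoverable
# from normalized landmarks; lower values flag rarer or subtler AUs.
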