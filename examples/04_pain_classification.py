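"""Classify pain vs. non-pain segments from AU time series.

Ground-truth AU presence sequences are cut into fixed-length windows and
fed to the Transformer-encoder classifier and the LSTM baseline. Both are
evaluated on held-out subjects (subject-independent split).
"""

import numpy as np

import painmesh as pm
from painmesh.evaluation import _au_sequences_for

config = pm.SimulationConfig(n_subjects=16, segment_seconds=10.0,
                             topology_id="bp4d83", noise_sd=0.005, seed=3)
segments = pm.simulate_dataset(config)
train_subjects = {f"subj_{i:04d}" for i in range(11)}
train = [s for s in segments if s.sequence.subject_id in train_subjects]
test = [s for s in segments if s.sequence.subject_id not in train_subjects]

T = 150  # 6 s windows at 25 fps
train_windows = pm.window_segments(_au_sequences_for(train, "ground8"), T=T)
test_windows = pm.window_segments(_au_sequences_for(test, "ground8"), T=T)
labels = [w.label for w in test_windows]

transformer_cfg = pm.PainTransformerConfig(
    projection_dim=64, num_heads=4, num_encoder_layers=2, ffn_dim=128,
    mlp_hidden=64, dropout=0.1, learning_rate=1e-3, max_epochs=25, seed=0)
lstm_cfg = pm.PainLSTMConfig(hidden_dim=64, mlp_hidden=64,
                             learning_rate=1e-3, max_epochs=25, seed=0)

for name, cfg in [("transformer", transformer_cfg), ("lstm", lstm_cfg)]:
    model = pm.train_pain_model(train_windows, cfg)
    probs = model.predict_proba(test_windows)
    acc = np.mean((probs >= 0.5).astype(int) == labels)
    print(f"{name}: held-out window accuracy {acc:.3f} "
          f"({len(train_windows)} train / {len(test_windows)} test windows)")
# Accuracy near 1.0 reflects that pain segments carry a distinctive
# sustained activation of the pain AU set (4, 6, 7, 9, 17, 18, 23, 24).
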