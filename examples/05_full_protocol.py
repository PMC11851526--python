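"""The full subject-independent evaluation protocol at desk scale.

Runs 3-fold AU-detection CV and 3-fold pain CV (with the AU detector
re-trained inside each fold so held-out subjects' AU inputs come from a
detector that never saw them — the fully predicted pipeline), then prints
the report tables with the summed confusion matrix.
"""

import painmesh as pm

config = pm.SimulationConfig(n_subjects=12, segment_seconds=8.0,
                             topology_id="bp4d83", noise_sd=0.005, seed=4)
segments = pm.simulate_dataset(config)
template = pm.make_template("bp4d83", seed=config.seed)

au_cfg = pm.AUDetectorConfig(input_size=3 * template.n_points,
                             max_epochs=30, seed=0)
report = pm.run_au_cv(segments, template, k=3, config=au_cfg,
                      frame_stride=2, seed=0)
print(report.render_text())
print()

lstm_cfg = pm.PainLSTMConfig(hidden_dim=32, mlp_hidden=32,
                             learning_rate=1e-3, max_epochs=20, seed=0)
pain_report = pm.run_pain_cv(
    segments, lstm_cfg, k=3, au_source="predicted8", template=template,
    detector_config=au_cfg, window_length=150, frame_stride=1, seed=0)
print(pain_report.render_text())
# The confusion matrix sums over folds; its derived accuracy equals the
# reported aggregate, and each fold's subjects are disjoint from training.
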