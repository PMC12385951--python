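"""Ablation variants and feature export.

Shows how the three published ablations change the architecture's
parameter count, then trains briefly and exports per-segment fused
features suitable for external 2-D projection (e.g. t-SNE).
"""

from rdpnet import (ModelConfig, SynthConfig, TrainConfig, build_model,
                    count_parameters, export_embeddings, generate_dataset,
                    parse_task, segment_record, train_model)
from rdpnet.model import ablation_configs

for name, cfg in ablation_configs(ModelConfig()).items():
    print(f"{name:>12}: {count_parameters(build_model(cfg)):,} parameters")

records = generate_dataset(
    SynthConfig(n_classes=3, records_per_class=8, seed=4))
task = parse_task("A-B-C")
segments = []
for r in records:
    segments.extend(segment_record(r, 512, label=task.class_map[r.set_label]))

model = build_model(
    ModelConfig(rcm_channels=(16, 32), dcpm_channels=32, n_classes=3),
    seed=0)
model, history = train_model(
    model, segments, TrainConfig(max_epochs=3, seed=0))
print(f"selected epoch {history.selected_epoch} "
      f"(train acc {history.accuracy[history.selected_epoch]:.2%})")

features, labels = export_embeddings(model, segments, stage="fused")
print(f"fused embeddings: {features.shape[0]} segments x "
      f"{features.shape[1]} dims, labels {sorted(set(labels.tolist()))}")
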