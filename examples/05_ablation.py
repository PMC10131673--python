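"""Compare multi-view fusion strategies under controlled conditions.

All arms share one cohort, seed and data order, so rows differ only in
the fusion rule (elementwise max, mean, or both concatenated).
"""

import tempfile
from pathlib import Path

from pasivision import ModelConfig, TrainConfig
from pasivision.synth import generate_cohort
from pasivision.train import TABLE_FUSION_GRID, run_ablation

out = Path(tempfile.mkdtemp(prefix="pasi_ablate_"))
manifest_path, _ = generate_cohort(out, n_patients=24, seed=5, image_size=(32, 40))

base = TrainConfig(model=ModelConfig(image_size=(32, 40)), epochs=3, seed=5)
table = run_ablation(manifest_path, TABLE_FUSION_GRID, base, out_path=out / "ablation.csv")
print(table.to_string(index=False))
# Columns: per-subscore classification accuracy (exact-label match) and
# total-PASI mean absolute error per arm; lower MAE is better.
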