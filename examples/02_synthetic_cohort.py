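"""Generate a synthetic visit cohort with exact ground truth.

Every rendering knob maps deterministically to a PASI subscore, so the
manifest's scores are true by construction — no annotation noise.
"""

import tempfile
from pathlib import Path

from pasivision import generate_cohort, severity_band

out = Path(tempfile.mkdtemp(prefix="pasi_cohort_"))
manifest_path, manifest = generate_cohort(
    out, n_patients=25, visits_per_patient=2,
    severity_mix=(0.5, 0.28, 0.22),  # low / medium / high proportions
    seed=42, n_images=3, image_size=(64, 80),
)

visits = manifest.drop_duplicates(["patient_id", "visit_id"])
print(f"manifest: {manifest_path}")
print(f"{len(visits)} visits, {manifest['image_path'].nunique()} images, "
      f"{len(manifest)} manifest rows (one per lesion box)")
bands = visits["pasi"].map(severity_band).value_counts()
print("severity bands:", dict(bands))
print("PASI range: %.1f .. %.1f" % (visits.pasi.min(), visits.pasi.max()))
# Patients' second visits are never more severe than their first — the
# cohort encodes an improvement trend for the pairwise evaluation.
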