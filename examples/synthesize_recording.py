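"""Generate a complete synthetic recording on disk: model, truth, observations.

Writes the skeletal model (YAML), ground-truth angles (MOT), true and
corrupted markers (TRC) for a subject with random body scales; corruption is
5 mm jitter plus a constant 30-50 mm per-marker bias with occasional
occlusion gaps — the error profile of image-based keypoint detectors.
"""

import json
from pathlib import Path

import numpy as np

import skelkin as sk
from skelkin.experiment import ExperimentConfig, _make_sequence

out = Path("scratch/example_recording")
out.mkdir(parents=True, exist_ok=True)

model = sk.make_default_model()
cfg = ExperimentConfig(noise=sk.NoiseSpec(occlusion_rate=0.05, occlusion_window=8))
seq = _make_sequence(model, cfg, np.random.SeedSequence([42, 3, 0]))

sk.write_model(model, out / "model.yaml")
sk.write_mot(seq.motion, out / "gt.mot")
sk.write_trc(seq.true_markers, out / "gt.trc")
sk.write_trc(seq.observed, out / "observed.trc")
(out / "scales.json").write_text(json.dumps(seq.scales.to_mapping(), indent=2))

occluded = seq.observed.missing.mean()
bias = np.linalg.norm((seq.observed.positions - seq.true_markers.positions).mean(axis=0), axis=-1)
print(f"wrote {out}/: {seq.motion.n_frames} frames, {len(model.markers)} markers")
print(f"occluded fraction {occluded:.3f}; per-marker bias norms "
      f"{bias.min()*1e3:.0f}-{bias.max()*1e3:.0f} mm (spec: 30-50 mm + jitter)")
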