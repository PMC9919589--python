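"""Assemble an unpaired two-domain training dataset from degraded images.

Generates 10 synthetic degraded frames, sweeps Dyn per image, writes the
originals (domain A) and the best enhancements (domain B) with a seeded
80/20 split, and prints the per-Dyn report table.
"""

import tempfile
from pathlib import Path

from seepvision import build_dataset, dyn_report, make_fixture_set

fixtures = make_fixture_set(10, seed=5, conditions=5, size=(64, 64))
degraded = [d for _, d in fixtures["pairs"]]

with tempfile.TemporaryDirectory() as tmp:
    manifest = build_dataset(
        degraded, grid=[0.8, 1.6, 2.4, 3.2], split_fraction=0.8, seed=5,
        out_dir=Path(tmp) / "dataset",
    )
    print(f"domain A (originals)     : {len(manifest.domain_a)} images")
    print(f"domain B (best-enhanced) : {len(manifest.domain_b)} images")
    print(f"train/val per domain     : {len(manifest.train_a)}/{len(manifest.val_a)}")
    print(f"selected Dyn per image   : "
          + ", ".join(f"{e['best_dyn']:g}" for e in manifest.domain_b))

report = dyn_report(degraded, grid=[0.8, 1.6, 2.4, 3.2])
print()
print(report.to_frame().to_string(index=False))
print()
print("The 'best value chosen' row averages each image's own maximum, so its")
print("mean dominates every fixed-Dyn row — the gain of per-image selection.")
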