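"""Visualize the phantom generator and the weak-label corruption operator.

Writes ground-truth and corrupted label maps as indexed PNGs (with the
package's inspection palette) into ./corruption_demo/ and prints how much
each corruption parameter hurts each class.
"""

from pathlib import Path

from labelrefine import CorruptionSpec, corrupt_labels, generate_phantom
from labelrefine.io import save_sample
from labelrefine.metrics import class_overlap

out = Path("corruption_demo")
truth = generate_phantom(seed=7, height=96, width=96)
save_sample(truth, out)

settings = {
    "identity": CorruptionSpec(0.0, 0, 0, seed=1),
    "muscle_half_missing": CorruptionSpec(0.5, 0, 0, seed=1),
    "sat_band_3px": CorruptionSpec(0.0, 3, 0, seed=1),
    "standard": CorruptionSpec(0.5, 3, 0, seed=1),
}

print(f"{'corruption':22s} {'muscle':>8s} {'SAT':>8s} {'VAT':>8s}   (DSC vs truth)")
for name, spec in settings.items():
    weak = corrupt_labels(truth, spec)
    save_sample(weak.with_labels(weak.labels, sample_id=f"{truth.sample_id}-{name}"), out)
    dscs = [class_overlap(weak.labels, truth.labels, cls)[1] for cls in (1, 2, 3)]
    print(f"{name:22s} {dscs[0]:8.2f} {dscs[1]:8.2f} {dscs[2]:8.2f}")
print(f"\nlabel maps written to {out}/")
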