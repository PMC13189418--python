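"""Generate a phantom dataset on disk and validate its manifest.

Writes a small balanced dataset (PNG images + masks + CSV manifest) with a
mix of difficulty tiers, then reloads and validates it: per-class counts,
70/15/15 split fractions, and path resolution.
"""

import tempfile

from renalswin.manifest import load_manifest, validate_manifest
from renalswin.phantom import generate_dataset

with tempfile.TemporaryDirectory() as out:
    manifest = generate_dataset(
        n_per_class=10, out_dir=out,
        contrast_mix={"clear": 0.6, "mild": 0.3, "low": 0.1},
        seed=0, image_size=64)
    back = load_manifest(f"{out}/manifest.csv")
    report = validate_manifest(back, check_paths=True, root=out)
    print("per-class counts:", report["per_class"])
    print("split fractions:", {k: round(v, 2)
                               for k, v in report["split_fractions"].items()})
    print("problems:", report["problems"] or "none")
# Expect 10 records per class, fractions {train: 0.7, val: 0.2, test: 0.1}
# rounded per class at n=10, and no problems.
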