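"""Ten-fold rescaling augmentation of the ROI traces.

Each trace is multiplied by every factor 0.5, 1.0, ..., 4.5 and pooled with
the originals: 500 originals + 4500 rescaled copies = 5000 labeled spectra.
"""

import json
from pathlib import Path

from pastage.augment import AugmentPlan, augment_set
from pastage.io import read_spectra_csv, write_spectra_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    roi = read_spectra_csv(ROOT / "scratch" / "02_roi.csv")
    augmented = augment_set(roi, AugmentPlan())
    write_spectra_csv(augmented, ROOT / "scratch" / "03_augmented.csv")

    n_aug = sum(s.provenance == "augmented" for s in augmented)
    summary = {
        "factors": list(AugmentPlan().factors),
        "n_original": len(roi),
        "n_augmented": n_aug,
        "n_total": len(augmented),
    }
    (ROOT / "results" / "03_augment_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"{len(roi)} originals + {n_aug} rescaled copies = {len(augmented)} spectra")


if __name__ == "__main__":
    main()
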