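"""Pre-process every trace and cut the 0.27–0.6 ms region of interest.

Detrend, quadratic baseline correction and max-absolute normalization,
followed by the ROI slice (indices 702..1559 at 2.6 MHz — 858 samples).
"""

import json
from pathlib import Path

from pastage.io import read_spectra_csv, write_spectra_csv
from pastage.preprocess import ROIWindow, preprocess_set, roi_indices

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    spectra = read_spectra_csv(ROOT / "scratch" / "01_spectra.csv")
    roi = ROIWindow()
    processed = preprocess_set(spectra, roi)
    write_spectra_csv(processed, ROOT / "scratch" / "02_roi.csv")

    i0, i1 = roi_indices(roi, spectra[0].sampling_rate)
    summary = {
        "roi_start_ms": roi.start * 1e3,
        "roi_end_ms": roi.end * 1e3,
        "roi_sample_indices": [i0, i1 - 1],
        "roi_length": processed[0].n_samples,
        "n_spectra": len(processed),
    }
    (ROOT / "results" / "02_preprocess_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"pre-processed {len(processed)} traces; ROI samples {i0}..{i1 - 1} ({i1 - i0} points)")


if __name__ == "__main__":
    main()
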