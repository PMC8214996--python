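"""db6 level-2 wavelet-packet decomposition and AA2 feature extraction.

Confirms that essentially all ROI energy falls in the level-2
approximation-of-approximation node (AA2) for every progression group, then
extracts the 215 AA2 coefficients of each of the 5000 spectra as the raw
feature table.
"""

from pathlib import Path

import pandas as pd

from pastage.io import read_spectra_csv, write_feature_table
from pastage.wpd import aa2_fraction, extract_aa2_features

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    roi = read_spectra_csv(ROOT / "scratch" / "02_roi.csv")
    energy = pd.DataFrame(
        {"label": [s.label for s in roi], "aa2_pct": [100 * aa2_fraction(s) for s in roi]}
    )
    by_class = (
        energy.groupby("label", sort=False)["aa2_pct"].agg(["mean", "min"]).round(3)
    )
    by_class.to_csv(ROOT / "results" / "04_aa2_energy_by_class.csv")
    print("AA2 energy fraction per group (% of level-2 energy):")
    print(by_class.to_string())

    augmented = read_spectra_csv(ROOT / "scratch" / "03_augmented.csv")
    table = extract_aa2_features(augmented)
    write_feature_table(table, ROOT / "scratch" / "04_features.csv")
    n_feat = sum(c.startswith("aa2_") for c in table.columns)
    print(f"feature table: {len(table)} spectra x {n_feat} AA2 coefficients")


if __name__ == "__main__":
    main()
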