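"""mRMR ranking of the AA2 coefficients and top-10 feature matrix.

Greedy minimal-redundancy-maximal-relevance selection over the 215
coefficients; the ten selected columns form the 5000 x 10 input matrix for
the SVM stage.
"""

from pathlib import Path

from pastage.io import read_feature_table, write_feature_table, write_ranking_csv
from pastage.mrmr import build_feature_matrix, mrmr_rank

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = read_feature_table(ROOT / "scratch" / "04_features.csv")
    ranking = mrmr_rank(table, k=10)
    write_ranking_csv(ranking, ROOT / "results" / "05_mrmr_ranking.csv")
    matrix = build_feature_matrix(table, ranking, 10)
    write_feature_table(matrix, ROOT / "scratch" / "05_feature_matrix.csv")

    print("top-10 AA2 coefficients by mRMR (coefficient index, criterion score):")
    for rank, (idx, score) in enumerate(zip(ranking.indices, ranking.scores), start=1):
        print(f"  feature {rank:2d}: coefficient {idx:3d}  score {score:+.4f}")
    print(f"feature matrix: {matrix.shape[0]} rows x 10 selected features")


if __name__ == "__main__":
    main()
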