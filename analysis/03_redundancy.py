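"""Fingerprint redundancy: pairwise similarity, duplicate groups, dedup.

Reports the share of accessions identical (100%) and near-identical
(>= 99.9%) to another accession, and writes the deduplicated matrix used by
all downstream population analyses.
"""

import argparse
from pathlib import Path

import pandas as pd

from germscan import io, similarity


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    g = io.read_genotypes(args.results / "filtered_genotypes.tsv", format="matrix-tsv")
    pairs = similarity.pairwise_similarity(g)
    pairs.to_csv(args.results / "similarity_pairs.tsv", sep="\t", index=False)

    groups_100 = similarity.redundancy_groups(pairs, threshold=1.0)
    groups_999 = similarity.redundancy_groups(pairs, threshold=0.999)
    summary = similarity.summarize_redundancy(groups_100, groups_999, g.n_accessions)
    summary.to_csv(args.results / "redundancy_summary.tsv", sep="\t", index=False)

    rows = [
        {"group_id": k, "representative": grp.representative,
         "members": ";".join(grp.members)}
        for k, grp in enumerate(groups_999)
    ]
    pd.DataFrame(rows).to_csv(args.results / "redundancy_groups.tsv", sep="\t", index=False)

    deduped = similarity.deduplicate(g, groups_999)
    io.write_matrix_tsv(deduped, args.results / "deduplicated_genotypes.tsv")
    for row in summary.itertuples():
        print(f"{row.threshold}: {row.n_grouped}/{row.n_total} accessions grouped "
              f"({row.percent}%)")
    print(f"deduplicated: {g.n_accessions} -> {deduped.n_accessions} accessions")


if __name__ == "__main__":
    main()
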