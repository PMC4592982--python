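"""Fst selection scans: wild vs landrace (domestication) and landrace vs
cultivar (modern breeding), with genome-wide thresholds, per-chromosome
summaries and merged candidate regions.
"""

import argparse
from pathlib import Path

import pandas as pd

from germscan import fst, io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--merge-gap-bp", type=int, default=500_000)
    args = ap.parse_args()

    g = io.read_genotypes(args.results / "deduplicated_genotypes.tsv", format="matrix-tsv")
    meta = pd.read_csv(args.fixtures / "accessions.tsv", sep="\t", index_col=0)
    pops = {
        p: [a for a in g.accession_ids if a in meta.index and meta.loc[a, "population"] == p]
        for p in ("wild", "landrace", "cultivar")
    }

    for pa, pb in (("wild", "landrace"), ("landrace", "cultivar")):
        scan = fst.scan(g, pops[pa], pops[pb], labels=(pa, pb), alpha=args.alpha)
        tag = f"{pa}_{pb}"
        table = scan.table.assign(significant=scan.table["fst"] >= scan.threshold)
        table.to_csv(args.results / f"fst_{tag}.tsv", sep="\t", index=False)
        fst.chromosome_summary(scan).to_csv(
            args.results / f"fst_{tag}_by_chromosome.tsv", sep="\t", index=False
        )
        regions = fst.candidate_regions(scan, merge_gap_bp=args.merge_gap_bp)
        pd.DataFrame(
            [
                {"chromosome": r.chromosome, "start_bp": r.start_bp, "end_bp": r.end_bp,
                 "n_loci": len(r.locus_ids), "max_fst": round(r.max_fst, 3)}
                for r in regions
            ]
        ).to_csv(args.results / f"fst_{tag}_regions.tsv", sep="\t", index=False)
        print(f"{pa} vs {pb}: mean Fst {scan.genome_mean:.3f} "
              f"(SD {scan.genome_sd:.3f}), threshold {scan.threshold}; "
              f"{int(table['significant'].sum())} significant loci in "
              f"{len(regions)} candidate regions")


if __name__ == "__main__":
    main()
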