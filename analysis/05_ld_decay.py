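"""Per-population LD: windowed pair statistics, decay curves, half-decay.

Computes r^2 / D' / CI for all same-chromosome pairs within 1 Mb in each
population, bins mean r^2 by distance per region class, and reports the
distance at which LD falls to half of its maximum.
"""

import argparse
from pathlib import Path

import pandas as pd

from germscan import io, ld
from germscan.genotypes import EUCHROMATIC, HETEROCHROMATIC

POPULATIONS = ("wild", "landrace", "cultivar")
BIN_BP = {EUCHROMATIC: 10_000, HETEROCHROMATIC: 50_000}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
    ap.add_argument("--window-bp", type=int, default=1_000_000)
    args = ap.parse_args()

    g = io.read_genotypes(args.results / "deduplicated_genotypes.tsv", format="matrix-tsv")
    g = io.assign_region_class(g, io.read_region_bed(args.fixtures / "regions.bed"))
    meta = pd.read_csv(args.fixtures / "accessions.tsv", sep="\t", index_col=0)

    rows = []
    for pop in POPULATIONS:
        ids = [a for a in g.accession_ids if a in meta.index and meta.loc[a, "population"] == pop]
        sub = io.maf_filter(g.subset_accessions(ids))
        pairs = ld.window_pairs(sub, max_bp=args.window_bp)
        pairs.to_csv(args.results / f"ld_pairs_{pop}.tsv", sep="\t", index=False)
        for klass, bin_bp in BIN_BP.items():
            curve = ld.decay_curve(pairs, bin_bp, region_class=klass)
            curve.to_csv(args.results / f"ld_decay_{pop}_{klass}.tsv", sep="\t", index=False)
            half = ld.half_decay_distance(curve)
            rows.append({"population": pop, "region_class": klass,
                         "n_pairs": int(curve["n_pairs"].sum()),
                         "half_decay_kb": half / 1000})
            print(f"{pop:9s} {klass:15s}: {len(pairs)} pairs, "
                  f"half-decay ~{half / 1000:g} kb")
    pd.DataFrame(rows).to_csv(args.results / "half_decay.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
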