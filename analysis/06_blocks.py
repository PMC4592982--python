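"""Haplotype-block maps per population: detection, summaries, sharing,
gene content and recombination contrast.

Needs the LD pair tables from 05_ld_decay.py.
"""

import argparse
from pathlib import Path

import pandas as pd

from germscan import blocks, io, ld

POPULATIONS = ("wild", "landrace", "cultivar")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
    args = ap.parse_args()

    g = io.read_genotypes(args.results / "deduplicated_genotypes.tsv", format="matrix-tsv")
    regions = io.read_region_bed(args.fixtures / "regions.bed")
    g = io.assign_region_class(g, regions)
    meta = pd.read_csv(args.fixtures / "accessions.tsv", sep="\t", index_col=0)
    genes = io.read_gene_table(args.fixtures / "genes.tsv")
    gmap = io.read_genetic_map(args.fixtures / "genetic_map.tsv")

    maps = {}
    for pop in POPULATIONS:
        ids = [a for a in g.accession_ids if a in meta.index and meta.loc[a, "population"] == pop]
        sub = io.maf_filter(g.subset_accessions(ids))
        pairs = pd.read_csv(args.results / f"ld_pairs_{pop}.tsv", sep="\t")
        bmap = blocks.annotate_haplotypes(
            blocks.find_blocks(pairs, sub.loci, population=pop), sub
        )
        maps[pop] = bmap
        bed = pd.DataFrame(
            [
                {"chrom": b.chromosome, "start": b.start_bp, "end": b.end_bp,
                 "n_snps": b.n_snps, "n_haplotypes": b.n_haplotypes,
                 "region_class": b.region_class}
                for b in bmap.blocks
            ]
        )
        bed.to_csv(args.results / f"blocks_{pop}.tsv", sep="\t", index=False)
        summary = blocks.summarize_blocks(bmap, regions)
        summary["table"].to_csv(args.results / f"block_summary_{pop}.tsv", sep="\t", index=False)
        summary["histogram"].to_csv(
            args.results / f"block_histogram_{pop}.tsv", sep="\t", index=False
        )
        gc = blocks.gene_block_contrast(bmap, genes, regions)
        rc = blocks.recombination_in_blocks(bmap, gmap, regions)
        gc.to_csv(args.results / f"gene_contrast_{pop}.tsv", sep="\t", index=False)
        rc.to_csv(args.results / f"recomb_contrast_{pop}.tsv", sep="\t", index=False)
        genome = summary["table"].query("region_class == 'genome'").iloc[0]
        print(f"{pop:9s}: {genome.n_blocks} blocks, mean {genome.mean_kb} kb, "
              f"{genome.haplotypes_per_block} haplotypes/block; "
              f"in-block recombination ratio "
              f"{rc['ratio'].mean():.2f}")

    share_rows = []
    for a, b in (("wild", "landrace"), ("landrace", "cultivar"), ("wild", "cultivar")):
        res = blocks.block_sharing(maps[a], maps[b])
        share_rows.append({"pop_a": a, "pop_b": b, "concordant": res.concordant,
                           "nonconcordant": res.nonconcordant,
                           "sharing_percent": round(res.sharing_percent, 1)})
        print(f"block sharing {a}-{b}: {res.sharing_percent:.1f}%")
    pd.DataFrame(share_rows).to_csv(args.results / "block_sharing.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
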