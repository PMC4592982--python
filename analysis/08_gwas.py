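"""Case-control GWAS of seed weight: dichotomize (>=20 g case, <=10 g
control), cluster-stratified CMH test, genomic control, significance at
-log10(p) > 3.
"""

import argparse
from pathlib import Path

import pandas as pd

from germscan import gwas, io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
    ap.add_argument("--k", type=int, default=2, help="cluster count for stratification")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--threshold", type=float, default=3.0)
    args = ap.parse_args()

    g = io.read_genotypes(args.results / "deduplicated_genotypes.tsv", format="matrix-tsv")
    trait = io.read_trait_table(args.fixtures / "trait.tsv")
    pheno = gwas.dichotomize(trait)
    phenotyped = set(pheno["accession"])
    sub = g.subset_accessions([a for a in g.accession_ids if a in phenotyped])
    counts = pheno["label"].value_counts()
    print(f"dichotomized: {counts.get('case', 0)} cases, "
          f"{counts.get('control', 0)} controls, "
          f"{counts.get('excluded', 0)} excluded")

    clusters = gwas.assign_clusters(sub, args.k, seed=args.seed)
    clusters.to_csv(args.results / "gwas_clusters.tsv", sep="\t", index=False)
    res = gwas.genome_scan(sub, pheno, clusters)
    res = gwas.call_significant(gwas.genomic_control(res), args.threshold)
    res.to_csv(args.results / "gwas_results.tsv", sep="\t", index=False)
    sig = res[res["significant"]]
    print(f"lambda_gc = {res['lambda_gc'].iloc[0]:.3f}; "
          f"{len(sig)} loci with -log10(p) > {args.threshold:g}")
    if len(sig):
        print(sig[["locus_id", "chromosome", "position", "neg_log10_p"]]
              .sort_values("neg_log10_p", ascending=False).head(10).to_string(index=False))


if __name__ == "__main__":
    main()
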