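"""Locus-level QC: bad-call-rate filter, het masking, MAF filter, region labels.

Reads results/fixtures/, writes the filtered matrix and a QC report.
"""

import argparse
from pathlib import Path

from germscan import io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--max-bad-rate", type=float, default=0.1)
    ap.add_argument("--min-maf", type=float, default=0.05)
    args = ap.parse_args()

    g = io.read_genotypes(args.fixtures / "genotypes.tsv", format="matrix-tsv")
    regions = io.read_region_bed(args.fixtures / "regions.bed")
    filtered, report = io.filter_loci(g, args.max_bad_rate, return_report=True)
    masked = io.apply_het_to_missing(filtered)
    kept = io.maf_filter(masked, args.min_maf)
    kept = io.assign_region_class(kept, regions)

    io.write_matrix_tsv(kept, args.out / "filtered_genotypes.tsv")
    with open(args.out / "qc_report.txt", "w") as fh:
        fh.write(
            f"input loci\t{report.n_input}\n"
            f"removed: het+missing rate > {args.max_bad_rate}\t{report.n_bad_rate}\n"
            f"removed: monomorphic\t{report.n_monomorphic}\n"
            f"removed: MAF < {args.min_maf}\t{masked.n_loci - kept.n_loci}\n"
            f"retained loci\t{kept.n_loci}\n"
        )
    print(f"QC: {report.n_input} loci -> {kept.n_loci} "
          f"({report.n_bad_rate} bad-rate, {report.n_monomorphic} monomorphic, "
          f"{masked.n_loci - kept.n_loci} low-MAF removed)")


if __name__ == "__main__":
    main()
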