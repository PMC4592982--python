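"""Generate the synthetic germplasm collection and write all pipeline inputs.

Writes the genotype matrix (TSV), region-class BED, genetic map, gene list,
seed-weight trait table and the planted-truth JSON under results/fixtures/.
"""

import argparse
from pathlib import Path

from germscan import io, simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/fixtures"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sim = simulate.simulate_collection(simulate.SimulationConfig(seed=args.seed))
    io.write_matrix_tsv(sim.genotypes, args.out / "genotypes.tsv")
    io.write_vcf(sim.genotypes, args.out / "genotypes.vcf")
    io.write_region_bed(sim.regions, args.out / "regions.bed")
    sim.genetic_map.to_csv(args.out / "genetic_map.tsv", sep="\t", index=False)
    sim.genes.to_csv(args.out / "genes.tsv", sep="\t", index=False)
    sim.trait.to_csv(args.out / "trait.tsv", sep="\t", index=False)
    sim.genotypes.accession_meta.to_csv(args.out / "accessions.tsv", sep="\t")
    sim.truth.to_json(args.out / "truth.json")

    g = sim.genotypes
    print(f"simulated {g.n_accessions} accessions x {g.n_loci} loci (seed {args.seed})")
    print(f"  populations: {dict(g.accession_meta['population'].value_counts())}")
    print(f"  planted: {len(sim.truth.duplicate_groups)} duplicate pairs, "
          f"{len(sim.truth.planted_blocks)} blocks, "
          f"{len(sim.truth.selected_loci)} selected loci, "
          f"{len(sim.truth.causal_loci)} causal loci")
    print(f"wrote fixtures to {args.out}/")


if __name__ == "__main__":
    main()
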