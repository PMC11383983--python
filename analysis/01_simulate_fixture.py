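#!/usr/bin/env python
"""Build the simulated study dataset: three 3-intron genes on one
chromosome, two phased haplotypes each.

gene0 and gene2 are null genes (identical alleles). gene1 carries every
planted allelic effect at once: a pure splicing-order swap (hap1 removes
introns 1->2->3, hap2 removes 2->1->3), a large poly(A) tail difference
(233 vs 143 nt means), and distinct 3'-cleavage sites 100 nt apart.

Writes SAM/VCF/BED/truth under results/fixture/ for the downstream drivers.
"""

import pathlib

from splicord.simulate import simulate_gene_set, write_fixture

SEED = 11
DEPTH = 400.0

SETTINGS = [
    {},
    {
        "order_mixture_hap1": {(0, 1, 2): 1.0},
        "order_mixture_hap2": {(1, 0, 2): 1.0},
        "polya_hap1": (233.0, 30.0),
        "polya_hap2": (143.0, 30.0),
    },
    {},
]


def main() -> None:
    outdir = pathlib.Path(__file__).resolve().parents[1] / "results" / "fixture"
    # dry pass at depth 1 to learn gene1's coordinates for the APA site
    _, _, models, _ = simulate_gene_set(SETTINGS, seed=SEED, depth=1)
    apa = dict(SETTINGS[1])
    # alternative cleavage site 100 nt upstream of hap1's, still inside the
    # last exon so reads cover the final intron's acceptor window
    apa["end_sites_hap2"] = ((models[1].end - 150, 1.0),)
    reads, truth, models, snps = simulate_gene_set(
        [SETTINGS[0], apa, SETTINGS[2]], seed=SEED, depth=DEPTH
    )
    paths = write_fixture(reads, truth, models, snps, str(outdir))
    n_alleles = truth.groupby(["gene_id", "allele"]).size()
    print(f"wrote {len(reads)} reads over {len(models)} genes to {outdir}")
    print(n_alleles.to_string())
    print("planted in gene1: order swap 1->2->3 vs 2->1->3, "
          "poly(A) 233 vs 143 nt, 3' cleavage sites 100 nt apart")
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
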