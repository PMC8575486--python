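#!/usr/bin/env python
"""Generate the synthetic study system all downstream analyses consume.

Writes the ground-truth taxonomy (2 classes / 4 orders / 8 families /
16 genera / 48 genomes), the rank-structured tree, seven marker
alignments with 10% marker loss and 5% paralog duplication, and the
divergence-grid genome set, under results/01_simulate/.
"""

from pathlib import Path

from gvtaxon.io import write_fasta, write_newick, write_table
from gvtaxon.synthetic import (SimulationConfig, simulate_genome_set,
                               simulate_marker_alignments, simulate_taxonomy,
                               simulate_tree)
from gvtaxon.pipeline import DEFAULT_MARKERS

OUT = Path(__file__).resolve().parent.parent / "results" / "01_simulate"
SEED = 11


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    taxonomy = simulate_taxonomy(cfg)
    tree = simulate_tree(taxonomy, cfg)
    names = sorted(DEFAULT_MARKERS)
    msim = simulate_marker_alignments(
        tree, names, [DEFAULT_MARKERS[m] for m in names], cfg)
    gsim = simulate_genome_set(cfg)

    write_table(taxonomy.to_frame(), OUT / "taxonomy_truth.tsv")
    write_newick(tree, OUT / "true_tree.nwk")
    for m in names:
        write_fasta(msim.alignments[m], OUT / f"marker_{m}.faa")
    write_table(msim.truth, OUT / "marker_truth.tsv")
    write_fasta(gsim.genomes, OUT / "genomes.fna")
    write_table(gsim.truth, OUT / "genome_divergence_truth.tsv")

    counts = taxonomy.counts()
    n_lost = int((~msim.truth.present).sum())
    n_para = int((msim.truth.paralog_ids != "").sum())
    print(f"study system (seed {SEED}): {len(taxonomy.assignments)} genomes, "
          f"{counts['class']} classes / {counts['order']} orders / "
          f"{counts['family']} families / {counts['genus']} genera")
    print(f"markers: {len(names)} ({', '.join(names)}); "
          f"{n_lost} genome-marker cells lost, {n_para} paralog copies planted")
    print(f"genome set: ancestor + {len(gsim.genomes) - 1} mutants at "
          f"divergences {cfg.divergence_grid}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
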