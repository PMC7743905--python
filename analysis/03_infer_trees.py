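"""Build the genome-based reference tree and every per-tissue
transcriptome tree (both methods), with 200 column-bootstrap replicates.

Supermatrices are concatenated per-group alignments (occupancy-trimmed at
0.3, length cutoff 150 columns); trees are neighbor joining on
Poisson-corrected distances.  Main trees and replicate sets are written
as Newick under results/trees/.
"""

import sys
import zlib
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import METHODS, RESULTS, SCRATCH, all_records, study_config, study_dataset

from phylotrx import io as pio
from phylotrx import pipeline as pl
from phylotrx.trees import robinson_foulds, write_newick

N_BOOTSTRAP = 200


def main() -> None:
    cfg = study_config()
    ds = study_dataset()
    records = all_records(ds)
    groups_dir = SCRATCH / "orthologs"
    out = RESULTS / "trees"
    out.mkdir(parents=True, exist_ok=True)
    bulk = SCRATCH / "trees"
    bulk.mkdir(parents=True, exist_ok=True)

    pg_groups = pio.read_groups_tsv(groups_dir / "groups_genome.tsv")
    _, pg_tree, pg_reps, _ = pl.species_tree_from_groups(
        pg_groups, ds.genome_records, min_codons=cfg.length_cutoff,
        trim_occupancy=cfg.trim_occupancy, n_bootstrap=N_BOOTSTRAP, seed=1)
    pio.write_tree(pg_tree, out / "pg.nwk")
    with open(bulk / "pg_bootstrap.nwk", "w") as fh:
        fh.writelines(write_newick(t) + "\n" for t in pg_reps)
    d_true = robinson_foulds(pg_tree, ds.species_tree)
    print(f"genome (PG) tree: d_T = {d_true} to the true species tree, "
          f"{len(pg_groups)} groups")

    for method in METHODS:
        for tissue in ds.config.tissues:
            groups = pio.read_groups_tsv(
                groups_dir / f"groups_{method}_{tissue}.tsv")
            _, tree, reps, _ = pl.species_tree_from_groups(
                groups, records, min_codons=cfg.length_cutoff,
                trim_occupancy=cfg.trim_occupancy,
                n_bootstrap=N_BOOTSTRAP,
                seed=zlib.crc32(f"{method}/{tissue}".encode()) % 2**31)
            pio.write_tree(tree, out / f"pt_{method}_{tissue}.nwk")
            with open(bulk / f"pt_{method}_{tissue}_bootstrap.nwk", "w") as fh:
                fh.writelines(write_newick(t) + "\n" for t in reps)
            print(f"{method}/{tissue}: tree on {tree.n_tips()} species "
                  f"({len(groups)} groups)")
    print(f"trees -> {out}; bootstrap replicates -> {bulk}")


if __name__ == "__main__":
    main()
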