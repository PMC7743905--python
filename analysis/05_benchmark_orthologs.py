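"""Benchmark every method's ortholog groups against the gold standard.

Each group is correct if all members descend from the same ancestral
lineage, incorrect on any conflict.  The genome route should be cleanest,
the gene-tree-based transcriptome route close behind, and reciprocal best
hit worst — hidden ancient paralogy plus missing data sends transcripts
to the wrong group.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import METHODS, RESULTS, SCRATCH, study_dataset

from phylotrx import benchmark as bench
from phylotrx import io as pio


def main() -> None:
    ds = study_dataset()
    groups_dir = SCRATCH / "orthologs"
    out = RESULTS / "benchmark"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    sources = [("genome", None, groups_dir / "groups_genome.tsv")]
    sources += [(method, tissue,
                 groups_dir / f"groups_{method}_{tissue}.tsv")
                for method in METHODS for tissue in ds.config.tissues]
    for method, tissue, path in sources:
        groups = pio.read_groups_tsv(path)
        verdicts = [bench.classify_group(g, ds.gold.lineage_labels)
                    for g in groups]
        s = bench.summarize(verdicts)
        rows.append({"method": method, "tissue": tissue or "-",
                     "n_groups": s.n_groups,
                     "fraction_correct": round(s.fraction_correct, 4),
                     "fraction_incorrect": round(s.fraction_incorrect, 4),
                     "fraction_unannotated": round(s.fraction_unannotated, 4)})

    table = pd.DataFrame(rows)
    table.to_csv(out / "benchmark.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    means = table[table.tissue != "-"].groupby("method")[
        "fraction_incorrect"].mean()
    print("\nmean fraction incorrect across tissues:")
    for method, value in means.items():
        print(f"  {method}: {value:.3f}")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
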