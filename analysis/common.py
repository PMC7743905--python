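"""Shared study configuration for the analysis scripts.

One seeded mammal-like simulation (22 species, 7 tissues, 200 gene
families with duplication, loss, ancient paralogy, isoform redundancy and
30% expression dropout) is the dataset every numbered script works on.
Scripts re-derive it deterministically from the seed, so each can run
standalone; derived artifacts are written under results/ as plain text.
"""

from pathlib import Path

from phylotrx.pipeline import PipelineConfig
from phylotrx.simulate import mammal_like, simulate_dataset

STUDY_SEED = 17
_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results"        # small summary tables, kept
SCRATCH = _ROOT / "scratch"       # bulky regenerable artifacts

METHODS = ("tree_based", "rbh")


def study_config() -> PipelineConfig:
    return PipelineConfig(sim=mammal_like(seed=STUDY_SEED), seed=STUDY_SEED)


def study_dataset():
    return simulate_dataset(study_config().sim)


def all_records(dataset) -> dict:
    records = dict(dataset.genome_records)
    for tissue_records in dataset.transcriptomes.values():
        records.update(tissue_records)
    return records
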