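"""Readers and writers for the pipeline's plain-text artifacts.

FASTA goes through Biopython.  Record metadata (species, gene, isoform,
coordinate frame) rides in the FASTA description as ``key=value`` pairs so
a FASTA round trip preserves everything needed downstream.  Similarity
tables, ortholog groups and gold-standard labels are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .orthology import OrthologGroup, SequenceRecord, SimilarityEdge
from .trees import PhyloTree, parse_newick, write_newick

SIMILARITY_COLUMNS = ["query", "subject", "aligned_fraction",
                      "identity_fraction", "hit_fraction", "bitscore_like"]


def write_fasta(records: Iterable[SequenceRecord], path: Path | str) -> None:
    bio = []
    for r in records:
        desc = f"species={r.species_id} gene={r.gene_id} isoform={r.isoform_id}"
        if r.frame_id is not None:
            desc += f" frame={r.frame_id}"
        if r.aligned is not None:
            desc += f" aligned={r.aligned}"
        bio.append(BioSeqRecord(Seq(r.residues), id=r.seq_id, description=desc))
    SeqIO.write(bio, str(path), "fasta")


def read_fasta(path: Path | str) -> dict[str, SequenceRecord]:
    out: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
        out[rec.id] = SequenceRecord(
            seq_id=rec.id,
            species_id=meta.get("species", rec.id.split("|")[0]),
            gene_id=meta.get("gene", rec.id),
            isoform_id=meta.get("isoform", "i0"),
            residues=str(rec.seq),
            aligned=meta.get("aligned"),
            frame_id=meta.get("frame"))
    return out


def write_similarity_tsv(edges: Iterable[SimilarityEdge],
                         path: Path | str) -> None:
    df = pd.DataFrame([{c: getattr(e, c) for c in SIMILARITY_COLUMNS}
                       for e in edges], columns=SIMILARITY_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_similarity_tsv(path: Path | str) -> list[SimilarityEdge]:
    df = pd.read_csv(path, sep="\t")
    return [SimilarityEdge(query=str(r.query), subject=str(r.subject),
                           aligned_fraction=float(r.aligned_fraction),
                           identity_fraction=float(r.identity_fraction),
                           hit_fraction=float(r.hit_fraction),
                           bitscore_like=float(r.bitscore_like))
            for r in df.itertuples(index=False)]


def write_groups_tsv(groups: Iterable[OrthologGroup], path: Path | str) -> None:
    rows = [{"group_id": g.group_id, "species_id": sp, "seq_id": sid,
             "method_tag": g.method_tag}
            for g in groups for sp, sid in sorted(g.members.items())]
    pd.DataFrame(rows, columns=["group_id", "species_id", "seq_id",
                                "method_tag"]).to_csv(path, sep="\t",
                                                      index=False)


def read_groups_tsv(path: Path | str) -> list[OrthologGroup]:
    df = pd.read_csv(path, sep="\t")
    groups: dict[str, OrthologGroup] = {}
    for r in df.itertuples(index=False):
        g = groups.setdefault(str(r.group_id), OrthologGroup(
            group_id=str(r.group_id), members={}, method_tag=str(r.method_tag)))
        g.members[str(r.species_id)] = str(r.seq_id)
    return list(groups.values())


def write_labels_tsv(labels: dict[str, str], path: Path | str) -> None:
    pd.DataFrame(sorted(labels.items()),
                 columns=["seq_id", "label"]).to_csv(path, sep="\t",
                                                     index=False)


def read_labels_tsv(path: Path | str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.seq_id): str(r.label) for r in df.itertuples(index=False)}


def read_tree(path: Path | str) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_tree(tree: PhyloTree, path: Path | str) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


def write_json(obj: dict, path: Path | str) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
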