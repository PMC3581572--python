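"""File formats: per-species FASTA genomes, alignment FASTA, event-log TSV.

FASTA headers follow the ``species|gene_id|family`` convention so that every
sequence is traceable to its simulated family; readers accept the same
layout and return :class:`~orthosim.evolver.Gene` records.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evolver import EventRecord, Gene, SimulatedDataset

__all__ = [
    "write_genomes_fasta",
    "read_genomes_fasta",
    "write_msa_fasta",
    "write_event_log",
    "read_event_log",
]


def _records(genes: Iterable[Gene]) -> Iterable[SeqRecord]:
    for g in genes:
        yield SeqRecord(
            Seq(g.sequence), id=f"{g.species}|{g.gene_id}|{g.family}", description=""
        )


def write_genomes_fasta(dataset: SimulatedDataset, outdir: Path) -> list[Path]:
    """One FASTA per species, sorted deterministically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for species in sorted(dataset.genomes):
        path = outdir / f"{species}.fa"
        genes = sorted(dataset.genomes[species], key=lambda g: g.gene_id)
        SeqIO.write(_records(genes), path, "fasta")
        paths.append(path)
    return paths


def read_genomes_fasta(paths: Iterable[Path]) -> dict[str, list[Gene]]:
    genomes: dict[str, list[Gene]] = {}
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: header {rec.id!r} is not species|gene|family"
                )
            species, gene_id, family = parts
            genomes.setdefault(species, []).append(
                Gene(species, gene_id, family, str(rec.seq))
            )
    return genomes


def write_msa_fasta(row_ids: list[str], rows: list[str], path: Path) -> None:
    records = [
        SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(row_ids, rows)
    ]
    SeqIO.write(records, path, "fasta")


_EVENT_FIELDS = ["event", "family", "species_branch", "depth", "detail"]


def write_event_log(events: Iterable[EventRecord], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_EVENT_FIELDS)
        for e in events:
            writer.writerow([e.event, e.family, e.species_branch,
                             f"{e.depth:.6f}", e.detail])


def read_event_log(path: Path) -> list[EventRecord]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                EventRecord(row["event"], row["family"], row["species_branch"],
                            float(row["depth"]), row["detail"])
            )
    return out
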