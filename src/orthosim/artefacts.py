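"""Sequencing/assembly artefact injection: X-masking of one stretch per gene.

Low-coverage genome assemblies and sloppy gene annotation leave runs of
ambiguous residues in protein sequences.  This is emulated by replacing, in
every gene of every genome, a single randomly placed stretch with the
ambiguity character ``X``.  The stretch length is a proportion of the gene
length drawn from a normal distribution with mean ``mu`` (varied between
0.06 and 0.18 across benchmark scenarios) and standard deviation ``sd``,
clamped to [0, 1]; a non-positive draw leaves the gene unmasked.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .evolver import EventRecord, Gene, SimulatedDataset

__all__ = ["ArtefactParams", "inject", "mask_sequence"]


@dataclass(frozen=True)
class ArtefactParams:
    """Length-proportion distribution of the masked stretch.

    ``sd`` defaults to ``mu / 3``, which keeps clamping to [0, 1] rare over
    the 6-18% range of ``mu``; pass an explicit value to override.
    """

    mu: float
    sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if self.sd is None:
            object.__setattr__(self, "sd", self.mu / 3.0)
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def mask_sequence(seq: str, p: float, rng: np.random.Generator) -> str:
    """Replace one stretch of ``round(p * len)`` residues with X, uniformly
    placed among valid positions.  Uses round-half-to-even; a stretch of
    length 0 means no masking."""
    n = len(seq)
    # round-half-to-even for cross-platform determinism
    k = int(np.round(np.clip(p, 0.0, 1.0) * n))
    if k <= 0:
        return seq
    k = min(k, n)
    start = int(rng.integers(0, n - k + 1))
    return seq[:start] + "X" * k + seq[start + k :]


def inject(
    dataset: SimulatedDataset,
    params: ArtefactParams,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Return a masked copy of the dataset; the input is left untouched.

    For every gene a proportion p ~ Normal(mu, sd) is drawn, clamped to
    [0, 1]; ``round(p * L)`` consecutive residues at a uniform start are
    replaced by X.  Gene trees, true alignments and the event log are shared
    with the input (masking does not alter evolutionary history); unmasked
    genes (p <= 0) are logged.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    new_genomes: dict[str, list[Gene]] = {}
    extra_events: list[EventRecord] = []
    for species in sorted(dataset.genomes):
        masked: list[Gene] = []
        for gene in dataset.genomes[species]:
            p = float(rng.normal(params.mu, params.sd))
            new_seq = mask_sequence(gene.sequence, p, rng)
            if p <= 0 or new_seq == gene.sequence:
                extra_events.append(
                    EventRecord(
                        "mask_skipped", gene.family, species, 0.0,
                        f"gene={gene.gene_id} p={p:.4f}",
                    )
                )
            masked.append(_dc_replace(gene, sequence=new_seq))
        new_genomes[species] = masked
    return SimulatedDataset(
        genomes=new_genomes,
        gene_trees=dataset.gene_trees,
        true_msas=dataset.true_msas,
        event_log=list(dataset.event_log) + extra_events,
        config=dataset.config,
    )
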