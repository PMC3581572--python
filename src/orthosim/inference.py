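"""Baseline orthology inference: all-vs-all local alignment, BBH and RSD.

The two classic graph-based baselines are implemented on top of an
all-vs-all Smith-Waterman phase:

* BBH (bidirectional best hit): genes a and b are predicted orthologs iff b
  is a's unique highest-*scoring* hit in b's genome and vice versa.
* RSD (reciprocal smallest distance): same reciprocity, but ranking hits by
  maximum-likelihood PAM distance instead of alignment score.

Alignment uses an affine-gap local aligner (Biopython's C implementation)
with a log-odds scoring matrix derived from the same substitution process
that drives the simulator: M[a,b] = round(2 * log2(P_ab(d) / pi_b)) in
half-bit units at a fixed reference distance.  The ambiguity character X
scores zero against everything, is excluded from the "aligned characters"
count used for score normalisation, and never enters distance estimation --
ambiguous stretches are uninformative rather than penalised.

Score ties for a best hit exclude the gene from the prediction (strict
uniqueness); with continuous scores ties are rare and the rule keeps the
output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .evolver import Gene, SimulatedDataset
from .substitution import AMINO_ACIDS, DistanceEstimate, SubstitutionModel, ml_distance, wag_model
from .truth import OrthologPairSet

__all__ = [
    "Scoring",
    "AlignmentResult",
    "Hit",
    "HitTable",
    "default_scoring",
    "smith_waterman",
    "all_vs_all",
    "align_pairs",
    "bbh",
    "rsd",
]

EXTENDED_ALPHABET = AMINO_ACIDS + "X"
DEFAULT_HIT_THRESHOLD = 85.0  # half-bit score units


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap penalties.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend`` (both stored
    as positive penalties).
    """

    matrix: np.ndarray  # (21, 21) integer scores over EXTENDED_ALPHABET
    gap_open: float = 12.0
    gap_extend: float = 2.0

    def aligner(self) -> Align.PairwiseAligner:
        arr = substitution_matrices.Array(alphabet=EXTENDED_ALPHABET, dims=2)
        arr[:, :] = self.matrix
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = arr
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


_scoring_cache: dict[tuple[float, float, float], Scoring] = {}


def default_scoring(
    reference_distance: float = 120.0,
    gap_open: float = 12.0,
    gap_extend: float = 2.0,
    model: Optional[SubstitutionModel] = None,
) -> Scoring:
    """Half-bit log-odds matrix from the substitution model at a reference
    PAM distance.  Reversibility makes the matrix symmetric; the X row and
    column are zero (ambiguity is uninformative)."""
    key = (reference_distance, gap_open, gap_extend)
    if model is None and key in _scoring_cache:
        return _scoring_cache[key]
    m = model or wag_model()
    P = m.transition_matrix(reference_distance)
    with np.errstate(divide="ignore"):
        odds = np.log2(P / m.pi[None, :])
    scores = np.rint(2.0 * (odds + odds.T) / 2.0)
    full = np.zeros((21, 21))
    full[:20, :20] = scores
    scoring = Scoring(matrix=full, gap_open=gap_open, gap_extend=gap_extend)
    if model is None:
        _scoring_cache[key] = scoring
    return scoring


@dataclass
class AlignmentResult:
    """One local alignment: raw score, per-character normalised score, and
    the aligned residue pairs (gap and X columns excluded) for distance
    estimation."""

    score: float
    normalized_score: float
    aligned_columns: int
    residue_pairs: list[tuple[str, str]] = field(default_factory=list, repr=False)
    distance: Optional[DistanceEstimate] = None

    def estimate_distance(self, model: Optional[SubstitutionModel] = None) -> DistanceEstimate:
        if self.distance is None:
            if not self.residue_pairs:
                raise ValueError("no aligned residues for distance estimation")
            self.distance = ml_distance(self.residue_pairs, model)
        return self.distance


def smith_waterman(
    a: str,
    b: str,
    scoring: Optional[Scoring] = None,
    traceback: bool = True,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> AlignmentResult:
    """Optimal local alignment of two sequences under affine gap costs.

    With ``traceback=False`` only the score is computed (the normalised
    score and residue pairs are then unavailable), which is substantially
    faster for score-only screening.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or default_scoring()
    if aligner is None:
        aligner = scoring.aligner()
    if not traceback:
        return AlignmentResult(
            score=float(aligner.score(a, b)),
            normalized_score=float("nan"),
            aligned_columns=0,
        )
    alignments = aligner.align(a, b)
    score = float(alignments.score)
    try:
        aln = alignments[0]  # deterministic first traceback
    except IndexError:
        # no positive-scoring local alignment exists (empty optimum)
        return AlignmentResult(score=score, normalized_score=0.0, aligned_columns=0)
    pairs: list[tuple[str, str]] = []
    aligned_chars = 0
    n_cols = 0
    seg_a, seg_b = aln.aligned
    for (a0, a1), (b0, b1) in zip(seg_a, seg_b):
        for ca, cb in zip(a[a0:a1], b[b0:b1]):
            n_cols += 1
            if ca != "X":
                aligned_chars += 1
            if cb != "X":
                aligned_chars += 1
            if ca != "X" and cb != "X":
                pairs.append((ca, cb))
    normalized = score / aligned_chars if aligned_chars else 0.0
    return AlignmentResult(
        score=score,
        normalized_score=normalized,
        aligned_columns=n_cols,
        residue_pairs=pairs,
    )


@dataclass
class Hit:
    gene_a: str  # qualified id in genome A
    gene_b: str  # qualified id in genome B
    result: AlignmentResult


class HitTable:
    """Above-threshold alignment hits for every cross-genome gene pair.

    Hits are stored once per unordered genome pair (A < B lexicographically)
    and are symmetric by construction: the alignment of (a, b) and (b, a) is
    the same alignment.
    """

    def __init__(self) -> None:
        self._hits: dict[tuple[str, str], list[Hit]] = {}

    def add(self, species_a: str, species_b: str, hit: Hit) -> None:
        key = (species_a, species_b)
        if species_a > species_b:
            key = (species_b, species_a)
            hit = Hit(hit.gene_b, hit.gene_a, hit.result)
        self._hits.setdefault(key, []).append(hit)

    def genome_pairs(self) -> list[tuple[str, str]]:
        return sorted(self._hits)

    def hits(self, species_a: str, species_b: str) -> list[Hit]:
        """Hits oriented so ``gene_a`` belongs to ``species_a``."""
        if species_a <= species_b:
            return self._hits.get((species_a, species_b), [])
        return [
            Hit(h.gene_b, h.gene_a, h.result)
            for h in self._hits.get((species_b, species_a), [])
        ]

    def __len__(self) -> int:
        return sum(len(v) for v in self._hits.values())

    def ensure_distances(self, model: Optional[SubstitutionModel] = None) -> None:
        for hits in self._hits.values():
            for hit in hits:
                if hit.result.distance is None and not hit.result.residue_pairs:
                    # fully ambiguous overlap: no usable columns, treat as
                    # maximally distant so it can never win an RSD race
                    hit.result.distance = DistanceEstimate(
                        d_hat=float("inf"), variance=float("inf"),
                        loglik=float("-inf"), at_bound=True,
                    )
                else:
                    hit.result.estimate_distance(model)

    def all_results(self) -> Iterable[AlignmentResult]:
        for hits in self._hits.values():
            for hit in hits:
                yield hit.result


def _genomes_of(genomes) -> dict[str, list[Gene]]:
    if isinstance(genomes, SimulatedDataset):
        return genomes.genomes
    return genomes


def all_vs_all(
    genomes,
    scoring: Optional[Scoring] = None,
    threshold: float = DEFAULT_HIT_THRESHOLD,
    within_families: bool = False,
    compute_distances: bool = False,
    traceback: bool = True,
    model: Optional[SubstitutionModel] = None,
) -> HitTable:
    """Align every cross-species gene pair and keep hits above ``threshold``.

    ``genomes`` is a ``{species: [Gene, ...]}`` mapping or a
    :class:`~orthosim.evolver.SimulatedDataset`.  With
    ``within_families=True`` only genes sharing a family tag are compared --
    valid for simulated data where unrelated families are random sequences
    whose alignment scores fall below any sensible hit threshold, and much
    faster.  Distances are computed lazily unless ``compute_distances``.
    With ``traceback=False`` hits carry scores only (sufficient for BBH);
    normalised scores and distances can be recovered later for a subset of
    pairs with :func:`align_pairs`.
    """
    genomes = _genomes_of(genomes)
    if len(genomes) < 2:
        raise ValueError("all-vs-all needs at least 2 genomes")
    scoring = scoring or default_scoring()
    aligner = scoring.aligner()  # build once; construction dominates short alignments
    table = HitTable()
    species = sorted(genomes)
    for i, sp_a in enumerate(species):
        for sp_b in species[i + 1 :]:
            genes_a = genomes[sp_a]
            genes_b = genomes[sp_b]
            if within_families:
                by_family: dict[str, list[Gene]] = {}
                for g in genes_b:
                    by_family.setdefault(g.family, []).append(g)
                candidates = [
                    (ga, gb)
                    for ga in genes_a
                    for gb in by_family.get(ga.family, ())
                ]
            else:
                candidates = [(ga, gb) for ga in genes_a for gb in genes_b]
            for ga, gb in candidates:
                if not ga.sequence or not gb.sequence:
                    continue
                res = smith_waterman(
                    ga.sequence, gb.sequence, scoring,
                    traceback=traceback, aligner=aligner,
                )
                if res.score < threshold:
                    continue
                if compute_distances and res.residue_pairs:
                    res.estimate_distance(model)
                table.add(sp_a, sp_b, Hit(ga.qualified_id, gb.qualified_id, res))
    return table


def align_pairs(
    genomes,
    pairs: Iterable[tuple[str, str]],
    scoring: Optional[Scoring] = None,
    compute_distances: bool = True,
    model: Optional[SubstitutionModel] = None,
) -> dict[tuple[str, str], AlignmentResult]:
    """Full alignments (normalised score, residue pairs, optionally ML
    distance) for selected qualified-id pairs; used to decorate score-only
    BBH output without paying traceback cost for every candidate hit."""
    genomes = _genomes_of(genomes)
    seqs = {
        g.qualified_id: g.sequence
        for genes in genomes.values()
        for g in genes
    }
    scoring = scoring or default_scoring()
    aligner = scoring.aligner()
    out: dict[tuple[str, str], AlignmentResult] = {}
    for a, b in pairs:
        res = smith_waterman(seqs[a], seqs[b], scoring, aligner=aligner)
        if compute_distances and res.residue_pairs:
            res.estimate_distance(model)
        out[(a, b)] = res
    return out


def _reciprocal_best(
    hits: list[Hit], value, minimize: bool
) -> list[tuple[str, str]]:
    """Pairs (a, b) where each is the other's unique best hit under
    ``value`` (max by default, min when ``minimize``)."""
    best_a: dict[str, tuple[float, Optional[str]]] = {}
    best_b: dict[str, tuple[float, Optional[str]]] = {}
    sign = -1.0 if minimize else 1.0
    for hit in hits:
        v = sign * value(hit)
        for key, other, store in (
            (hit.gene_a, hit.gene_b, best_a),
            (hit.gene_b, hit.gene_a, best_b),
        ):
            cur = store.get(key)
            if cur is None or v > cur[0]:
                store[key] = (v, other)
            elif v == cur[0]:
                store[key] = (v, None)  # tie: strict uniqueness excludes
    out = []
    for a, (_, b) in best_a.items():
        if b is None:
            continue
        back = best_b.get(b)
        if back is not None and back[1] == a:
            out.append((a, b))
    return out


def bbh(hits: HitTable) -> OrthologPairSet:
    """Bidirectional best hits by alignment score."""
    out = OrthologPairSet(source="BBH")
    for sp_a, sp_b in hits.genome_pairs():
        for a, b in _reciprocal_best(
            hits.hits(sp_a, sp_b), lambda h: h.result.score, minimize=False
        ):
            out.add(a, b)
    return out


def rsd(hits: HitTable, model: Optional[SubstitutionModel] = None) -> OrthologPairSet:
    """Reciprocal smallest ML distance; distances are computed on demand."""
    hits.ensure_distances(model)
    out = OrthologPairSet(source="RSD")
    for sp_a, sp_b in hits.genome_pairs():
        for a, b in _reciprocal_best(
            hits.hits(sp_a, sp_b),
            lambda h: h.result.distance.d_hat,
            minimize=True,
        ):
            out.add(a, b)
    return out
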