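"""WAG amino-acid substitution model and ML pairwise distance estimation.

The rate matrix Q is assembled from the published WAG exchangeabilities S and
stationary frequencies pi as Q = S.diag(pi) with the diagonal set for zero
row sums, then globally rescaled so the expected number of substitutions per
site per PAM unit is exactly 0.01.  With this calibration, branch lengths,
event rates and estimated distances all share the PAM unit system: evolving
a sequence along a branch of length d PAM changes on the order of d% of
sites (less at large d because of multiple hits).

WAG is time-reversible, so Q can be symmetrised by a pi^(1/2) similarity
transform; the transition matrices P(d) = expm(Q d) used both for simulation
and for likelihood evaluation are computed from a single eigendecomposition.

Distances between aligned sequence pairs are estimated by maximum likelihood:
d_hat maximises sum over aligned columns (a, b) of log(pi_a * P_ab(d)),
which is the standard pairwise ML distance for a stationary reversible
Markov model.  The curvature of the log-likelihood at the optimum (observed
Fisher information) provides the variance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "SubstitutionModel",
    "DistanceEstimate",
    "load_wag_tables",
    "build_model",
    "wag_model",
    "sample_stationary",
    "evolve_sites",
    "ml_distance",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

D_MIN = 0.01
D_MAX = 1000.0
_BRENT_TOL = 1e-4


@dataclass(frozen=True)
class DistanceEstimate:
    """ML distance between an aligned pair, in PAM units."""

    d_hat: float
    variance: float
    loglik: float
    at_bound: bool = False


class SubstitutionModel:
    """Calibrated reversible amino-acid substitution model.

    Attributes
    ----------
    Q : (20, 20) ndarray
        Instantaneous rate matrix in 1/PAM units (rows sum to zero,
        -sum_i pi_i Q_ii = 0.01).
    pi : (20,) ndarray
        Stationary amino-acid frequencies.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        self.pi = pi
        self.alphabet = AMINO_ACIDS
        # Reversibility: B = D^(1/2) Q D^(-1/2) is symmetric; eigendecompose
        # once and reuse for every P(d).
        sq = np.sqrt(pi)
        B = (Q * sq[:, None] / sq[None, :])
        B = (B + B.T) / 2.0
        lam, U = np.linalg.eigh(B)
        self._lam = lam
        self._left = U / sq[:, None]       # D^(-1/2) U
        self._right = U.T * sq[None, :]    # U^T D^(1/2)
        self.log_pi = np.log(pi)

    def transition_matrix(self, d: float) -> np.ndarray:
        """P(d) = expm(Q d); rows are conditional residue distributions."""
        if d < 0:
            raise ValueError("distance must be non-negative")
        P = (self._left * np.exp(self._lam * d)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def expected_change(self, d: float) -> float:
        """Probability that a stationary site differs after distance d."""
        P = self.transition_matrix(d)
        return float(np.sum(self.pi * (1.0 - np.diag(P))))


def load_wag_tables() -> tuple[np.ndarray, np.ndarray]:
    """Read the WAG exchangeabilities (lower triangle, column-major) and
    stationary frequencies shipped with the package."""
    text = (resources.files("orthosim") / "data" / "wag.txt").read_text()
    section = None
    ex: list[float] = []
    fr: list[float] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        if section == "exchangeabilities":
            ex.append(float(line))
        elif section == "frequencies":
            fr.append(float(line))
    if len(ex) != 190 or len(fr) != 20:
        raise ValueError("malformed WAG table file")
    S = np.zeros((20, 20))
    k = 0
    for j in range(20):          # column-major strict lower triangle
        for i in range(j + 1, 20):
            S[i, j] = S[j, i] = ex[k]
            k += 1
    return S, np.asarray(fr)


def build_model(
    exchangeabilities: Optional[np.ndarray] = None,
    frequencies: Optional[np.ndarray] = None,
) -> SubstitutionModel:
    """Assemble the calibrated rate matrix from exchangeabilities S and
    frequencies pi (defaults: the shipped WAG tables)."""
    if exchangeabilities is None or frequencies is None:
        S, pi = load_wag_tables()
        if exchangeabilities is not None:
            S = np.asarray(exchangeabilities, dtype=float)
        if frequencies is not None:
            pi = np.asarray(frequencies, dtype=float)
    else:
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1 (got {pi.sum():.8f})")
    pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # Calibrate: 1 PAM = 1 expected substitution per 100 sites.
    rate = -np.sum(pi * np.diag(Q))
    Q *= 0.01 / rate
    return SubstitutionModel(Q, pi)


_WAG_CACHE: Optional[SubstitutionModel] = None


def wag_model() -> SubstitutionModel:
    """The default WAG model (cached)."""
    global _WAG_CACHE
    if _WAG_CACHE is None:
        _WAG_CACHE = build_model()
    return _WAG_CACHE


def seq_to_indices(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r} in sequence") from None


def indices_to_seq(idx: Sequence[int]) -> str:
    return "".join(AMINO_ACIDS[i] for i in idx)


def sample_stationary(
    length: int, model: SubstitutionModel, rng: np.random.Generator
) -> str:
    """Draw an i.i.d. sequence of ``length`` residues from pi."""
    if length < 1:
        raise ValueError("length must be >= 1")
    idx = rng.choice(20, size=length, p=model.pi)
    return indices_to_seq(idx)


def evolve_indices(
    idx: np.ndarray, d: float, model: SubstitutionModel, rng: np.random.Generator
) -> np.ndarray:
    """Site-wise substitution over distance d on integer-coded residues."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d == 0 or len(idx) == 0:
        return idx.copy()
    cum = np.cumsum(model.transition_matrix(d), axis=1)
    u = rng.random(len(idx))
    # categorical draw per site from its residue's row
    return (u[:, None] > cum[idx]).sum(axis=1).astype(np.int8)


def evolve_sites(
    seq: str, d: float, model: SubstitutionModel, rng: np.random.Generator
) -> str:
    """Evolve each site independently along a branch of length d PAM.

    Substitution only: length is unchanged.  Input must be over the canonical
    20-letter alphabet (ambiguity characters are a downstream artefact, never
    part of the evolutionary process).
    """
    return indices_to_seq(evolve_indices(seq_to_indices(seq), d, model, rng))


def _count_matrix(pairs_a: np.ndarray, pairs_b: np.ndarray) -> np.ndarray:
    N = np.zeros((20, 20))
    np.add.at(N, (pairs_a, pairs_b), 1.0)
    return N


def ml_distance(
    aligned_pair: Sequence[tuple[str, str]] | tuple[str, str],
    model: Optional[SubstitutionModel] = None,
    d_min: float = D_MIN,
    d_max: float = D_MAX,
) -> DistanceEstimate:
    """Maximum-likelihood PAM distance of a gapless aligned residue pair.

    ``aligned_pair`` is either a sequence of (residue, residue) column tuples
    or a pair of equal-length strings; gap and ambiguity columns must be
    excluded by the caller.  Maximises L(d) = sum_cols log(pi_a P_ab(d)) over
    d in [d_min, d_max] with Brent's method; an optimum within tolerance of a
    search bound is flagged via ``at_bound``.  Variance is the inverse
    observed Fisher information at d_hat.
    """
    from scipy.optimize import minimize_scalar

    if model is None:
        model = wag_model()
    if (
        isinstance(aligned_pair, tuple)
        and len(aligned_pair) == 2
        and isinstance(aligned_pair[0], str)
    ):
        sa, sb = aligned_pair
        if len(sa) != len(sb):
            raise ValueError("aligned sequences must have equal length")
        cols = list(zip(sa, sb))
    else:
        cols = list(aligned_pair)
    if not cols:
        raise ValueError("no aligned residues")
    a_idx = np.fromiter((_AA_INDEX[a] for a, _ in cols), dtype=np.intp)
    b_idx = np.fromiter((_AA_INDEX[b] for _, b in cols), dtype=np.intp)
    N = _count_matrix(a_idx, b_idx)
    base = float(np.sum(N.sum(axis=1) * model.log_pi))

    def neg_loglik(d: float) -> float:
        P = model.transition_matrix(d)
        with np.errstate(divide="ignore"):
            logP = np.log(P)
        logP[N == 0] = 0.0  # avoid -inf * 0
        return -(base + float(np.sum(N * logP)))

    res = minimize_scalar(
        neg_loglik, bounds=(d_min, d_max), method="bounded",
        options={"xatol": _BRENT_TOL},
    )
    d_hat = float(res.x)
    loglik = -float(res.fun)
    at_bound = d_hat - d_min < 10 * _BRENT_TOL or d_max - d_hat < 10 * _BRENT_TOL
    # Observed Fisher information by central difference.
    h = max(1e-3, 1e-3 * d_hat)
    if d_hat - h > d_min and d_hat + h < d_max:
        second = (
            -neg_loglik(d_hat - h) + 2 * neg_loglik(d_hat) - neg_loglik(d_hat + h)
        ) / h**2
        variance = -1.0 / second if second < 0 else float("inf")
    else:
        variance = float("inf")
    return DistanceEstimate(
        d_hat=d_hat, variance=max(variance, 0.0), loglik=loglik, at_bound=at_bound
    )
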