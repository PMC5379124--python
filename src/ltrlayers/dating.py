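"""Insertion dating from intra-element LTR divergence.

The two LTRs of one element are identical at insertion time, so their
divergence is a molecular clock: align the 5' and 3' LTR, count transition
(P) and transversion (Q) site proportions, compute the Kimura two-parameter
distance K = -1/2 ln((1-2P-Q) sqrt(1-2Q)) and convert to years via
T = K / (2r) at a given substitution rate r.
"""

from __future__ import annotations

from dataclasses import dataclass

from math import log, sqrt

from Bio import Align

#: substitution rates (substitutions/site/year) reported with every estimate
RATE_FAST = 1.3e-8
RATE_SLOW = 7e-9
DEFAULT_RATES = (RATE_FAST, RATE_SLOW)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = _PURINES | _PYRIMIDINES

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturatedDistanceError(ValueError):
    """The K2P logarithm is undefined (2P+Q >= 1 or 2Q >= 1)."""


@dataclass(frozen=True)
class AgeEstimate:
    """K2P dating of one LTR pair at one substitution rate."""

    P: float
    Q: float
    K: float
    r: float
    T: float
    compared_sites: int


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def align_ltr_pair(seq5: str, seq3: str) -> tuple[str, str]:
    """Globally align the 5' and 3' LTR sequences (match +1, mismatch -1,
    gap -2) and return the two gapped rows."""
    if not seq5 or not seq3:
        raise ValueError("LTR sequences must be non-empty")
    alignment = _aligner().align(seq5.upper(), seq3.upper())[0]
    return str(alignment[0]), str(alignment[1])


def count_site_patterns(aligned5: str, aligned3: str) -> tuple[int, int, int]:
    """(transitions, transversions, comparable_sites) over columns free of
    gaps and ambiguity codes."""
    if len(aligned5) != len(aligned3):
        raise ValueError("aligned sequences differ in length")
    ts = tv = sites = 0
    for a, b in zip(aligned5, aligned3):
        if a not in _VALID or b not in _VALID:
            continue
        sites += 1
        if a == b:
            continue
        if (a, b) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return ts, tv, sites


def k2p_from_proportions(P: float, Q: float) -> float:
    """K2P distance from transition/transversion site proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(
            f"distance saturated (P={P:.4f}, Q={Q:.4f})"
        )
    return -0.5 * log(w1 * sqrt(w2))


def k2p_distance(aligned5: str, aligned3: str) -> tuple[float, float, float]:
    """(P, Q, K) for an aligned LTR pair.

    Raises :class:`SaturatedDistanceError` when the distance is undefined and
    ValueError when no comparable column exists.
    """
    ts, tv, sites = count_site_patterns(aligned5, aligned3)
    if sites == 0:
        raise ValueError("no comparable alignment columns")
    P = ts / sites
    Q = tv / sites
    return P, Q, k2p_from_proportions(P, Q)


def insertion_time(K: float, r: float) -> float:
    """Years since insertion: T = K / (2 r)."""
    if K < 0:
        raise ValueError("K must be non-negative")
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    return K / (2.0 * r)


def estimate_age(
    seq5: str, seq3: str, rates: tuple[float, ...] = DEFAULT_RATES
) -> list[AgeEstimate]:
    """Align an LTR pair and date it at each substitution rate."""
    a5, a3 = align_ltr_pair(seq5, seq3)
    ts, tv, sites = count_site_patterns(a5, a3)
    if sites == 0:
        raise ValueError("no comparable alignment columns")
    P, Q = ts / sites, tv / sites
    K = k2p_from_proportions(P, Q)
    return [
        AgeEstimate(P=P, Q=Q, K=K, r=r, T=insertion_time(K, r), compared_sites=sites)
        for r in rates
    ]
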