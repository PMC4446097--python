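"""Gene-list overlap enrichment by the one-sided hypergeometric test."""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .exceptions import ValidationError

__all__ = ["OverlapResult", "list_overlap_test"]


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of list A with list B inside a universe of N identifiers.

    ``fraction`` is the overlap relative to A (m / |A|); ``p_value`` is the
    hypergeometric upper tail P(X >= m) for drawing |A| identifiers from a
    universe of N containing |B| successes.
    """

    size_a: int
    size_b: int
    universe_n: int
    overlap: int
    fraction: float
    p_value: float


def list_overlap_test(list_a, list_b, universe_n: int) -> OverlapResult:
    """Test whether two identifier lists overlap more than chance.

    Lists are treated as sets (duplicates rejected); both must fit in the
    universe.  The p-value is one-sided for enrichment: the probability that
    a random |A|-subset of the universe hits at least the observed number of
    B members.
    """
    a, b = list(list_a), list(list_b)
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValidationError("input lists must be deduplicated")
    set_a, set_b = set(a), set(b)
    if len(set_a) == 0:
        raise ValidationError("list A is empty")
    if universe_n < 1:
        raise ValidationError("universe_n must be >= 1")
    if len(set_a) > universe_n or len(set_b) > universe_n:
        raise ValidationError("a list is larger than the universe")
    m = len(set_a & set_b)
    # P(X >= m) with population N, |B| successes, |A| draws
    p = float(stats.hypergeom.sf(m - 1, universe_n, len(set_b), len(set_a)))
    return OverlapResult(
        size_a=len(set_a),
        size_b=len(set_b),
        universe_n=universe_n,
        overlap=m,
        fraction=m / len(set_a),
        p_value=min(max(p, 0.0), 1.0),
    )
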