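"""Fuzzy matching of free-text treatment records to licensed product names.

Farm software stores treatments as free text ("betamux", "pen/strep"),
which must be matched to a reference list of licensed veterinary
products to recover the use category (antimicrobial, anti-inflammatory,
vaccine).  Matching uses the partial-ratio measure: with x the shorter
of the two case-folded strings (length m), the Levenshtein similarity
100*(1 - d/m) is computed between x and every length-m substring of the
longer string, and the maximum over windows is returned.  An exact or
substring match therefore scores 100.
"""

from __future__ import annotations

import edlib

__all__ = ["levenshtein", "partial_ratio", "best_match"]


def levenshtein(a: str, b: str) -> int:
    """Exact Levenshtein (unit-cost edit) distance."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _normalise(s: str) -> str:
    return s.strip().casefold()


def partial_ratio(a: str, b: str) -> float:
    """Best windowed Levenshtein similarity between two strings, 0..100.

    Case and leading/trailing whitespace are ignored.  Both strings
    empty scores 100; exactly one empty scores 0.
    """
    x, y = _normalise(a), _normalise(b)
    if len(x) > len(y):
        x, y = y, x
    m = len(x)
    if m == 0:
        return 100.0 if len(y) == 0 else 0.0
    best = 0.0
    for i in range(len(y) - m + 1):
        d = levenshtein(x, y[i:i + m])
        score = 100.0 * (1.0 - d / m)
        if score > best:
            best = score
            if best == 100.0:
                break
    return best


def best_match(text: str, names: list[str]) -> tuple[int, float]:
    """Index and score of the best-matching product name (ties: first)."""
    best_i, best_s = -1, -1.0
    for i, name in enumerate(names):
        s = partial_ratio(text, name)
        if s > best_s:
            best_i, best_s = i, s
    return best_i, best_s
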