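"""Normalized Levenshtein distance (LDN) and the averaged lexical distance matrix.

The lexical distance between two language varieties is the mean, over all
glosses for which both varieties have a recorded form, of the Levenshtein
edit distance between the two forms divided by the length of the longer
form. Missing entries are excluded pairwise, so each language pair is
averaged over its own set of shared glosses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wordlist_io import MISSING, DistanceMatrix, ValidationError, WordList

__all__ = ["LdnParams", "levenshtein", "ldn", "pairwise_ldn"]


@dataclass(frozen=True)
class LdnParams:
    """Parameters of the LDN matrix construction.

    Missingness handling is fixed to pairwise-complete averaging;
    ``min_shared_glosses`` sets the minimum number of shared glosses a
    pair must have for its mean to be considered defined (default 1).
    """

    min_shared_glosses: int = 1

    def __post_init__(self) -> None:
        if self.min_shared_glosses < 1:
            raise ValueError("min_shared_glosses must be >= 1")


def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character insertions, deletions and
    substitutions turning ``a`` into ``b`` (unit costs, no transpositions).

    The character unit is the Unicode code point.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def ldn(a: str, b: str) -> float:
    """Levenshtein distance normalized by the longer string's length.

    Lies in [0, 1]: 0 iff the forms are identical, 1 when no aligned
    character survives. Undefined (raises) when both strings are empty;
    callers must have excluded missing forms first.
    """
    m = max(len(a), len(b))
    if m == 0:
        raise ValueError("ldn undefined for two empty strings")
    return levenshtein(a, b) / m


def pairwise_ldn(w: WordList, params: LdnParams | None = None) -> DistanceMatrix:
    """Averaged LDN matrix over all variety pairs of a wordlist.

    For each pair the mean runs over exactly the glosses where both
    varieties have a non-missing form (pairwise-complete); the returned
    matrix's ``support`` records that gloss count per pair.

    Raises
    ------
    ValidationError
        If any pair shares fewer than ``params.min_shared_glosses``
        glosses, naming the pair and its support.
    """
    params = params or LdnParams()
    if len(w.varieties) < 2:
        raise ValidationError("need at least 2 varieties")
    n = len(w.varieties)
    values = np.zeros((n, n))
    support = np.zeros((n, n), dtype=int)
    forms = [[w.get(v, g) for g in w.glosses] for v in w.varieties]
    for i in range(n):
        for j in range(i + 1, n):
            total, count = 0.0, 0
            for fa, fb in zip(forms[i], forms[j]):
                if fa is MISSING or fb is MISSING:
                    continue
                total += ldn(fa, fb)
                count += 1
            if count < params.min_shared_glosses:
                raise ValidationError(
                    f"pair ({w.varieties[i]!r}, {w.varieties[j]!r}) shares "
                    f"{count} glosses (< {params.min_shared_glosses})"
                )
            values[i, j] = values[j, i] = total / count
            support[i, j] = support[j, i] = count
    return DistanceMatrix(list(w.varieties), values, kind="lexical", support=support)
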