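"""Compact letter displays for pairwise comparisons.

Groups that share at least one letter are not significantly different;
groups that share no letter are. Letters are assigned with the
insert-and-absorb algorithm, which is deterministic given the input order
(it does not guarantee a minimal number of letters).
"""

from __future__ import annotations

import string
from typing import Sequence

import numpy as np

__all__ = ["compact_letter_display"]


def _absorb(columns: list[set[int]]) -> list[set[int]]:
    """Drop columns that are strict subsets of another column, and duplicates."""
    kept: list[set[int]] = []
    for col in columns:
        if any(col < other for other in columns):
            continue
        if col in kept:
            continue
        kept.append(col)
    return kept


def compact_letter_display(
    labels: Sequence[str], significant: np.ndarray
) -> dict[str, str]:
    """Assign letters to groups from a pairwise significance matrix.

    Parameters
    ----------
    labels
        Group labels, in display order.
    significant
        Square boolean matrix; ``significant[i, j]`` is True when groups
        *i* and *j* differ significantly. Must be symmetric with a False
        diagonal.

    Returns
    -------
    dict mapping each label to its letter string (e.g. ``"a"``, ``"ab"``).
    """
    sig = np.asarray(significant, dtype=bool)
    k = len(labels)
    if sig.shape != (k, k):
        raise ValueError(f"significance matrix must be {k}x{k}, got {sig.shape}")
    if not np.array_equal(sig, sig.T):
        raise ValueError("significance matrix must be symmetric")
    if sig.diagonal().any():
        raise ValueError("a group cannot differ significantly from itself")

    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_columns: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    new_columns.append(col - {i})
                    new_columns.append(col - {j})
                else:
                    new_columns.append(col)
            columns = _absorb(new_columns)

    # Deterministic letter order: sort columns by their smallest member.
    columns.sort(key=lambda col: (min(col) if col else k, sorted(col)))
    alphabet = string.ascii_lowercase
    if len(columns) > len(alphabet):  # pragma: no cover - >26 groups is unrealistic
        alphabet = [
            a + b for a in [""] + list(string.ascii_lowercase) for b in string.ascii_lowercase
        ]
    letters = {lab: "" for lab in labels}
    for letter, col in zip(alphabet, columns):
        for idx in sorted(col):
            letters[labels[idx]] += letter
    return letters
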