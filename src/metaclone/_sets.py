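"""Set-overlap helpers shared by the mutation, neoantigen and TCR analyses."""

from __future__ import annotations

import warnings

import pandas as pd


def jaccard(a: set, b: set) -> float:
    """Jaccard index |A n B| / |A u B|; defined as 0 when both sets are empty."""
    if not a and not b:
        warnings.warn("Jaccard of two empty sets; returning 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(a | b)


def jaccard_matrix(sets: dict[str, set]) -> pd.DataFrame:
    """Symmetric pairwise Jaccard matrix over labelled sets.

    The diagonal is 1 for nonempty sets (0 for empty ones, with a warning
    from :func:`jaccard`).
    """
    labels = list(sets)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            ji = jaccard(sets[a], sets[b])
            mat.loc[a, b] = ji
            mat.loc[b, a] = ji
    return mat


def upper_triangle_pairs(mat: pd.DataFrame) -> pd.Series:
    """Flatten the strict upper triangle of a symmetric labelled matrix into a
    Series indexed by (row, column) pairs in a fixed label order."""
    labels = list(mat.index)
    idx, vals = [], []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            idx.append((a, b))
            vals.append(mat.loc[a, b])
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx))
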