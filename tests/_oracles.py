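"""Independent scoring oracles for alignment tests.

These deliberately share no code with the package's alignment engine:

* :func:`enumerate_global_score` — exponential enumeration of every global
  alignment (tiny inputs only); the ground truth that validates the DP oracle.
* :func:`gotoh_scores_batch` — a vectorized three-state affine-gap DP over a
  batch of equal-length sequence pairs, used for exhaustive screens.

Both use the package's declared gap convention: a gap of length L costs
``gap_open + L * gap_extend``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

MATCH = 2
MISMATCH = -4
GAP_OPEN = -8
GAP_EXTEND = -1

NEG = -10**9


def enumerate_global_score(query: str, ref: str) -> int:
    """Max score over all global alignments by brute-force enumeration.

    State: (i, j, last) where last marks an open query-gap ('q'), ref-gap
    ('r'), or neither; memoized recursion enumerates every alignment path.
    """

    @lru_cache(maxsize=None)
    def go(i: int, j: int, last: str) -> int:
        if i == len(query) and j == len(ref):
            return 0
        best = NEG
        if i < len(query) and j < len(ref):
            s = MATCH if query[i] == ref[j] else MISMATCH
            best = max(best, s + go(i + 1, j + 1, "m"))
        if i < len(query):  # query base against a gap in ref (insertion)
            cost = GAP_EXTEND if last == "q" else GAP_OPEN + GAP_EXTEND
            best = max(best, cost + go(i + 1, j, "q"))
        if j < len(ref):  # ref base against a gap in query (deletion)
            cost = GAP_EXTEND if last == "r" else GAP_OPEN + GAP_EXTEND
            best = max(best, cost + go(i, j + 1, "r"))
        return best

    return go(0, 0, "m")


def gotoh_scores_batch(queries: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Affine-gap global scores for a batch of encoded sequence pairs.

    ``queries``: (B, m) and ``refs``: (B, n) integer-coded arrays.  Returns
    (B,) optimal scores via the Gotoh three-matrix recurrence, vectorized
    over the batch dimension.
    """
    B, m = queries.shape
    _, n = refs.shape
    M = np.full((B, m + 1, n + 1), NEG, dtype=np.int64)  # ends in (mis)match
    X = np.full((B, m + 1, n + 1), NEG, dtype=np.int64)  # gap in ref (query base)
    Y = np.full((B, m + 1, n + 1), NEG, dtype=np.int64)  # gap in query (ref base)
    M[:, 0, 0] = 0
    for i in range(1, m + 1):
        X[:, i, 0] = GAP_OPEN + GAP_EXTEND * i
    for j in range(1, n + 1):
        Y[:, 0, j] = GAP_OPEN + GAP_EXTEND * j
    for i in range(1, m + 1):
        sub = np.where(queries[:, i - 1 : i] == refs, MATCH, MISMATCH)  # (B, n)
        for j in range(1, n + 1):
            prev = np.maximum.reduce(
                [M[:, i - 1, j - 1], X[:, i - 1, j - 1], Y[:, i - 1, j - 1]]
            )
            M[:, i, j] = prev + sub[:, j - 1]
            X[:, i, j] = np.maximum(
                np.maximum(M[:, i - 1, j], Y[:, i - 1, j]) + GAP_OPEN + GAP_EXTEND,
                X[:, i - 1, j] + GAP_EXTEND,
            )
            Y[:, i, j] = np.maximum(
                np.maximum(M[:, i, j - 1], X[:, i, j - 1]) + GAP_OPEN + GAP_EXTEND,
                Y[:, i, j - 1] + GAP_EXTEND,
            )
    return np.maximum.reduce([M[:, m, n], X[:, m, n], Y[:, m, n]])


def all_sequences(alphabet: str, length: int) -> list[str]:
    if length == 0:
        return [""]
    shorter = all_sequences(alphabet, length - 1)
    return [s + c for s in shorter for c in alphabet]
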