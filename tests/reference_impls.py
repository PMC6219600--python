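"""Independent reference implementations used as oracles in tests.

These deliberately avoid the package's code paths: the UPGMA oracle
recomputes every inter-cluster distance as a direct mean over original
leaf pairs (no Lance-Williams update), the Pearson oracle uses the
long-hand textbook sums, and the specificity oracle evaluates the
per-marker truth table exhaustively.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


def longhand_pearson(x, y) -> float:
    """Textbook Pearson r via explicit sums (no numpy vectorized moments)."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def naive_upgma(d: pd.DataFrame):
    """Average-linkage agglomeration computing each cluster distance as the
    plain mean of original leaf-pair distances; lexicographic tie rule.

    Returns the merge list [(sorted_leaves_a, sorted_leaves_b, height), ...].
    """
    labels = list(d.index)
    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            dist = float(np.mean([[d.loc[i, j] for j in b] for i in a]))
            key = tuple(sorted(("".join(sorted(a)), "".join(sorted(b)))))
            cand = (dist, key, (a, b))
            if best is None or cand < best:
                best = cand
        dist, _, (a, b) = best
        merges.append((sorted(a), sorted(b), dist / 2.0))
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(tuple(sorted(a + b)))
    return merges


def truthtable_specific(scores: pd.DataFrame, species_of: dict, focal: str,
                        background: list[str], missing_policy: str) -> list[str]:
    """Exhaustive per-marker evaluation of the species-specific rule.

    ``scores``: markers x samples with NaN missing; ``species_of``: sample ->
    species. Present = any focal sample scores 1. Absent in a background
    species: no sample scores 1, and under ``strict`` no missing call either.
    """
    result = []
    for marker in scores.index:
        row = scores.loc[marker]
        focal_vals = [row[s] for s in scores.columns if species_of[s] == focal]
        if not any(v == 1 for v in focal_vals if not pd.isna(v)):
            continue
        ok = True
        for other in background:
            vals = [row[s] for s in scores.columns if species_of[s] == other]
            if any(v == 1 for v in vals if not pd.isna(v)):
                ok = False
                break
            if missing_policy == "strict" and any(pd.isna(v) for v in vals):
                ok = False
                break
        if ok:
            result.append(marker)
    return result
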