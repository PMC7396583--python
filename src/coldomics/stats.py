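"""Multiple-comparison letters for group summaries.

One-way ANOVA across groups followed by pairwise comparisons — Tukey's HSD
by default, Fisher's protected LSD as an alternative — rendered as a compact
letter display (groups sharing a letter are not significantly different at
alpha). Letters are assigned to the maximal cliques of the
non-significance graph, ordered by descending group mean, which is the
standard presentation in agronomy tables.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["pairwise_significance", "compact_letters"]


def pairwise_significance(
    groups: dict[str, np.ndarray], alpha: float = 0.05, method: str = "tukey"
) -> dict[tuple[str, str], bool]:
    """Whether each group pair differs significantly.

    ``method='tukey'``: Tukey HSD on all pairs. ``method='lsd'``: Fisher's
    protected LSD — pairwise t-tests with the pooled ANOVA error, gated on a
    significant omnibus F. Degenerate inputs (constant data, <2 replicates
    anywhere) yield no significant pairs.
    """
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    pairs = list(itertools.combinations(range(len(names)), 2))
    out = {(names[i], names[j]): False for i, j in pairs}
    if len(names) < 2 or any(len(a) < 2 for a in arrays):
        return out
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return out

    if method == "tukey":
        data = np.concatenate(arrays)
        labels = np.concatenate([[n] * len(a) for n, a in zip(names, arrays)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pairwise_tukeyhsd(data, labels, alpha=alpha)
        for (g1, g2), reject in zip(itertools.combinations(res.groupsunique, 2), res.reject):
            out[(str(g1), str(g2))] = bool(reject)
        return out

    if method != "lsd":
        raise ValueError(f"unknown method {method!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_p = stats.f_oneway(*arrays).pvalue
    if not np.isfinite(f_p) or f_p >= alpha:
        return out
    # pooled within-group mean square
    df_err = sum(len(a) - 1 for a in arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_err
    for i, j in pairs:
        a, b = arrays[i], arrays[j]
        se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
        if se == 0:
            continue
        t = abs(a.mean() - b.mean()) / se
        p = 2 * stats.t.sf(t, df_err)
        out[(names[i], names[j])] = p < alpha
    return out


def compact_letters(
    groups: dict[str, np.ndarray], alpha: float = 0.05, method: str = "tukey"
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter do not differ at alpha."""
    names = sorted(groups, key=lambda n: -np.mean(groups[n]) if len(groups[n]) else 0.0)
    if not names:
        return {}
    sig = pairwise_significance(groups, alpha=alpha, method=method)

    def differs(a: str, b: str) -> bool:
        return sig.get((a, b), sig.get((b, a), False))

    # maximal cliques of the non-significance graph (group counts are tiny)
    cliques: list[tuple[str, ...]] = []
    for r in range(len(names), 0, -1):
        for combo in itertools.combinations(names, r):
            if any(set(combo) <= set(c) for c in cliques):
                continue
            if all(not differs(a, b) for a, b in itertools.combinations(combo, 2)):
                cliques.append(combo)
    # order cliques by the largest member mean so 'a' tags the top group
    cliques.sort(key=lambda c: -max(np.mean(groups[n]) for n in c))
    letters = {n: "" for n in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for n in clique:
            letters[n] += letter
    return {n: "".join(sorted(v)) for n, v in letters.items()}
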