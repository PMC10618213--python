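"""Fisher-Pitman permutation tests for hotspot / non-hotspot contrasts.

The Fisher-Pitman test compares raw group means (equivalently, the sum of
one group) under the permutation distribution obtained by reshuffling
group labels — no distributional assumption beyond exchangeability under
the null. Exact enumeration of all label partitions is used automatically
when feasible; otherwise a seeded Monte-Carlo sample of permutations with
the add-one p-value convention p = (1 + #extreme) / (n_perm + 1).

The k-sample statistic is the between-group sum of squares, which for
k = 2 is a monotone transform of the two-sample statistic. Post-hoc
pairwise comparisons use single-step max-T adjustment (the permutation
analogue of Tukey-style multiplicity control) with Holm as a
deterministic fallback, and report a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "fisher_pitman_two_sample",
    "fisher_pitman_k_sample",
    "posthoc_pairwise",
    "PosthocResult",
]

_DEFAULT_EXACT_CAP = 50_000


def _tol(values: np.ndarray) -> float:
    scale = float(np.abs(values).max(initial=1.0))
    return 1e-9 * max(1.0, scale)


def fisher_pitman_two_sample(
    x,
    y,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
    exact_cap: int = _DEFAULT_EXACT_CAP,
) -> tuple[float, float]:
    """Two-sample Fisher-Pitman permutation test.

    The statistic is the sum of the first group's values. Returns
    ``(statistic, p)``. When the number of label partitions C(n, n1) is at
    most ``exact_cap`` the p-value is exact (proportion of partitions as
    or more extreme); otherwise it is a seeded Monte-Carlo estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    obs = float(x.sum())
    center = n1 * pooled.mean()
    tol = _tol(pooled)

    def extreme(sums: np.ndarray) -> np.ndarray:
        if alternative == "greater":
            return sums >= obs - tol
        if alternative == "less":
            return sums <= obs + tol
        if alternative == "two-sided":
            return np.abs(sums - center) >= abs(obs - center) - tol
        raise ValueError(f"unknown alternative {alternative!r}")

    n_comb = comb(n, n1)
    if n_comb <= exact_cap:
        sums = np.fromiter(
            (pooled[list(c)].sum() for c in combinations(range(n), n1)),
            dtype=float,
            count=n_comb,
        )
        p = float(extreme(sums).sum()) / n_comb
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        chunk = 4096
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            order = np.argsort(rng.random((m, n)), axis=1)[:, :n1]
            sums = pooled[order].sum(axis=1)
            hits += int(extreme(sums).sum())
            done += m
        p = (1 + hits) / (n_perm + 1)
    return obs, p


def _between_ss(values: np.ndarray, sizes: np.ndarray) -> float:
    grand = values.mean()
    out = 0.0
    start = 0
    for s in sizes:
        m = values[start : start + s].mean()
        out += s * (m - grand) ** 2
        start += s
    return float(out)


def _enumerate_partitions(values: np.ndarray, sizes: np.ndarray):
    """Yield the between-group SS over all distinct index partitions."""

    def rec(remaining: tuple[int, ...], gi: int, assigned: list[np.ndarray]):
        if gi == len(sizes) - 1:
            parts = assigned + [np.array(remaining)]
            arranged = np.concatenate([values[p] for p in parts])
            yield _between_ss(arranged, sizes)
            return
        for c in combinations(remaining, int(sizes[gi])):
            rest = tuple(i for i in remaining if i not in set(c))
            yield from rec(rest, gi + 1, assigned + [np.array(c)])

    yield from rec(tuple(range(values.size)), 0, [])


def fisher_pitman_k_sample(
    groups: list,
    n_perm: int = 10_000,
    seed: int = 0,
    exact_cap: int = _DEFAULT_EXACT_CAP,
) -> tuple[float, float]:
    """k-sample Fisher-Pitman test on the between-group sum of squares."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate(arrays)
    sizes = np.array([a.size for a in arrays])
    obs = _between_ss(pooled, sizes)
    tol = _tol(pooled) ** 2 + 1e-12

    n_arrangements = 1
    remaining = int(sizes.sum())
    for s in sizes[:-1]:
        n_arrangements *= comb(remaining, int(s))
        remaining -= int(s)
    if n_arrangements <= exact_cap:
        stats = np.fromiter(
            _enumerate_partitions(pooled, sizes), dtype=float, count=n_arrangements
        )
        p = float((stats >= obs - tol).sum()) / n_arrangements
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            hits += _between_ss(perm, sizes) >= obs - tol
        p = (1 + hits) / (n_perm + 1)
    return obs, p


@dataclass
class PosthocResult:
    """Pairwise permutation comparisons with multiplicity adjustment."""

    pairs: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_adj
    letters: dict[str, str]
    alpha: float
    adjust: str


def _pair_t(values: np.ndarray, labels: np.ndarray, a, b) -> float:
    va, vb = values[labels == a], values[labels == b]
    na, nb = va.size, vb.size
    pooled_var = (
        ((na - 1) * va.var(ddof=1) + (nb - 1) * vb.var(ddof=1)) / (na + nb - 2)
        if na + nb > 2
        else 0.0
    )
    denom = np.sqrt(max(pooled_var, 1e-300) * (1 / na + 1 / nb))
    return abs(va.mean() - vb.mean()) / denom


def _letters_from_graph(names: list[str], nsd: set[frozenset]) -> dict[str, str]:
    """Compact letter display from the not-significantly-different graph."""
    g = nx.Graph()
    g.add_nodes_from(range(len(names)))
    index = {n: i for i, n in enumerate(names)}
    for pair in nsd:
        a, b = tuple(pair)
        g.add_edge(index[a], index[b])
    cliques = sorted(nx.find_cliques(g), key=lambda c: (min(c), -len(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {n: [] for n in names}
    for li, clique in enumerate(cliques):
        for node in clique:
            letters[names[node]].append(alphabet[li])
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def posthoc_pairwise(
    groups: dict[str, np.ndarray],
    n_perm: int = 10_000,
    seed: int = 0,
    adjust: str = "maxT",
    alpha: float = 0.05,
) -> PosthocResult:
    """All pairwise two-sample permutation tests with multiplicity control.

    ``adjust="maxT"`` uses single-step adjustment against the joint
    permutation distribution of the maximum standardized pairwise
    statistic (Tukey-style familywise control); ``adjust="holm"`` applies
    the Holm step-down to the raw Monte-Carlo p-values. Groups sharing a
    letter in the compact letter display are not significantly different
    at ``alpha``.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("need >= 3 groups; use fisher_pitman_two_sample for two")
    arrays = {n: np.asarray(groups[n], dtype=float) for n in names}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("every group must be non-empty")
    values = np.concatenate([arrays[n] for n in names])
    labels = np.concatenate([np.full(arrays[n].size, n, dtype=object) for n in names])
    pairs = list(combinations(names, 2))
    obs_t = {p: _pair_t(values, labels, *p) for p in pairs}

    rng = np.random.default_rng(seed)
    raw_hits = {p: 0 for p in pairs}
    max_hits = {p: 0 for p in pairs}
    for _ in range(n_perm):
        perm_vals = rng.permutation(values)
        ts = {p: _pair_t(perm_vals, labels, *p) for p in pairs}
        t_max = max(ts.values())
        for p in pairs:
            raw_hits[p] += ts[p] >= obs_t[p] - 1e-12
            max_hits[p] += t_max >= obs_t[p] - 1e-12
    p_raw = {p: (1 + raw_hits[p]) / (n_perm + 1) for p in pairs}
    if adjust == "maxT":
        p_adj = {p: (1 + max_hits[p]) / (n_perm + 1) for p in pairs}
    elif adjust == "holm":
        order = sorted(pairs, key=lambda p: p_raw[p])
        m = len(pairs)
        p_adj, running = {}, 0.0
        for i, p in enumerate(order):
            running = max(running, min(1.0, (m - i) * p_raw[p]))
            p_adj[p] = running
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    nsd = {frozenset(p) for p in pairs if p_adj[p] >= alpha}
    letters = _letters_from_graph(names, nsd)
    frame = pd.DataFrame(
        {
            "group_a": [p[0] for p in pairs],
            "group_b": [p[1] for p in pairs],
            "statistic": [obs_t[p] for p in pairs],
            "p_raw": [p_raw[p] for p in pairs],
            "p_adj": [p_adj[p] for p in pairs],
        }
    )
    return PosthocResult(pairs=frame, letters=letters, alpha=alpha, adjust=adjust)
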