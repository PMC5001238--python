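"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible from the definitions
(path enumeration, triple loops) and deliberately shares no code with the
package's optimized implementations.
"""

from __future__ import annotations

import math


def brute_ancestors(parents: dict[str, set[str]], term: str) -> set[str]:
    """Reflexive ancestor set by exhaustive path enumeration (DFS on edges)."""
    seen: set[str] = set()
    stack = [term]
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        stack.extend(parents.get(t, ()))
    return seen


def brute_propagate(parents: dict[str, set[str]], terms: set[str]) -> set[str]:
    out: set[str] = set()
    for t in terms:
        out |= brute_ancestors(parents, t)
    return out


def brute_ic(parents: dict[str, set[str]], gene_terms: dict[str, set[str]]) -> dict[str, float]:
    """IC from first principles: propagate every gene, count memberships."""
    closed = {g: brute_propagate(parents, ts) for g, ts in gene_terms.items() if ts}
    universe = len(closed)
    counts: dict[str, int] = {}
    for ts in closed.values():
        for t in ts:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / universe) for t, c in counts.items()}


def brute_term_sim(parents: dict[str, set[str]], ic: dict[str, float],
                   t1: str, t2: str) -> float:
    common = brute_ancestors(parents, t1) & brute_ancestors(parents, t2)
    vals = [ic[a] for a in common if a in ic]
    return max(vals) if vals else 0.0


def brute_directed_sim(parents: dict[str, set[str]], ic: dict[str, float],
                       p1: set[str], p2: set[str]) -> float:
    """Triple loop over p1 terms x p2 terms x common ancestors."""
    t1s = [t for t in p1 if t in ic]
    t2s = [t for t in p2 if t in ic]
    total = 0.0
    for t1 in t1s:
        total += max(brute_term_sim(parents, ic, t1, t2) for t2 in t2s)
    return total / len(t1s)


def brute_profile_sim(parents: dict[str, set[str]], ic: dict[str, float],
                      p1: set[str], p2: set[str]) -> float:
    return 0.5 * (brute_directed_sim(parents, ic, p1, p2)
                  + brute_directed_sim(parents, ic, p2, p1))


def brute_average_precision(order: list[str], positives: set[str]) -> float:
    """AP straight from the definition: mean precision at each hit rank."""
    found = [d for d in order if d in positives]
    if not found:
        raise ValueError("no positives in list")
    hits = 0
    precisions = []
    for i, d in enumerate(order, start=1):
        if d in positives:
            hits += 1
            precisions.append(hits / i)
    return sum(precisions) / len(found)


def brute_paired_t(a: list[float], b: list[float]) -> tuple[float, float]:
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), two-sided p."""
    from scipy.stats import t as tdist

    n = len(a)
    d = [x - y for x, y in zip(a, b)]
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2.0 * tdist.sf(abs(t), df=n - 1)
    return t, p
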