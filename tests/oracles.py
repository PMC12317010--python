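"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately takes a different computational route from the
package code it checks: exhaustive multinomial enumeration instead of
polynomial convolution for isotope patterns, direct hypergeometric
enumeration with integer combinatorics for Fisher's test, and a plain
linear scan for screening.
"""

from __future__ import annotations

from itertools import product
from math import comb, factorial

from dtims.isotopes import ISOTOPES


def _element_isotopologues(el: str, count: int) -> dict[int, float]:
    """Distribution of nominal mass offsets for `count` atoms of element `el`,
    by exhaustive enumeration of isotope count vectors with multinomial weights."""
    isos = ISOTOPES[el]
    offsets = [round(m - isos[0][0]) for m, _ in isos]
    abunds = [a for _, a in isos]
    k = len(isos)
    dist: dict[int, float] = {}
    # enumerate all (n_1, ..., n_k) with sum == count
    def rec(pos: int, left: int, vec: list[int]) -> None:
        if pos == k - 1:
            vec = vec + [left]
            weight = factorial(count)
            p = 1.0
            for n_i, a_i in zip(vec, abunds):
                weight //= factorial(n_i)
                p *= a_i**n_i
            off = sum(n_i * o_i for n_i, o_i in zip(vec, offsets))
            dist[off] = dist.get(off, 0.0) + weight * p
            return
        for n in range(left + 1):
            rec(pos + 1, left - n, vec + [n])

    rec(0, count, [])
    return dist


def isotope_pattern_oracle(formula: dict[str, int], n_peaks: int) -> list[float]:
    """M, M+1, ... abundances relative to the base peak, by full enumeration."""
    total: dict[int, float] = {0: 1.0}
    for el, count in formula.items():
        eldist = _element_isotopologues(el, count)
        new: dict[int, float] = {}
        for o1, p1 in total.items():
            for o2, p2 in eldist.items():
                new[o1 + o2] = new.get(o1 + o2, 0.0) + p1 * p2
        total = new
    base = max(total.values())
    return [total.get(k, 0.0) / base for k in range(n_peaks)]


def fisher_two_sided_oracle(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration (math.comb only).

    Margins fixed; p sums the probabilities of all tables no more probable
    than the observed one (1e-12 relative slack on the comparison).
    """
    r1, r2 = n11 + n10, n01 + n00
    c1 = n11 + n01
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[n11]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def screen_scan_oracle(query, entries, ppm_tol: float, ccs_tol: float):
    """Linear-scan suspect screening: returns list of (chemical_id, ion_type,
    mode, score, ccs_pct_diff) in the package's documented sort order."""
    hits = []
    for e in entries:
        if e["mode"] != query.mode:
            continue
        if query.ion_type is not None and e["ion_type"] != query.ion_type:
            continue
        lib_mz = e["mz_measured_mean"]
        ppm = 1e6 * (query.mz - lib_mz) / lib_mz
        pct = 200.0 * abs(query.ccs - e["ccs_mean_A2"]) / (query.ccs + e["ccs_mean_A2"])
        if abs(ppm) <= ppm_tol and pct <= ccs_tol:
            score = (1 - abs(ppm) / ppm_tol) * (1 - pct / ccs_tol)
            hits.append((e["chemical_id"], e["ion_type"], e["mode"], score, pct))
    hits.sort(key=lambda h: (-h[3], h[4], h[0]))
    return hits


def venn_regions_oracle(matrix_rows: dict[str, tuple[bool, bool, bool]], modes):
    """Exhaustive set-algebra mode-overlap partition."""
    sets = {m: {cid for cid, flags in matrix_rows.items() if flags[i]}
            for i, m in enumerate(modes)}
    regions = {}
    for mask in range(1, 2 ** len(modes)):
        combo = [m for i, m in enumerate(modes) if mask >> i & 1]
        inside = set.intersection(*(sets[m] for m in combo)) if combo else set()
        outside = set.union(*(sets[m] for m in modes if m not in combo), set())
        regions["&".join(combo)] = len(inside - outside)
    return regions
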