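"""Slow brute-force reference implementations for cross-checking.

These deliberately share no code with the fast paths they validate:
the segment caller is checked against an O(n^2) enumeration of every
sub-interval, and the exact Hardy-Weinberg test against direct
summation of log-gamma multinomial probabilities.  Used by the test
suite and the acceptance script; far too slow for production data.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .detect import ROHParams, ROHSegment
from .model import HET, HOM_ALT, HOM_REF, MISSING


def hwe_pvalue_by_enumeration(
    n_hom_ref: int, n_het: int, n_hom_alt: int, *, midp: bool = False
) -> float:
    """Two-sided exact HWE p-value by direct summation.

    Enumerates every heterozygote count compatible with the observed
    allele counts, computes each outcome's conditional probability from
    the closed-form expression

        P(h) = n! / (r! h! c!) * 2^h * nA! * nB! / (2n)!

    via log-gamma, and sums the probabilities at most as large as the
    observed one (same 1+1e-12 tie tolerance as the production test).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1 or min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("invalid genotype counts")
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    log_const = (
        math.lgamma(n + 1)
        + math.lgamma(n_a + 1)
        + math.lgamma(n_b + 1)
        - math.lgamma(2 * n + 1)
    )

    def log_prob(h: int) -> float:
        r = (n_a - h) // 2
        c = (n_b - h) // 2
        return (
            log_const
            + h * math.log(2.0)
            - math.lgamma(r + 1)
            - math.lgamma(h + 1)
            - math.lgamma(c + 1)
        )

    rare = min(n_a, n_b)
    support = range(rare % 2, rare + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in support}
    p_obs = probs[n_het]
    tail = sum(p for p in probs.values() if p <= p_obs * (1.0 + 1e-12))
    if midp:
        tail -= 0.5 * p_obs
    return min(tail, 1.0)


def enumerate_roh_segments(
    flagged: Sequence[bool],
    calls: Sequence[int],
    positions: Sequence[int],
    params: ROHParams,
    *,
    family_id: str = "0",
    individual_id: str = "0",
    chromosome: int = 0,
) -> list[ROHSegment]:
    """Exhaustive sub-interval enumeration of ROH segments.

    An index interval [i, j] is *admissible* when every SNP in it is
    flagged and non-terminating (heterozygous calls terminate unless
    ``het_terminates`` is off) and no two adjacent SNPs in it are more
    than ``max_gap_kb`` apart.  Maximal admissible intervals (those not
    contained in a longer admissible interval) are trimmed to homozygous
    endpoints and kept if they satisfy the min-SNP, min-length and
    density constraints.  O(n^2); for validation only.
    """
    flagged = list(flagged)
    calls = list(calls)
    positions = list(positions)
    n = len(calls)
    gap_bp = params.max_gap_kb * 1000.0

    def ok(k: int) -> bool:
        if not flagged[k]:
            return False
        if params.het_terminates and calls[k] == HET:
            return False
        return True

    def admissible(i: int, j: int) -> bool:
        for k in range(i, j + 1):
            if not ok(k):
                return False
        for k in range(i, j):
            if positions[k + 1] - positions[k] > gap_bp:
                return False
        return True

    maximal: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i, n):
            if not admissible(i, j):
                continue
            left_ext = i > 0 and admissible(i - 1, j)
            right_ext = j < n - 1 and admissible(i, j + 1)
            if not left_ext and not right_ext:
                maximal.append((i, j))

    out: list[ROHSegment] = []
    for i, j in maximal:
        hom = [k for k in range(i, j + 1) if calls[k] in (HOM_REF, HOM_ALT)]
        if not hom:
            continue
        a, b = hom[0], hom[-1]
        n_hom = len(hom)
        length = positions[b] - positions[a] + 1
        if n_hom < params.min_snps:
            continue
        if length < params.min_length_kb * 1000.0:
            continue
        if length / n_hom > params.max_density_kb_per_snp * 1000.0:
            continue
        out.append(
            ROHSegment(family_id, individual_id, chromosome,
                       int(positions[a]), int(positions[b]), n_hom)
        )
    out.sort(key=lambda s: s.start_bp)
    return out


def count_windows_direct(
    calls: Sequence[int], params: ROHParams
) -> list[bool]:
    """Per-window recount of heterozygous/missing calls, loop-by-loop."""
    n = len(calls)
    k = params.window_snps
    out = []
    for w in range(max(0, n - k + 1)):
        window = calls[w : w + k]
        n_het = sum(1 for c in window if c == HET)
        n_mis = sum(1 for c in window if c == MISSING)
        out.append(n_het <= params.window_max_het
                   and n_mis <= params.window_max_missing)
    return out


__all__ = [
    "hwe_pvalue_by_enumeration",
    "enumerate_roh_segments",
    "count_windows_direct",
]
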