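"""Independent brute-force reference implementations used only by the tests.

Deliberately naive: explicit per-window enumeration, per-base bitmaps and
per-read latent-state sums, sharing no code with the package internals.
"""

import itertools

import numpy as np

from erodescan.matrix import HET, MISSING


def bitmap_union_length(intervals, span):
    """Total covered bases of half-open intervals via a per-base boolean array."""
    hit = np.zeros(span, dtype=bool)
    for s, e in intervals:
        hit[s:e] = True
    return int(hit.sum())


def window_fractions_bruteforce(calls, params):
    """Per-SNP homozygous-window fraction by enumerating every window."""
    calls = np.asarray(calls)
    n = calls.size
    w = params.window_snp
    if n == 0:
        return np.zeros(0)
    if n < w:
        ok = ((calls == HET).sum() <= params.window_het_max
              and (calls == MISSING).sum() <= params.window_missing_max)
        return np.full(n, 1.0 if ok else 0.0)
    hom = []
    for i in range(n - w + 1):
        win = calls[i:i + w]
        hom.append((win == HET).sum() <= params.window_het_max
                   and (win == MISSING).sum() <= params.window_missing_max)
    frac = np.zeros(n)
    for j in range(n):
        covering = [hom[i] for i in range(max(0, j - w + 1),
                                          min(j, n - w) + 1)]
        frac[j] = sum(covering) / len(covering)
    return frac


def roh_segments_bruteforce(calls, positions, params):
    """Direct-scan segment calling; returns (start, end, n_snps) tuples."""
    frac = window_fractions_bruteforce(calls, params)
    qualifying = frac >= params.hit_threshold
    runs, current = [], []
    for j in range(len(calls)):
        if qualifying[j]:
            current.append(j)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)

    segments = []
    for run in runs:
        piece = [run[0]]
        pieces = []
        for j in run[1:]:
            if positions[j] - positions[piece[-1]] > params.gap_max_kb * 1000:
                pieces.append(piece)
                piece = []
            piece.append(j)
        pieces.append(piece)
        for piece in pieces:
            n_snps = len(piece)
            start = positions[piece[0]] - 1
            end = positions[piece[-1]]
            length = end - start
            if (n_snps >= params.seg_min_snp
                    and length >= params.seg_min_kb * 1000
                    and n_snps * params.density_kb_per_snp * 1000 >= length):
                segments.append((int(start), int(end), n_snps))
    return segments


def profile_likelihood_enumeration(n_ref, n_alt, theta, epsilon):
    """Site likelihood by summing over latent genotype and per-read states.

    Homozygous branch: for each candidate true allele, enumerate per-read
    error indicators; keep the better allele.  Heterozygous branch:
    enumerate per-read (chosen allele, error) pairs.  Feasible for depth <= 8.
    """
    n = n_ref + n_alt
    if n == 0:
        return 1.0

    def hom_prob(true_is_ref):
        total = 0.0
        for errors in itertools.product([0, 1], repeat=n):
            k_alt = sum(e if true_is_ref else 1 - e for e in errors)
            if k_alt != n_alt:
                continue
            p = 1.0
            for e in errors:
                p *= epsilon if e else 1 - epsilon
            total += p
        return total

    p_hom = max(hom_prob(True), hom_prob(False))

    p_het = 0.0
    for choices in itertools.product([0, 1], repeat=n):      # 1 = alt chosen
        for errors in itertools.product([0, 1], repeat=n):
            k_alt = sum(c ^ e for c, e in zip(choices, errors))
            if k_alt != n_alt:
                continue
            p = 1.0
            for e in errors:
                p *= 0.5 * (epsilon if e else 1 - epsilon)
            p_het += p

    return (1 - theta) * p_hom + theta * p_het
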