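"""Independent brute-force oracles used by the property/acceptance tests.

Deliberately naive implementations that share no code with the package:
exhaustive enumeration for the tandem-repeat finder and a regex scan for the
WGCW counter.
"""
import re

ACGT = set("ACGT")


def regex_wgcw_count(seq: str) -> int:
    """Overlapping [AT]GC[AT] matches via lookahead regex."""
    return len(re.findall(r"(?=[AT]GC[AT])", seq.upper()))


def brute_force_repeats(seq, period_max=12, min_score=60, match=2, mismatch=-7):
    """Enumerate every (start, end, period) segment, apply the same scoring
    and greedy disjoint selection, and return (period, start, end, score)
    tuples sorted by start."""
    seq = seq.upper()
    n = len(seq)
    candidates = []
    for p in range(1, period_max + 1):
        if n < 2 * p:
            break
        scored = [
            match if (seq[i] == seq[i - p] and seq[i] in ACGT) else mismatch
            for i in range(p, n)
        ]
        m = len(scored)
        segments = []
        for g in range(m):
            total = 0
            for e in range(g + 1, m + 1):
                total += scored[e - 1]
                if total >= min_score:
                    segments.append((total, g, e))
        # greedy: best score, then smallest end, then shortest (largest start)
        segments.sort(key=lambda t: (-t[0], t[2], -t[1]))
        taken = []
        for s, g, e in segments:
            if any(g < te and tg < e for _s, tg, te in taken):
                continue
            taken.append((s, g, e))
        for s, g, e in taken:
            start, end = g, p + e
            if end - start >= 2 * p:
                candidates.append((s, p, start, end))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    accepted = []
    for cand in candidates:
        _s, _p, start, end = cand
        if any(start < ae and astart < end for _, _, astart, ae in accepted):
            continue
        accepted.append(cand)
    return sorted((p, start, end, s) for s, p, start, end in accepted)
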