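"""Independent brute-force oracle for global alignment scores.

Enumerates every global alignment of two short strings by plain recursion
(no memoization, no DP table) and returns the best achievable score under a
match/mismatch/linear-gap scheme.  Exponential in the input lengths, so only
usable for strings of length <= ~8 — which is the point: it shares no
machinery with the dynamic-programming implementation it checks.
"""

from __future__ import annotations

import math


def brute_force_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Best global alignment score over exhaustive enumeration."""
    if not a and not b:
        return 0.0
    best = -math.inf
    if a and b:
        sub = match if a[0] == b[0] else mismatch
        best = max(best, sub + brute_force_score(a[1:], b[1:], match, mismatch, gap))
    if a:
        best = max(best, gap + brute_force_score(a[1:], b, match, mismatch, gap))
    if b:
        best = max(best, gap + brute_force_score(a, b[1:], match, mismatch, gap))
    return best
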