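"""Independent brute-force oracles used to cross-check the implementation.

These deliberately recompute everything the slow, obvious way (explicit
per-window loops, a from-scratch stack matcher) and share no code with the
package internals.
"""

import numpy as np

TIERS = {"(": ")", "[": "]", "{": "}", "<": ">"}


def naive_bpc(pairing, window):
    """Per-position percent paired over the truncated window, O(N*W)."""
    n = len(pairing)
    h = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        members = range(max(0, i - h), min(n - 1, i + h) + 1)
        paired = sum(1 for j in members if pairing[j] > 0)
        out[i] = 100.0 * paired / len(list(members))
    return out


def naive_median_smooth(values, window):
    """Per-position median of non-missing values over the truncated window."""
    n = len(values)
    h = (window - 1) // 2
    out = np.full(n, np.nan)
    for i in range(n):
        chunk = np.asarray(values[max(0, i - h): i + h + 1], dtype=float)
        chunk = chunk[~np.isnan(chunk)]
        if chunk.size:
            out[i] = np.median(chunk)
    return out


def stack_match(line):
    """Brute-force per-tier stack matcher: returns the 1-based pairing vector."""
    pairing = [0] * len(line)
    for opener, closer in TIERS.items():
        stack = []
        for pos, ch in enumerate(line, start=1):
            if ch == opener:
                stack.append(pos)
            elif ch == closer:
                j = stack.pop()
                pairing[j - 1] = pos
                pairing[pos - 1] = j
        assert not stack, f"unbalanced {opener}{closer}"
    return pairing


def naive_bin_counts(mask, bin_size):
    """Count True entries per non-overlapping bin by explicit iteration."""
    n = len(mask)
    rows = []
    start = 1
    while start <= n:
        end = min(start + bin_size - 1, n)
        count = sum(bool(mask[i - 1]) for i in range(start, end + 1))
        rows.append((start, end, count, 100.0 * count / (end - start + 1)))
        start = end + 1
    return rows
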