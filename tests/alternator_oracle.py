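"""Brute-force segmentation oracle for the summit-valley-alternator.

Re-derives the scan from its definition with explicit nested loops,
independently of the implementation: repeatedly find the first position
whose value drops below delta times the running maximum (emitting the
leftmost position attaining that maximum), then the first position
rising strictly above the running minimum divided by delta, and restart
there.  Also records, per summit, the stretch it was the maximum of.
"""

import math


def alternator_oracle(seg, delta, with_stretches=False):
    emitted = []
    stretches = []  # (stretch_start, drop_index_or_n) per emitted summit
    n = len(seg)
    i = 0
    while i < n:
        best = -math.inf
        best_i = None
        drop = None
        for k in range(i, n):
            if seg[k] > best:
                best = seg[k]
                best_i = k
            if seg[k] < delta * best:
                drop = k
                break
        if drop is None:
            emitted.append(best_i)
            stretches.append((i, n))
            break
        emitted.append(best_i)
        stretches.append((i, drop))
        vmin = math.inf
        rise = None
        for k in range(drop, n):
            if seg[k] < vmin:
                vmin = seg[k]
            elif seg[k] * delta > vmin:
                rise = k
                break
        if rise is None:
            break
        i = rise
    if with_stretches:
        return emitted, stretches
    return emitted
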