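"""Naive greedy clumping oracle, shared between unit and end-to-end tests.

Deliberately written in the most literal way possible — pairwise loops and
per-pair correlation calls — so it stays independent of the vectorized
implementation it checks.
"""

import numpy as np


def clump_oracle(minp, G, p_thresh, r2_cutoff, window_kb):
    meta = {v.variant_id: (v.chromosome, v.position) for v in G.variants}
    col = {v.variant_id: j for j, v in enumerate(G.variants)}
    cand = [
        (p, meta[i][0], meta[i][1], i)
        for i, p in zip(minp["variant_id"], minp["min_pvalue"])
        if p < p_thresh
    ]
    cand.sort()
    dropped, chosen = set(), []
    for p, ch, pos, i in cand:
        if i in dropped:
            continue
        chosen.append(i)
        for q, ch2, pos2, j in cand:
            if j == i or j in dropped or j in chosen:
                continue
            if ch2 == ch and abs(pos2 - pos) <= window_kb * 1000:
                r = np.corrcoef(G.dosages[:, col[i]], G.dosages[:, col[j]])[0, 1]
                if r**2 > r2_cutoff:
                    dropped.add(j)
    return chosen
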