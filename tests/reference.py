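"""Straight-line brute-force transcription of one interaction round.

Independent of the package's vectorized implementation: works directly on a
networkx graph with per-agent Python loops, evaluating perception, conformity
switching and the bounded-confidence value update exactly as written. Used as
the oracle for small-network equivalence tests.
"""

import numpy as np


def clamp(x):
    return max(-1.0, min(1.0, x))


def brute_force_round(graph, types, values, arousal, gamma, lam, d1, theta1, a, draws=None):
    """One synchronous round on ``graph`` (edges carry a 'strength' attribute).

    ``draws`` replays the per-node uniforms of the Bernoulli switch mode;
    ``draws=None`` uses the deterministic switch rule.
    """
    n = len(types)
    new_t = [int(t) for t in types]
    new_v = [float(v) for v in values]
    for i in range(n):
        if types[i] == 0:
            continue
        nbrs = list(graph.neighbors(i))
        deg = len(nbrs)
        counts = {k: sum(1 for j in nbrs if types[j] == k) for k in (1, 2, 3, 4)}
        if deg == 0 or sum(counts.values()) == 0:
            continue  # inert: nothing to perceive
        best = max(counts.values())
        u = min(k for k in (1, 2, 3, 4) if counts[k] == best)
        pn_iu = counts[u] / deg
        pn_i = counts[int(types[i])] / deg
        t_iu = abs(pn_iu - pn_i) * gamma[i]
        if pn_i > t_iu:
            switch = False
        elif draws is None:
            switch = t_iu > 0
        else:
            switch = draws[i] < t_iu

        def weighted_avg(target):
            num = den = 0.0
            for j in nbrs:
                if types[j] == target:
                    s = graph[i][j]["strength"]
                    num += values[j] * (a * arousal[j]) * lam[i] * s
                    den += s
            return num, den

        if switch:
            num, den = weighted_avg(u)
            new_t[i] = u
            new_v[i] = clamp(num / den)
        else:
            num, den = weighted_avg(int(types[i]))
            if den > 0:
                avg = num / den
                y = values[i]
                if abs(y - avg) < d1:
                    step = theta1 * abs(avg - y)
                    y = y + step if y > 0 else (y - step if y < 0 else y)
                new_v[i] = clamp(y)
    return np.array(new_t), np.array(new_v)
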