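"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (BFS path enumeration,
combinatorial tail sums) and deliberately shares no code with the package's
own computational paths.
"""

from collections import deque
from itertools import combinations
from math import comb


def brute_force_betweenness(nodes, edges):
    """BC(n) over unordered pairs {s,t}, s != n != t, by explicit BFS
    shortest-path counting."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def count_paths(s):
        dist = {s: 0}
        sigma = {s: 1}
        order = []
        q = deque([s])
        while q:
            u = q.popleft()
            order.append(u)
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    q.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        return dist, sigma

    bc = {n: 0.0 for n in nodes}
    node_list = sorted(nodes)
    for s, t in combinations(node_list, 2):
        dist_s, sigma_s = count_paths(s)
        if t not in dist_s:
            continue
        dist_t, sigma_t = count_paths(t)
        d = dist_s[t]
        total = sigma_s[t]
        for n in node_list:
            if n in (s, t) or n not in dist_s or n not in dist_t:
                continue
            if dist_s[n] + dist_t[n] == d:
                bc[n] += sigma_s[n] * sigma_t[n] / total
    return bc


def hypergeom_fisher_two_sided(table):
    """Two-sided Fisher exact p for a 2x2 table by summing hypergeometric
    probabilities no larger than the observed one."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def pmf(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def exact_mannwhitney_two_sided(xs, ys):
    """Exact two-sided Mann-Whitney p by full enumeration of the rank
    arrangements (no ties; small samples only)."""
    n1, n2 = len(xs), len(ys)
    pooled = sorted(xs + ys)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    u_obs = sum(1 for x in xs for y in ys if x > y)
    counts = {}
    for positions in combinations(range(n1 + n2), n1):
        pos = set(positions)
        u = sum(1 for i in positions for j in range(n1 + n2) if j not in pos and i > j)
        counts[u] = counts.get(u, 0) + 1
    total = comb(n1 + n2, n1)
    mean_u = n1 * n2 / 2
    dev = abs(u_obs - mean_u)
    extreme = sum(c for u, c in counts.items() if abs(u - mean_u) >= dev - 1e-9)
    return extreme / total


def yates_chi_square(table):
    """Yates-corrected chi-square statistic from the definition
    sum (|O - E| - 0.5)^2 / E."""
    (a, b), (c, d) = table
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    stat = 0.0
    obs = ((a, b), (c, d))
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (abs(obs[i][j] - e) - 0.5) ** 2 / e
    return stat
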