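"""Independent brute-force oracles used to check the package.

Everything here is written as a literal transcription of the defining
formulas (double loops, O(n^3) agglomeration) and never calls into the
vectorized implementation paths it validates.
"""

import math


def naive_couplings(coords, sigma):
    """Dense Gaussian couplings by explicit double loop."""
    n = len(coords)
    J = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            r2 = sum((coords[i][k] - coords[j][k]) ** 2 for k in range(3))
            J[i][j] = math.exp(-r2 / (4.0 * sigma * sigma))
    return J


def naive_norm(members, J):
    """Double sum of couplings over one residue-index set (diagonal included)."""
    return sum(J[i][j] for i in members for j in members)


def naive_scalar_product(members_a, members_b, J):
    return sum(J[i][j] for i in members_a for j in members_b)


def naive_distance(members_a, members_b, J):
    arg = (
        naive_norm(members_a, J)
        + naive_norm(members_b, J)
        - 2.0 * naive_scalar_product(members_a, members_b, J)
    )
    return math.sqrt(max(arg, 0.0))


def naive_sine(members_a, members_b, J):
    cos = naive_scalar_product(members_a, members_b, J) / math.sqrt(
        naive_norm(members_a, J) * naive_norm(members_b, J)
    )
    cos = min(max(cos, 0.0), 1.0)
    return math.sqrt(1.0 - cos * cos)


def naive_average_linkage(dist, threshold):
    """O(n^3) UPGMA agglomeration with an inclusive distance cut.

    ``dist`` is a full square matrix (list of lists).  Returns the
    partition as a set of frozensets of item indices.  Merge ties are
    broken by the lexicographically smallest index pair.
    """
    n = len(dist)
    clusters = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = sum(
                    dist[i][j] for i in clusters[a] for j in clusters[b]
                ) / (len(clusters[a]) * len(clusters[b]))
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        if d > threshold:
            break
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


def pearson(xs, ys):
    """Covariance over the product of standard deviations, spelled out."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    sx = math.sqrt(sum((x - mx) ** 2 for x in xs) / n)
    sy = math.sqrt(sum((y - my) ** 2 for y in ys) / n)
    return cov / (sx * sy)
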