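"""Independent reference implementations used to verify pipeline output.

These are deliberately naive (repeated full scans, direct combinatorial
enumeration) and share no code with the package internals they check.
"""

from math import comb


def greedy_cluster_oracle(positions: dict, window: int):
    """Brute-force greedy clustering over {(contig, strand, pos): count}.

    Repeatedly scans the full unassigned set for the maximum-count position
    (ties: lexical contig, then strand, then 3'-most on the transcript
    strand), absorbs everything within ±window on the same contig/strand,
    and emits (contig, strand, representative, frozenset of member
    positions).
    """
    unassigned = dict(positions)
    clusters = []
    while unassigned:
        def order(item):
            (contig, strand, pos), count = item
            three_prime = -pos if strand == "+" else pos
            return (-count, contig, strand, three_prime)

        (contig, strand, rep), _ = min(unassigned.items(), key=order)
        members = frozenset(
            p for (c, s, p) in unassigned
            if c == contig and s == strand and abs(p - rep) <= window
        )
        for p in members:
            del unassigned[(contig, strand, p)]
        clusters.append((contig, strand, rep, members))
    return sorted(clusters)


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher exact p-value by exhaustive enumeration of all 2x2
    tables with the observed margins, summing hypergeometric probabilities
    not exceeding the observed table's (probability-mass method)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0:
        return 1.0
    denom = comb(n, row1)

    def weight(k):  # un-normalized hypergeometric mass for table [[k, ...]]
        return comb(col1, k) * comb(n - col1, row1 - k)

    w_obs = weight(a)
    k_min = max(0, row1 - (n - col1))
    k_max = min(row1, col1)
    total = sum(w for k in range(k_min, k_max + 1)
                if (w := weight(k)) <= w_obs)
    return total / denom


def count_motif_oracle(sequence: str, pattern_sets) -> int:
    """Positional sliding-window motif count (overlaps allowed), regex-free.

    ``pattern_sets`` is a sequence of allowed-character sets per position,
    over the RNA alphabet.
    """
    seq = sequence.upper().replace("T", "U")
    k = len(pattern_sets)
    count = 0
    for i in range(len(seq) - k + 1):
        ok = True
        for j in range(k):
            if seq[i + j] not in pattern_sets[j]:
                ok = False
                break
        if ok:
            count += 1
    return count
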