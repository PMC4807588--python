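"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: contact extraction
is re-done as a plain all-pairs distance scan, alignment as a textbook
Needleman-Wunsch, and complete-linkage clustering as naive agglomeration
over explicit cluster sets.
"""

from __future__ import annotations

import math


def brute_force_contact_positions(model, het, cutoff):
    """All-atom-pair scan: {(chain_id, residue_number, icode)} of residues
    with any atom within cutoff of any ligand atom, plus min distances."""
    found = {}
    for chain in model.chains:
        for res in chain.residues:
            dmin = math.inf
            for a in res.atoms:
                for b in het.atoms:
                    d = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
                    if d < dmin:
                        dmin = d
            if dmin <= cutoff:
                found[(chain.chain_id, res.number, res.icode)] = dmin
    return found


def nw_identity(a: str, b: str) -> float:
    """Global alignment identity with match 1, mismatch 0, linear gap -1;
    deterministic traceback preferring diagonal, then up, then left."""
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = -i
    for j in range(1, m + 1):
        score[0][j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
            up = score[i - 1][j] - 1
            left = score[i][j - 1] - 1
            score[i][j] = max(diag, up, left)
    i, j = n, m
    matches = 0
    length = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            1 if a[i - 1] == b[j - 1] else 0
        ):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and score[i][j] == score[i - 1][j] - 1:
            i -= 1
        else:
            j -= 1
        length += 1
    return matches / length


def greedy_nonredundant(sequences, threshold, identity=nw_identity):
    retained = []
    for seq in sequences:
        if all(identity(seq, kept) < threshold for kept in retained):
            retained.append(seq)
    return retained


def complete_linkage_agglomerate(ids, dist):
    """Naive agglomeration under complete linkage.

    ``dist`` maps frozenset({p, q}) -> distance for singleton members.
    Returns the list of merge heights and the sequence of partitions
    (one partition per merge, each a set of frozensets).
    """
    clusters = [frozenset([i]) for i in ids]
    heights = []
    partitions = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = max(
                    dist[frozenset([p, q])]
                    for p in clusters[x]
                    for q in clusters[y]
                )
                if best is None or d < best[0]:
                    best = (d, x, y)
        d, x, y = best
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
        heights.append(d)
        partitions.append(set(clusters))
    return heights, partitions
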