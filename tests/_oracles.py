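"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by exhaustive enumeration or naive
looping, deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------------------
# Cliff's delta by full pair enumeration


def cliffs_delta_bruteforce(x, y) -> float:
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (len(x) * len(y))


# ---------------------------------------------------------------------------
# k-mer uniqueness by dictionary counting


def kmer_uniqueness_bruteforce(sequences: dict[str, str], k: int, canonical: bool):
    """Per-transcript unique-kmer counts and index unique fraction."""
    comp = str.maketrans("ACGT", "TGCA")

    def canon(s: str) -> str:
        rc = s.translate(comp)[::-1]
        return min(s, rc) if canonical else s

    per_sets = {}
    for tid, seq in sequences.items():
        kmers = set()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) <= set("ACGT"):
                kmers.add(canon(w))
        per_sets[tid] = kmers
    counts: dict[str, int] = {}
    for kmers in per_sets.values():
        for km in kmers:
            counts[km] = counts.get(km, 0) + 1
    unique = {tid: sum(1 for km in kmers if counts[km] == 1) for tid, kmers in per_sets.items()}
    distinct = len(counts)
    frac = (sum(1 for c in counts.values() if c == 1) / distinct) if distinct else 0.0
    return unique, distinct, frac


# ---------------------------------------------------------------------------
# longest ORF by exhaustive ATG -> first-stop scan


def longest_orf_bruteforce(seq: str) -> int | None:
    """Longest forward-strand ORF length in aa, or None."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    n = len(seq)
    for atg in range(n - 2):
        if seq[atg : atg + 3] != "ATG":
            continue
        pos = atg
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if set(codon) - set("ACGT"):
                break  # N codon: ORF cannot extend through it
            if pos > atg and codon in stops:
                aa = (pos - atg) // 3
                if best is None or aa > best:
                    best = aa
                break
            pos += 3
    return best


# ---------------------------------------------------------------------------
# affine-gap global alignment by exhaustive move-sequence enumeration


def enumerate_global_alignments(a: str, b: str, score_fn, gap_open: float,
                                gap_extend: float):
    """Yield (score, identity_percent) over ALL global alignments of a and b.

    Moves: M consumes one char of each; X gaps sequence b (consumes a);
    Y gaps sequence a (consumes b).  The first column of each gap run costs
    gap_open, subsequent columns gap_extend; end gaps are penalised the same
    way.
    """
    n, m = len(a), len(b)

    def rec(i, j, prev, score, matches, cols):
        if i == n and j == m:
            yield score, 100.0 * matches / cols
            return
        if i < n and j < m:
            yield from rec(i + 1, j + 1, "M",
                           score + score_fn(a[i], b[j]),
                           matches + (1 if a[i] == b[j] else 0), cols + 1)
        if i < n:
            pen = gap_extend if prev == "X" else gap_open
            yield from rec(i + 1, j, "X", score - pen, matches, cols + 1)
        if j < m:
            pen = gap_extend if prev == "Y" else gap_open
            yield from rec(i, j + 1, "Y", score - pen, matches, cols + 1)

    yield from rec(0, 0, None, 0.0, 0, 0)


def best_global_alignment_bruteforce(a: str, b: str, score_fn,
                                     gap_open: float = 10.0,
                                     gap_extend: float = 0.5):
    """(optimal score, max identity among optimal alignments)."""
    best_score = None
    best_identity = 0.0
    for score, ident in enumerate_global_alignments(a, b, score_fn, gap_open, gap_extend):
        if best_score is None or score > best_score + 1e-9:
            best_score, best_identity = score, ident
        elif abs(score - best_score) <= 1e-9:
            best_identity = max(best_identity, ident)
    return best_score, best_identity


def blosum62_score_fn():
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")

    def score(x, y):
        if x == "X" or y == "X":
            return 0.0
        return float(m[x, y])

    return score


# ---------------------------------------------------------------------------
# Mann-Whitney exact p by enumeration of group labelings


def mannwhitney_exact_bruteforce(x, y):
    """Two-sided exact p for tie-free samples, by enumerating all C(n+m, n)
    assignments of the pooled values to the x group."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    observed = u_stat(x, y)
    nm = n * len(y)
    obs_dev = abs(observed - nm / 2)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(combo)]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - nm / 2) >= obs_dev - 1e-12:
            count += 1
    return observed, count / total


# ---------------------------------------------------------------------------
# random additive trees for neighbour-joining recovery


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (skbio.TreeNode, labels, distance matrix as ndarray) where the
    matrix holds the exact leaf-to-leaf path lengths.
    """
    import skbio

    labels = [f"L{i}" for i in range(n_taxa)]
    nodes = []
    for lab in labels:
        tip = skbio.TreeNode(name=lab)
        tip.length = float(rng.uniform(0.1, 2.0))
        nodes.append(tip)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = skbio.TreeNode()
        parent.length = float(rng.uniform(0.1, 2.0))
        parent.extend([nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = skbio.TreeNode()
    root.extend(nodes)
    dm = root.tip_tip_distances(endpoints=labels)
    d = np.asarray(dm.data)
    order = [list(dm.ids).index(lab) for lab in labels]
    return root, labels, d[np.ix_(order, order)]
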