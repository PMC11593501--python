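"""Independent oracles for the alignment and merge tests.

These deliberately avoid the package's dynamic-programming / engine code
paths: alignments are enumerated exhaustively and scored by a linear scan,
and the consensus vote is recomputed column by column.
"""

from collections import Counter

GAP = "-"


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (aligned_a, aligned_b).

    Exponential (Delannoy) — only usable for lengths <= ~8.
    """

    def rec(i, j, xs, ys):
        if i == len(a) and j == len(b):
            yield "".join(xs), "".join(ys)
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, xs + [a[i]], ys + [b[j]])
        if i < len(a):
            yield from rec(i + 1, j, xs + [a[i]], ys + [GAP])
        if j < len(b):
            yield from rec(i, j + 1, xs + [GAP], ys + [b[j]])

    yield from rec(0, 0, [], [])


def score_alignment(aligned_a: str, aligned_b: str,
                    match=1.0, mismatch=-1.0, gap_open=-5.0, gap_extend=-1.0):
    """Affine score of one explicit alignment: a gap run of length k costs
    gap_open + (k - 1) * gap_extend; terminal gaps are penalised."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP and y == GAP:
            raise ValueError("double-gap column")
        if x == GAP:
            score += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            score += gap_extend if in_gap_b else gap_open
            in_gap_a, in_gap_b = False, True
        else:
            score += match if x == y else mismatch
            in_gap_a = in_gap_b = False
    return score


def brute_force_best_score(a: str, b: str, **scores) -> float:
    return max(
        score_alignment(x, y, **scores) for x, y in enumerate_alignments(a, b)
    )


def identity_excl_terminal_gaps(aligned_a: str, aligned_b: str) -> float:
    """Reference implementation of the default identity convention."""
    both = [i for i, (x, y) in enumerate(zip(aligned_a, aligned_b))
            if x != GAP and y != GAP]
    if not both:
        return 0.0
    lo, hi = both[0], both[-1]
    span_a, span_b = aligned_a[lo:hi + 1], aligned_b[lo:hi + 1]
    matches = sum(1 for x, y in zip(span_a, span_b) if x == y and x != GAP)
    return matches / (hi - lo + 1)


def vote_consensus(columns_of: list[str]):
    """Column-vote oracle for equal-length, indel-free copies.

    Returns (consensus, n_unanimous, n_majority, n_trimmed) following the
    merge rules: unanimous kept, strict majority kept, otherwise trimmed.
    """
    length = len(columns_of[0])
    assert all(len(s) == length for s in columns_of)
    consensus = []
    n_u = n_m = n_t = 0
    for i in range(length):
        col = [s[i] for s in columns_of]
        residue, top = Counter(col).most_common(1)[0]
        if top == len(col):
            consensus.append(residue)
            n_u += 1
        elif top * 2 > len(col):
            consensus.append(residue)
            n_m += 1
        else:
            n_t += 1
    return "".join(consensus), n_u, n_m, n_t
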