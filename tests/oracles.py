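"""Independent brute-force oracles used only by the tests.

The alignment oracle is a plain dynamic-programming implementation of
semi-global affine-gap alignment (free end gaps on the read), written
without reference to the package's aligner, for cross-checking optimal
scores on small instances.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def optimal_alignment_score(ref: str, read: str, match=1, mismatch=-1,
                            gap_open=-5, gap_extend=-1) -> float:
    """Optimal score of aligning ``read`` to ``ref``.

    Global in the read, free gaps at the reference ends (the read may start
    and end inside the reference). ``gap_open`` is the score of the first
    gapped position, ``gap_extend`` of each subsequent one. Three-state
    affine DP (match/mismatch, gap-in-read a.k.a. deletion, gap-in-ref
    a.k.a. insertion).
    """
    n, m = len(ref), len(read)
    # M[i][j]: ref[:i] vs read[:j] ending in substitution column
    # D[i][j]: ending with ref base deleted (gap in read)
    # I[i][j]: ending with read base inserted (gap in ref)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    D = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    I = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    D[0][0] = 0.0  # free left end gap in the read
    for i in range(1, n + 1):
        D[i][0] = 0.0
    for j in range(1, m + 1):
        I[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            best_prev = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            M[i][j] = best_prev + s
            D[i][j] = max(M[i - 1][j] + gap_open, D[i - 1][j] + gap_extend,
                          I[i - 1][j] + gap_open)
            I[i][j] = max(M[i][j - 1] + gap_open, I[i][j - 1] + gap_extend,
                          D[i][j - 1] + gap_open)
    # free right end gap in the read: best over all reference end points
    best = NEG_INF
    for i in range(n + 1):
        best = max(best, M[i][m], I[i][m])
    best = max(best, D[n][m])
    return best


def left_shift_indels(ref: str, indels, left_bound: int = 0):
    """Test-local canonical leftmost placement of (kind, start, length, seq)."""
    out = []
    prev_end = left_bound
    for kind, start, length, seq in sorted(indels, key=lambda t: t[1]):
        if kind == "deletion":
            while start > prev_end and ref[start - 1] == ref[start + length - 1]:
                start -= 1
            out.append(("deletion", start, length, ""))
            prev_end = start + length
        else:
            while start > prev_end and ref[start - 1] == seq[-1]:
                seq = ref[start - 1] + seq[:-1]
                start -= 1
            out.append(("insertion", start, length, seq))
            prev_end = start
    return out


def apply_alignment(ref: str, aln) -> str:
    """Reconstruct the read implied by a ReadAlignment (no mismatches)."""
    seq = ref[aln.left_boundary_offset:len(ref) - aln.right_boundary_offset]
    offset = -aln.left_boundary_offset
    for ind in aln.indels:
        pos = ind.ref_start + offset
        if ind.kind == "deletion":
            seq = seq[:pos] + seq[pos + ind.length:]
            offset -= ind.length
        else:
            seq = seq[:pos] + ind.inserted_seq + seq[pos:]
            offset += ind.length
    return seq


def score_of_alignment(aln, gap_open=-5, gap_extend=-1, match=1) -> float:
    """Score implied by a ReadAlignment's indel set, assuming no mismatches."""
    n_gap_positions = 0
    n_gaps = 0
    read_aligned = aln.read_length
    for ind in aln.indels:
        n_gaps += 1
        n_gap_positions += ind.length
        if ind.kind == "insertion":
            read_aligned -= ind.length
    gap_score = n_gaps * gap_open + (n_gap_positions - n_gaps) * gap_extend
    return read_aligned * match + gap_score
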