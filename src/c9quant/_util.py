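"""Small sequence helpers shared across the long-read stages."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance; unequal lengths count the overhang as mismatches."""
    d = abs(len(a) - len(b))
    return d + sum(x != y for x, y in zip(a, b))


def levenshtein(a: str, b: str) -> int:
    # tiny DP; only ever called on <=7-nt windows, so no need for edlib here
    if a == b:
        return 0
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ai != b[j - 1]),
            )
        prev = cur
    return prev[n]


def find_approx(seq: str, motif: str, max_mismatches: int) -> tuple[int, int] | None:
    """Locate ``motif`` in ``seq`` allowing Hamming mismatches.

    Returns ``(position, mismatches)`` for the leftmost exact hit when one
    exists, otherwise the leftmost minimal-mismatch hit with at most
    ``max_mismatches``; ``None`` when nothing qualifies.
    """
    pos = seq.find(motif)
    if pos >= 0:
        return pos, 0
    if max_mismatches <= 0:
        return None
    k = len(motif)
    best: tuple[int, int] | None = None
    for i in range(len(seq) - k + 1):
        d = 0
        window = seq[i : i + k]
        for x, y in zip(window, motif):
            if x != y:
                d += 1
                if d > max_mismatches:
                    break
        else:
            if best is None or d < best[1]:
                best = (i, d)
                if d == 1:
                    # 0 handled by the exact scan above; 1 cannot be beaten
                    break
    return best
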