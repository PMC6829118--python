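"""Independent oracles shared by unit and acceptance tests."""

import numpy as np

from breakmap.synthetic_genome import ReferenceSet


def longest_prefix_match(consensus: str, seq: str) -> int:
    """Max over every alignment position of the exact prefix-match length.

    Exhaustive: every start offset in ``seq`` is scored, independent of any
    seeding or anchoring heuristic.
    """
    n = len(consensus)
    d = np.frombuffer(consensus.encode(), np.uint8)
    # pad with a sentinel so every start offset gets a full-width window
    s = np.frombuffer((seq + "\x00" * n).encode(), np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(s, n)[:len(seq)]
    neq = win != d
    first_mismatch = np.where(neq.any(axis=1), neq.argmax(axis=1), n)
    return int(first_mismatch.max())


def longest_suffix_match(consensus: str, seq: str) -> int:
    return longest_prefix_match(consensus[::-1], seq[::-1])


def split_enumeration(consensus: str, left_seq: str, right_seq: str
                      ) -> tuple[int, int, int, str]:
    """Oracle junction resolution: (p, s, mh_len, ins_seq).

    p/s are the globally best prefix/suffix match lengths; the split point
    maximizing total matched bases then yields either a microhomology of
    ``p + s - len`` or an unmatched insertion in the middle.
    """
    n = len(consensus)
    p = longest_prefix_match(consensus, left_seq)
    s = longest_suffix_match(consensus, right_seq)
    if p + s >= n:
        return p, s, p + s - n, ""
    return p, s, 0, consensus[p:n - s]


def random_split_case(rng: np.random.Generator, ref_len: int = 5000,
                      flank: int = 100):
    """A consensus built as a true junction over two fresh random references.

    Returns (consensus, left_seq, right_seq) with a blunt, microhomologous
    (1-4 nt planted) or inserted (1-5 nt) junction and ~``flank`` matched
    bases on each side.
    """
    def draw(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    left = draw(ref_len)
    right = draw(ref_len)
    x0 = int(rng.integers(200, ref_len - 200 - flank))
    y0 = int(rng.integers(200, ref_len - 200 - flank))
    kind = int(rng.integers(0, 3))
    ins = ""
    if kind == 1:  # plant microhomology left of the right-side cut
        m = int(rng.integers(1, 5))
        right = right[:y0 - m] + left[x0 + flank - m:x0 + flank] + right[y0:]
    elif kind == 2:
        ins = draw(int(rng.integers(1, 6)))
    consensus = left[x0:x0 + flank] + ins + right[y0:y0 + flank]
    return consensus, left, right
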