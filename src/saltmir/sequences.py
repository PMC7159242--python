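"""Small sequence utilities shared across the pipeline.

Genome and reads are kept in the DNA alphabet (A/C/G/T); conversion to RNA
(T->U) happens only at the boundary of thermodynamic folding calls.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def gc_percent(seq: str) -> float:
    """G+C content as a percentage of sequence length."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def au_percent(seq: str) -> float:
    """A+U (A+T in DNA) content as a percentage of sequence length."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("A") + s.count("T") + s.count("U")) / len(s)


def mononucleotide_fraction(seq: str) -> float:
    """Fraction of positions occupied by the most frequent single base."""
    s = seq.upper()
    return max(s.count(b) for b in "ACGTN") / len(s)


def max_dinucleotide_repeat_fraction(seq: str) -> float:
    """Fraction of the sequence covered by the longest tandem dinucleotide
    repeat (period-2 stretch such as ATATAT...), over all 16 dinucleotides."""
    s = seq.upper()
    n = len(s)
    if n < 4:
        return 0.0
    best = 0
    # longest stretch where s[i+2] == s[i]
    run = 2
    for i in range(2, n):
        if s[i] == s[i - 2]:
            run += 1
        else:
            best = max(best, run)
            run = 2
    best = max(best, run)
    return best / n


def is_low_complexity(seq: str, mono_frac: float = 0.8, dinuc_frac: float = 0.8) -> bool:
    """DUST-like rule: a tag is low complexity when a single base makes up
    >= ``mono_frac`` of positions or one tandem dinucleotide repeat covers
    >= ``dinuc_frac`` of the sequence."""
    if mononucleotide_fraction(seq) >= mono_frac:
        return True
    return max_dinucleotide_repeat_fraction(seq) >= dinuc_frac


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts
    (Altschul-Erickson Eulerian-walk shuffle).

    Each base keeps its multiset of successors; a random terminal edge per
    base is drawn until the terminal edges form a tree into the last base,
    the remaining successor lists are shuffled, and the Eulerian walk is
    replayed from the original first base.
    """
    s = seq.upper()
    if len(s) < 3:
        return s
    succ: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        succ.setdefault(a, []).append(b)
    vertices = list(succ)
    last = s[-1]
    for _ in range(10_000):
        # pick a candidate terminal edge per non-terminal vertex
        last_edge = {
            v: succ[v][int(rng.integers(0, len(succ[v])))]
            for v in vertices if v != last
        }
        # tree check: following terminal edges from every vertex reaches `last`
        ok = True
        for v in last_edge:
            cur, hops = v, 0
            while cur != last and hops <= len(vertices):
                cur = last_edge.get(cur, last)
                hops += 1
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - tiny alphabets converge immediately
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")
    lists: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(succ[v])
        if v != last:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(last_edge[v])
        lists[v] = rest
    out = [s[0]]
    ptr = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = lists[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """Random DNA of length n with expected G+C proportion ``gc``."""
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
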