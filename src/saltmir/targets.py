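"""Plant-style miRNA target prediction with an expectation (penalty) score.

The expectation score over the miRNA/target duplex sums, per aligned miRNA
position: 0 for a Watson-Crick pair, 0.5 for a G:U wobble, 1 for a mismatch
and 2 per gap, with penalties doubled in the seed region (miRNA positions
2-13 from the 5' end). Alignments considered are the ungapped registration
plus all single-gap registrations (at most one gap per alignment, in either
strand); the reported alignment is the argmin. Targets with expectation <=
3.0 (inclusive) are reported, best-per-locus and non-overlapping.

Cleavage is predicted opposite miRNA positions 10-11: the reported
coordinate is the transcript position of the base paired with miRNA
position 10, the AGO cut falling immediately 5' of it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

from .sequences import to_dna

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in RNA

SEED_RANGE = (2, 13)   # miRNA positions (1-based from 5') with doubled penalty
GAP_PENALTY = 2.0
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5


@dataclass
class TargetHit:
    mirna_name: str
    transcript_id: str
    t_start: int            # 0-based half-open on the transcript
    t_end: int
    alignment: tuple[str, str, str]   # miRNA 3'->5', pairing row, target 5'->3'
    expectation: float
    cleavage: int | tuple[int, int]   # coordinate or interval when gapped


@lru_cache(maxsize=None)
def _alignments(m_len: int, w_len: int) -> tuple[tuple[tuple[int | None, int | None], ...], ...]:
    """All <=1-gap alignments of a reversed miRNA (length m_len) against a
    target window (length w_len), as column lists of (miRNA index into the
    reversed miRNA, window index); None marks a gap."""
    out = []
    if w_len == m_len:
        out.append(tuple((j, j) for j in range(m_len)))
    elif w_len == m_len + 1:          # bulged target base: gap in miRNA row
        for g in range(w_len):
            cols = []
            for j in range(w_len):
                if j == g:
                    cols.append((None, j))
                else:
                    cols.append((j if j < g else j - 1, j))
            out.append(tuple(cols))
    elif w_len == m_len - 1:          # bulged miRNA base: gap in target row
        for g in range(m_len):
            cols = []
            for j in range(m_len):
                if j == g:
                    cols.append((j, None))
                else:
                    cols.append((j, j if j < g else j - 1))
            out.append(tuple(cols))
    return tuple(out)


def _position_weight(mirna_pos: int) -> float:
    return 2.0 if SEED_RANGE[0] <= mirna_pos <= SEED_RANGE[1] else 1.0


def _column_penalty(mr: str, w: str, col: tuple[int | None, int | None],
                    m_len: int, consumed: int) -> tuple[float, int | None]:
    """(weighted penalty, miRNA 5'-based position) for one column.

    ``consumed`` is the number of miRNA bases already aligned in columns to
    the left; for a gap column the position of the next miRNA base is used.
    """
    mi, wi = col
    pos = m_len - consumed  # position of this (or the next) miRNA base
    weight = _position_weight(pos)
    if mi is None or wi is None:
        return GAP_PENALTY * weight, None
    pair = (mr[mi], w[wi])
    if pair in _WC:
        return 0.0, pos
    if pair in _WOBBLE:
        return WOBBLE_PENALTY * weight, pos
    return MISMATCH_PENALTY * weight, pos


def score_site(mirna_seq: str, window: str) -> tuple[float, tuple[str, str, str], tuple]:
    """Expectation score of a miRNA against a target window.

    Returns (expectation, alignment triple, alignment columns). The window
    must be within one nucleotide of the miRNA length (one gap allowed).
    """
    m = to_dna(mirna_seq)
    w = to_dna(window)
    mr = m[::-1]  # 3'->5'
    cands = _alignments(len(m), len(w))
    if not cands:
        raise ValueError(
            f"window length {len(w)} incompatible with miRNA length {len(m)}"
        )
    best = None
    for cols in cands:
        score = 0.0
        consumed = 0
        for col in cols:
            pen, _ = _column_penalty(mr, w, col, len(m), consumed)
            score += pen
            if col[0] is not None:
                consumed += 1
        if best is None or score < best[0]:
            best = (score, cols)
    score, cols = best
    mi_row = "".join("-" if c[0] is None else mr[c[0]] for c in cols)
    t_row = "".join("-" if c[1] is None else w[c[1]] for c in cols)
    pairing = []
    for a, b in zip(mi_row, t_row):
        if (a, b) in _WC:
            pairing.append("|")
        elif (a, b) in _WOBBLE:
            pairing.append("o")
        else:
            pairing.append(" ")
    return score, (mi_row, "".join(pairing), t_row), cols


def _min_score_bounded(mr: str, m_len: int, w: str, bound: float) -> float | None:
    """Minimum expectation over alignments, or None if every alignment
    exceeds ``bound``. Columns are scored seed-first so random windows
    abort early; penalties are non-negative, making the abort exact."""
    best = None
    for cols in _alignments(m_len, len(w)):
        # consumed-before-column, precomputed left to right
        consumed = 0
        before = []
        for c in cols:
            before.append(consumed)
            if c[0] is not None:
                consumed += 1
        score = 0.0
        limit = bound if best is None else min(bound, best)
        for idx in range(len(cols) - 1, -1, -1):  # seed side first
            pen, _ = _column_penalty(mr, w, cols[idx], m_len, before[idx])
            score += pen
            if score > limit:
                break
        else:
            if best is None or score < best:
                best = score
    return best


def scan_transcriptome(
    mirna_name: str,
    mirna_seq: str,
    transcripts: list[tuple[str, str]],
    cutoff: float = 3.0,
) -> list[TargetHit]:
    """All target sites with expectation <= ``cutoff`` (inclusive),
    best-per-locus and non-overlapping, sorted by ascending expectation with
    ties broken by transcript id then position."""
    if not transcripts:
        raise ValueError("empty transcriptome")
    m = to_dna(mirna_seq)
    mr = m[::-1]
    m_len = len(m)
    raw: list[TargetHit] = []
    for tid, tseq in transcripts:
        tseq = to_dna(tseq)
        for w_len in (m_len - 1, m_len, m_len + 1):
            if w_len < 1:
                continue
            for s in range(0, len(tseq) - w_len + 1):
                w = tseq[s:s + w_len]
                if _min_score_bounded(mr, m_len, w, cutoff) is None:
                    continue
                exp, aln, cols = score_site(m, w)
                if exp <= cutoff:
                    cleavage = _cleavage_from_columns(cols, m_len, s)
                    raw.append(TargetHit(
                        mirna_name, tid, s, s + w_len, aln, exp, cleavage
                    ))
    raw.sort(key=lambda h: (h.expectation, h.transcript_id, h.t_start))
    kept: list[TargetHit] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for h in raw:
        spans = occupied.setdefault(h.transcript_id, [])
        if all(h.t_end <= a or h.t_start >= b for a, b in spans):
            kept.append(h)
            spans.append((h.t_start, h.t_end))
    kept.sort(key=lambda h: (h.expectation, h.transcript_id, h.t_start))
    return kept


def _cleavage_from_columns(cols: tuple, m_len: int, t_start: int) -> int | tuple[int, int]:
    consumed = 0
    partner: dict[int, int | None] = {}
    gap_between_10_11 = False
    for mi, wi in cols:
        pos = m_len - consumed
        if mi is not None:
            partner[pos] = wi
            consumed += 1
        elif pos == 10:  # bulged target base between miRNA positions 10 and 11
            gap_between_10_11 = True
    w10 = partner.get(10)
    if not gap_between_10_11 and w10 is not None:
        return t_start + w10
    # gap opposite positions 10-11: report the flanking interval
    flanks = [w for w in (partner.get(11), w10, partner.get(9)) if w is not None]
    if flanks:
        return (t_start + min(flanks), t_start + max(flanks) + 1)
    return (t_start, t_start)


def predict_cleavage(hit: TargetHit) -> int | tuple[int, int]:
    """Transcript coordinate of the base paired with miRNA position 10 (the
    cut falls immediately 5' of it); an interval when a gap sits opposite
    miRNA positions 10-11."""
    return hit.cleavage


def tally_clones(clone_positions: list[int], predicted: int) -> tuple[float, dict[int, int]]:
    """Fraction of 5'-RACE clones whose mapped cleavage position equals the
    predicted site, plus the full position histogram."""
    if not clone_positions:
        raise ValueError("no clones supplied")
    hist = dict(Counter(clone_positions))
    frac = hist.get(predicted, 0) / len(clone_positions)
    return frac, hist
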