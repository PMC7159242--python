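"""Novel miRNA discovery: genome mapping, precursor excision, folding and
hairpin-criteria evaluation.

A tag without catalog support is a novel-miRNA candidate when a genomic
window around one of its perfect genome hits folds into a stem-loop that
satisfies the classical plant pre-miRNA criteria: precursor length >= 60 nt,
the mature lies entirely within one arm of a single-loop stem, the
miRNA/miRNA* duplex carries at most a configured number of mismatches,
MFE <= -15 kcal/mol, MFEI >= 0.64 (the tRNA reference value) and A+U content
within 20-85%.

MFEI, the minimum-free-energy index, is defined as

    MFEI = (|MFE| / precursor_length * 100) / (G+C%)

i.e. the MFE per 100 nt normalised by G+C content, which separates miRNA
precursors from tRNA/rRNA-like folds.

Folding delegates to the ViennaRNA nearest-neighbour thermodynamic model;
structures are reported in dot-bracket notation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import RNA

from .sequences import au_percent, gc_percent, revcomp, to_rna

#: flank grid (upstream, downstream of the mature, in read-strand
#: orientation) used to excise candidate precursor windows.
DEFAULT_FLANK_GRID = ((0, 250), (250, 0), (100, 100))


@dataclass
class Thresholds:
    """Hairpin acceptance thresholds (defaults per the classical criteria)."""

    min_precursor_length: int = 60
    max_loops: int = 1
    max_duplex_mismatches: int = 6
    max_mfe: float = -15.0          # kcal/mol; candidate must be <= this
    min_mfei: float = 0.64
    min_au: float = 20.0
    max_au: float = 85.0


@dataclass
class GenomeHit:
    sequence: str
    chrom: str
    start: int          # 0-based half-open on the + strand
    end: int
    strand: str         # '+' or '-'
    mismatches: int = 0


@dataclass
class HairpinCandidate:
    chrom: str
    window_start: int       # genomic coords of the evaluated window
    window_end: int
    strand: str
    precursor_start: int    # genomic coords of the trimmed precursor
    precursor_end: int
    precursor_seq: str      # read-strand 5'->3'
    structure: str
    pl: int
    mfe: float
    gc_pct: float
    au_pct: float
    mfei: float
    arm: str | None         # '5p' | '3p' | None when mature is unanchored
    mature_offset: int      # within precursor_seq
    mature_len: int
    star_seq: str | None
    duplex_mismatches: int | None
    loop_count: int
    verdict: dict[str, bool] = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(self.verdict.values())


def fold(seq: str) -> tuple[str, float]:
    """Minimum-free-energy secondary structure of an RNA/DNA sequence.

    Returns (dot-bracket structure, MFE in kcal/mol). The input may be DNA;
    T is read as U. Raises on non-ACGTU symbols or length outside 40-500 nt.
    """
    if not 40 <= len(seq) <= 500:
        raise ValueError(f"foldable length is 40-500 nt, got {len(seq)}")
    rna = to_rna(seq)
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGTU symbols in sequence: {sorted(bad)}")
    structure, mfe = RNA.fold(rna)
    return structure, float(mfe)


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 when unpaired) from dot-bracket."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pt


def count_terminal_loops(structure: str, lo: int = 0, hi: int | None = None) -> int:
    """Number of hairpin (terminal) loops within structure[lo:hi]:
    occurrences of '(' followed by ')' with only dots in between."""
    hi = len(structure) if hi is None else hi
    n = 0
    last_open = None
    for i in range(lo, hi):
        c = structure[i]
        if c == "(":
            last_open = i
        elif c == ")":
            if last_open is not None:
                n += 1
                last_open = None
    return n


def compute_mfei(mfe: float, pl: int, gc_pct: float) -> float:
    """MFEI = (|MFE| / PL * 100) / (G+C%)."""
    if pl <= 0:
        raise ValueError(f"precursor length must be positive, got {pl}")
    if not 0 < gc_pct < 100:
        raise ValueError(f"G+C% must be in (0,100), got {gc_pct}")
    return (abs(mfe) / pl * 100.0) / gc_pct


@dataclass
class StarResult:
    star_start: int
    star_end: int
    duplex_mismatches: int
    arm: str                 # arm of the *mature*
    failure: str | None = None


def find_star(structure: str, mature_offset: int, mature_len: int) -> StarResult:
    """Locate the miRNA* region pairing the mature under the fold.

    The star interval spans the partners of the paired mature positions,
    extended by the canonical 2-nt 3' overhang (the star 3' end is its
    rightmost base in precursor orientation). ``duplex_mismatches`` counts
    mature positions left unpaired within the duplex. A mature spanning the
    terminal loop (containing both '(' and ')') is a structural failure.
    """
    s, e = mature_offset, mature_offset + mature_len
    if s < 0 or e > len(structure):
        raise ValueError("mature span outside structure")
    span = structure[s:e]
    if "(" in span and ")" in span:
        return StarResult(-1, -1, mature_len, "none", failure="loop_spanning")
    pt = pair_table(structure)
    partners = [pt[i] for i in range(s, e) if pt[i] >= 0]
    if not partners:
        return StarResult(-1, -1, mature_len, "none", failure="unpaired")
    arm = "5p" if min(partners) >= e else "3p"
    star_lo = min(partners)
    star_hi = min(max(partners) + 1 + 2, len(structure))  # 2-nt 3' overhang
    mismatches = sum(1 for i in range(s, e) if pt[i] < 0)
    return StarResult(star_lo, star_hi, mismatches, arm)


def _trim_to_hairpin(pt: list[int], lo: int, hi: int) -> tuple[int, int]:
    """Extend [lo, hi) outward along enclosing base pairs to the base of the
    stem-loop containing the interval, returning the trimmed span."""
    n = len(pt)
    while True:
        enclosing = None
        # innermost pair enclosing [lo, hi): nesting guarantees the first
        # partner >= hi found scanning leftward is the innermost one
        for p in range(lo - 1, -1, -1):
            if pt[p] >= hi:
                enclosing = (p, pt[p])
                break
        if enclosing is None:
            return lo, hi
        lo, hi = enclosing[0], enclosing[1] + 1
        if lo == 0 and hi == n:
            return lo, hi


def evaluate_hairpin(
    window_seq: str,
    mature_offset: int,
    mature_len: int,
    thresholds: Thresholds | None = None,
    *,
    chrom: str = ".",
    window_start: int = 0,
    strand: str = "+",
) -> HairpinCandidate:
    """Fold a candidate window, trim it to the stem-loop bearing the mature,
    and evaluate the hairpin criteria.

    The window is folded once to locate the mature/star duplex; the
    precursor is then trimmed to the enclosing stem-loop and refolded so
    that MFE, MFEI and A+U refer to the precursor itself rather than to
    arbitrary flanking sequence.
    """
    thresholds = thresholds or Thresholds()
    structure, window_mfe = fold(window_seq)
    star = find_star(structure, mature_offset, mature_len)

    if star.failure is not None:
        lo, hi = 0, len(window_seq)
        precursor, pstruct, pmfe = window_seq, structure, window_mfe
        p_off = mature_offset
        star_seq = None
        dmm = None
        loops = count_terminal_loops(pstruct)
        arm = None
    else:
        pt = pair_table(structure)
        lo = min(mature_offset, star.star_start)
        hi = max(mature_offset + mature_len, star.star_end)
        lo, hi = _trim_to_hairpin(pt, lo, hi)
        precursor = window_seq[lo:hi]
        if len(precursor) < 40:
            pad = 40 - len(precursor)
            lo = max(0, lo - pad)
            hi = min(len(window_seq), lo + max(40, hi - lo))
            precursor = window_seq[lo:hi]
        pstruct, pmfe = fold(precursor)
        p_off = mature_offset - lo
        star2 = find_star(pstruct, p_off, mature_len)
        if star2.failure is None:
            star_seq = precursor[star2.star_start:star2.star_end]
            dmm = star2.duplex_mismatches
            arm = star2.arm
            loops = count_terminal_loops(
                pstruct,
                min(p_off, star2.star_start),
                max(p_off + mature_len, star2.star_end),
            )
        else:
            star_seq, dmm, arm = None, None, None
            loops = count_terminal_loops(pstruct)

    pl = len(precursor)
    gc = gc_percent(precursor)
    au = au_percent(precursor)
    mfei = compute_mfei(pmfe, pl, gc) if 0 < gc < 100 else 0.0

    verdict = {
        "precursor_length": pl >= thresholds.min_precursor_length,
        "single_loop": loops <= thresholds.max_loops and loops >= 1,
        "mature_one_arm": arm in ("5p", "3p"),
        "duplex_mismatches": (
            dmm is not None and dmm <= thresholds.max_duplex_mismatches
        ),
        "mfe": pmfe <= thresholds.max_mfe,
        "mfei": mfei >= thresholds.min_mfei,
        "au_content": thresholds.min_au <= au <= thresholds.max_au,
    }

    if strand == "+":
        g_lo, g_hi = window_start + lo, window_start + hi
    else:
        win_len = len(window_seq)
        g_lo = window_start + (win_len - hi)
        g_hi = window_start + (win_len - lo)

    return HairpinCandidate(
        chrom=chrom,
        window_start=window_start,
        window_end=window_start + len(window_seq),
        strand=strand,
        precursor_start=g_lo,
        precursor_end=g_hi,
        precursor_seq=precursor,
        structure=pstruct,
        pl=pl,
        mfe=pmfe,
        gc_pct=gc,
        au_pct=au,
        mfei=mfei,
        arm=arm,
        mature_offset=p_off if star.failure is None else mature_offset,
        mature_len=mature_len,
        star_seq=star_seq,
        duplex_mismatches=dmm,
        loop_count=loops,
        verdict=verdict,
    )


def map_tags(
    tags: list[str],
    genome: dict[str, str],
    max_mismatch: int = 0,
    max_loci: int = 20,
) -> dict[str, list[GenomeHit]]:
    """All genomic occurrences of each tag on both strands.

    Tags with more than ``max_loci`` hits are flagged multi-mappers: they are
    returned with an empty hit list (excluded from novel calling). With
    ``max_mismatch`` 0 (the default for novel calling) matching is exact
    substring search; small mismatch counts use a sliding comparison, which
    is adequate for the synthetic genome scale.
    """
    out: dict[str, list[GenomeHit]] = {}
    for tag in tags:
        hits: list[GenomeHit] = []
        rc = revcomp(tag)
        for chrom, seq in genome.items():
            if max_mismatch == 0:
                for query, strand in ((tag, "+"), (rc, "-")):
                    i = seq.find(query)
                    while i != -1:
                        hits.append(GenomeHit(tag, chrom, i, i + len(tag), strand))
                        i = seq.find(query, i + 1)
            else:
                k = len(tag)
                for i in range(len(seq) - k + 1):
                    win = seq[i:i + k]
                    for query, strand in ((tag, "+"), (rc, "-")):
                        mm = sum(a != b for a, b in zip(win, query))
                        if mm <= max_mismatch:
                            hits.append(GenomeHit(tag, chrom, i, i + k, strand, mm))
        out[tag] = [] if len(hits) > max_loci else hits
    return out


@dataclass
class CandidateWindow:
    chrom: str
    start: int
    end: int
    strand: str
    seq: str            # read-strand 5'->3'
    mature_offset: int  # within seq
    clipped: bool


def excise_candidates(
    hit: GenomeHit,
    genome: dict[str, str],
    flank_grid: tuple[tuple[int, int], ...] = DEFAULT_FLANK_GRID,
) -> list[CandidateWindow]:
    """Ladder of strand-oriented candidate windows around a genome hit.

    ``flank_grid`` entries are (upstream, downstream) flank lengths in the
    tag's 5'->3' orientation; windows are clipped (and flagged) at
    chromosome ends.
    """
    chrom_seq = genome[hit.chrom]
    n = len(chrom_seq)
    windows = []
    for up, down in flank_grid:
        if hit.strand == "+":
            lo, hi = hit.start - up, hit.end + down
        else:
            lo, hi = hit.start - down, hit.end + up
        clipped = lo < 0 or hi > n
        lo, hi = max(0, lo), min(n, hi)
        seq = chrom_seq[lo:hi]
        if hit.strand == "+":
            off = hit.start - lo
        else:
            seq = revcomp(seq)
            off = hi - hit.end
        windows.append(CandidateWindow(hit.chrom, lo, hi, hit.strand, seq, off, clipped))
    return windows


def discover_novel(
    tag_hits: dict[str, list[GenomeHit]],
    genome: dict[str, str],
    thresholds: Thresholds | None = None,
    flank_grid: tuple[tuple[int, int], ...] = DEFAULT_FLANK_GRID,
) -> dict[str, HairpinCandidate | None]:
    """Best hairpin candidate per tag over all hits and windows.

    Selection order: all criteria passing first, then lowest MFE. Tags with
    no mappable locus yield None.
    """
    thresholds = thresholds or Thresholds()
    best: dict[str, HairpinCandidate | None] = {}
    for tag, hits in tag_hits.items():
        tag_best: HairpinCandidate | None = None
        for hit in hits:
            for win in excise_candidates(hit, genome, flank_grid):
                if len(win.seq) < 40:
                    continue
                cand = evaluate_hairpin(
                    win.seq, win.mature_offset, len(tag), thresholds,
                    chrom=win.chrom, window_start=win.start, strand=win.strand,
                )
                key = (cand.all_pass, -cand.mfe)
                if tag_best is None or key > (tag_best.all_pass, -tag_best.mfe):
                    tag_best = cand
        best[tag] = tag_best
    return best
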