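"""Conserved miRNA annotation against a mature-miRNA catalog.

Tags are matched to miRBase-style catalog entries (global alignment, equal
length or up to a 2-nt terminal offset for isomiR tolerance, mismatches
scored over the overlap only), families are derived from names by the
standard rule (miR + digits, species prefix / letter suffix / -5p/-3p
dropped), and family diversity is the number of distinct mature names per
distinct family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .sequences import to_dna

_FAMILY_RE = re.compile(
    r"^(?:[a-z]{3,4}-)?miR(\d+)[a-zA-Z]*(?:[-.][35]p)?$", re.IGNORECASE
)


@dataclass
class MirnaAnnotation:
    tag: str
    name: str
    family: str
    mismatches: int
    ambiguous: bool = False
    libraries_present: tuple[str, ...] = ()
    max_rpm: float = 0.0


def assign_family(name: str) -> str:
    """Family from a miRNA name: 'osa-miR396a' -> 'miR396'."""
    m = _FAMILY_RE.match(name.strip())
    if not m:
        raise ValueError(f"unparseable miRNA name: {name!r}")
    return f"miR{m.group(1)}"


def _best_alignment(tag: str, cat: str, max_offset: int = 2) -> int | None:
    """Fewest mismatches over the overlap across terminal offsets of up to
    ``max_offset`` nt; None when the overlap would drop more than
    ``max_offset`` nt from either sequence."""
    n, m = len(tag), len(cat)
    best: int | None = None
    for s in range(-max_offset, max_offset + 1):
        lo = max(0, s)
        hi = min(n, m + s)
        overlap = hi - lo
        if overlap < max(n, m) - max_offset:
            continue
        mm = sum(1 for i in range(lo, hi) if tag[i] != cat[i - s])
        if best is None or mm < best:
            best = mm
    return best


def match_known(
    tags: pd.DataFrame,
    catalog: list[tuple[str, str]],
    max_mismatch: int = 2,
    min_count: int = 1,
) -> list[MirnaAnnotation]:
    """Annotate unique tags against the catalog.

    Each tag is assigned to the catalog entry with the fewest mismatches
    (<= ``max_mismatch``); ties are broken lexicographically by catalog name
    and flagged ambiguous. A library counts as "present" when the tag count
    there is >= ``min_count``.
    """
    cat = [(name, to_dna(seq)) for name, seq in catalog]
    for name, seq in cat:
        if not 18 <= len(seq) <= 26:
            raise ValueError(f"catalog entry {name} length {len(seq)} outside 18-26 nt")
    libs = [c[6:] for c in tags.columns if c.startswith("count_")]
    annotations: list[MirnaAnnotation] = []
    for row in tags.itertuples(index=False):
        seq = row.sequence
        scored = []
        for name, cseq in cat:
            mm = _best_alignment(seq, cseq)
            if mm is not None and mm <= max_mismatch:
                scored.append((mm, name))
        if not scored:
            continue
        scored.sort()
        mm, name = scored[0]
        ambiguous = len(scored) > 1 and scored[1][0] == mm
        present = tuple(
            lib for lib in libs if getattr(row, f"count_{lib}") >= min_count
        )
        if not present:
            continue
        max_rpm = max(getattr(row, f"rpm_{lib}") for lib in libs) if libs else 0.0
        annotations.append(MirnaAnnotation(
            tag=seq, name=name, family=assign_family(name),
            mismatches=mm, ambiguous=ambiguous,
            libraries_present=present, max_rpm=float(max_rpm),
        ))
    return annotations


def family_diversity(annotations: list[MirnaAnnotation],
                     libraries: tuple[str, ...] | None = None) -> float:
    """Distinct mature names per distinct family, optionally restricted to
    annotations present in any of ``libraries``."""
    sel = [
        a for a in annotations
        if libraries is None or any(l in a.libraries_present for l in libraries)
    ]
    if not sel:
        raise ValueError("no annotations in the requested subset")
    names = {a.name for a in sel}
    families = {a.family for a in sel}
    return len(names) / len(families)


_TABLE_COLUMNS = ["tag", "name", "family", "mismatches", "ambiguous",
                  "libraries_present", "max_rpm"]


def annotations_table(annotations: list[MirnaAnnotation]) -> pd.DataFrame:
    if not annotations:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    return pd.DataFrame([
        {
            "tag": a.tag, "name": a.name, "family": a.family,
            "mismatches": a.mismatches, "ambiguous": a.ambiguous,
            "libraries_present": ",".join(a.libraries_present),
            "max_rpm": a.max_rpm,
        }
        for a in annotations
    ])
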