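"""Synthetic data generator: genome with planted pre-miRNA hairpins,
contaminant ncRNAs, mature-miRNA catalog, transcriptome with planted target
sites, and four adapter-ligated sRNA FASTQ libraries (CR, CS, TR, TS) with
known per-library expression.

The generator defines the study conditions emulated throughout the package:
four libraries from a 2x2 control/NaCl-treated x root/shoot design, reads of
16-35 nt with a length peak at 23-24 nt, a tRNA/rRNA contaminant fraction,
adapter read-through on a 50 nt sequencer read, and planted hairpin loci
that satisfy the discovery criteria by construction.

Randomness: a single integer seed fans out to per-purpose substreams via
``numpy.random.default_rng([seed, stream_index])``; the fan-out indices are
fixed constants so a run is reproducible end to end. Cross-implementation
bit-identity is not a goal; same-(config, seed) determinism is.

Per-library read composition uses exact quota allocation (rounded expected
counts per planted mature, a rounded contaminant quota, background filling
the remainder, then a seeded shuffle) rather than multinomial draws, so the
observed RPM of every planted mature reproduces its programmed RPM up to
rounding. This isolates downstream statistical behaviour from sampling
noise in the generator itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import discovery
from .sequences import random_seq, revcomp

LIBRARIES = ("CR", "CS", "TR", "TS")

#: Illumina TruSeq small-RNA 3' adapter (configurable default).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: sequencer read length; inserts are 16-35 nt so the adapter is always read
#: into and the trimming path is always exercised.
READ_LENGTH = 50

# substream indices for the seed fan-out
_STREAM_GENOME = 0
_STREAM_HAIRPIN = 1
_STREAM_EXPRESSION = 2
_STREAM_NCRNA = 3
_STREAM_CATALOG = 4
_STREAM_TRANSCRIPTOME = 5
_STREAM_READS = {lib: 10 + i for i, lib in enumerate(LIBRARIES)}

#: background insert length distribution over 16-35 nt, peaked at 23-24 nt.
LENGTH_WEIGHTS = {
    16: 2, 17: 2, 18: 3, 19: 3, 20: 4, 21: 6, 22: 8, 23: 16, 24: 16,
    25: 8, 26: 6, 27: 4, 28: 3, 29: 3, 30: 2, 31: 2, 32: 1, 33: 1,
    34: 1, 35: 1,
}


def _length_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    lens = np.array(list(LENGTH_WEIGHTS), dtype=int)
    w = np.array(list(LENGTH_WEIGHTS.values()), dtype=float)
    return rng.choice(lens, size=n, p=w / w.sum())


@dataclass
class PlantedLocus:
    name: str
    chrom: str
    start: int          # 0-based half-open, + strand coordinates
    end: int
    strand: str
    mature_seq: str     # read-strand sequence (the sequenced tag)
    arm: str
    star_seq: str
    precursor_seq: str  # read-strand 5'->3'
    mature_offset: int  # within precursor_seq
    duplex_mismatches: int


@dataclass
class SyntheticTruth:
    seed: int
    genome_path: Path | None
    planted_loci: list[PlantedLocus]
    library_expression: dict[tuple[str, str], float]  # (locus, lib) -> RPM
    contaminant_fraction: float
    adapter: str = DEFAULT_ADAPTER
    length_distribution: dict[int, int] = field(
        default_factory=lambda: dict(LENGTH_WEIGHTS)
    )

    def expected_rpm(self, locus: str, lib: str) -> float:
        return self.library_expression[(locus, lib)]

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for loc in self.planted_loci:
            row = {
                "name": loc.name, "chrom": loc.chrom, "start": loc.start,
                "end": loc.end, "strand": loc.strand,
                "mature_seq": loc.mature_seq, "arm": loc.arm,
                "star_seq": loc.star_seq,
                "duplex_mismatches": loc.duplex_mismatches,
            }
            for lib in LIBRARIES:
                row[f"rpm_{lib}"] = self.library_expression[(loc.name, lib)]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for loc in self.planted_loci:
                attrs = [
                    f"ID={loc.name}",
                    f"mature_seq={loc.mature_seq}",
                    f"arm={loc.arm}",
                ] + [
                    f"rpm_{lib}={self.library_expression[(loc.name, lib)]:g}"
                    for lib in LIBRARIES
                ]
                fh.write(
                    f"{loc.chrom}\tsaltmir_synthetic\tmiRNA_primary_transcript\t"
                    f"{loc.start + 1}\t{loc.end}\t.\t{loc.strand}\t.\t"
                    + ";".join(attrs) + "\n"
                )


class HairpinConstructionError(RuntimeError):
    pass


class GenomeCapacityError(ValueError):
    pass


_NONPAIRING = {
    # substitution for the star base opposite mature base m that can neither
    # Watson-Crick pair nor G:U wobble with m
    "A": "A",   # opposite A: complement T, wobble none -> A (A:A)
    "C": "C",   # opposite C: complement G -> C (C:C)
    "G": "G",   # opposite G: complement C, wobble T(U) -> G (G:G)
    "T": "C",   # opposite T: complement A, wobble G -> C (T:C)
}


def plant_hairpin(
    mature_seq: str | None = None,
    arm: str = "5p",
    loop_len: int = 12,
    duplex_mismatches: int = 0,
    seed: int | np.random.Generator = 0,
    mature_len: int = 21,
    pad_len: int = 18,
    max_tries: int = 60,
) -> tuple[str, str, int]:
    """Construct a precursor around a mature sequence so that folding places
    the mature entirely in the requested arm with exactly the requested
    number of unpaired mature positions opposite the star.

    Returns (precursor_seq, star_seq, mature_offset), all DNA, precursor in
    5'->3' orientation. The star carries the canonical 2-nt 3' overhang.
    Construction is validated by folding; flanks/loop are resampled within a
    retry budget if an alternative fold dominates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if loop_len < 8:
        raise ValueError(f"loop_len must be >= 8, got {loop_len}")
    if duplex_mismatches > 6:
        raise ValueError(f"duplex_mismatches must be <= 6, got {duplex_mismatches}")
    if arm not in ("5p", "3p"):
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    if mature_seq is not None:
        mature_seq = mature_seq.upper()
        if not 20 <= len(mature_seq) <= 24:
            raise ValueError("mature length must be 20-24 nt")

    for _ in range(max_tries):
        m = mature_seq or random_seq(rng, mature_len, gc=0.5)
        if not 20 <= len(m) <= 24:
            raise ValueError("mature length must be 20-24 nt")
        # interior mismatch positions, keeping duplex ends paired
        if duplex_mismatches:
            pos = rng.choice(
                np.arange(2, len(m) - 2), size=duplex_mismatches, replace=False
            )
        else:
            pos = []
        star_core = list(revcomp(m))  # pairs m fully, antiparallel
        for p in pos:
            # star index opposite mature position p
            star_core[len(m) - 1 - p] = _NONPAIRING[m[p]]
        star_core = "".join(star_core)

        pad5 = random_seq(rng, pad_len, gc=0.55)
        pad3 = revcomp(pad5)  # perfectly paired lower stem
        # loop from A/C only: cannot self-pair (no G/T partners for A or C)
        loop = "".join(rng.choice(["A", "C"], size=loop_len, p=[0.6, 0.4]))

        if arm == "5p":
            precursor = pad5 + m + loop + star_core + pad3
            mature_offset = pad_len
            # star with 2-nt 3' overhang extends into pad3
            star = star_core + pad3[:2]
        else:
            precursor = pad5 + star_core + loop + m + pad3
            mature_offset = pad_len + len(star_core) + loop_len
            # star 3' end faces the loop
            star = star_core + loop[:2]

        if len(precursor) < 60:
            raise ValueError("precursor shorter than 60 nt; increase pads/loop")

        cand = discovery.evaluate_hairpin(precursor, mature_offset, len(m))
        if (
            cand.arm == arm
            and cand.duplex_mismatches == duplex_mismatches
            and cand.verdict["single_loop"]
            and cand.all_pass
        ):
            return precursor, star, mature_offset
    raise HairpinConstructionError(
        f"no valid fold in {max_tries} tries (arm={arm}, mm={duplex_mismatches})"
    )


def generate_genome(
    n_chrom: int = 1,
    chrom_len: int = 50_000,
    gc: float = 0.43,
    n_hairpins: int = 10,
    seed: int = 0,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Random genome with non-overlapping planted pre-miRNA hairpins.

    Every planted precursor satisfies the discovery pass-criteria by
    construction (asserted via folding inside :func:`plant_hairpin`).
    """
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    total = n_chrom * chrom_len
    if n_hairpins * 300 > total:
        raise GenomeCapacityError(
            f"{n_hairpins} hairpins need ~{n_hairpins * 300} nt, genome has {total}"
        )
    g_rng = np.random.default_rng([seed, _STREAM_GENOME])
    h_rng = np.random.default_rng([seed, _STREAM_HAIRPIN])

    genome = {
        f"chr{i + 1}": random_seq(g_rng, chrom_len, gc) for i in range(n_chrom)
    }

    loci: list[PlantedLocus] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for k in range(n_hairpins):
        arm = "5p" if h_rng.random() < 0.5 else "3p"
        mm = int(h_rng.integers(0, 4))
        loop_len = int(h_rng.integers(10, 16))
        mlen = int(h_rng.integers(20, 25))
        precursor, star, moff = plant_hairpin(
            None, arm=arm, loop_len=loop_len, duplex_mismatches=mm,
            seed=h_rng, mature_len=mlen,
        )
        mature = precursor[moff:moff + mlen]
        placed = False
        for _ in range(200):
            chrom = f"chr{int(h_rng.integers(0, n_chrom)) + 1}"
            start = int(h_rng.integers(0, chrom_len - len(precursor)))
            end = start + len(precursor)
            if all(e <= start - 50 or s >= end + 50 for s, e in occupied[chrom]):
                placed = True
                break
        if not placed:
            raise GenomeCapacityError("could not place hairpins without overlap")
        strand = "+" if h_rng.random() < 0.5 else "-"
        inserted = precursor if strand == "+" else revcomp(precursor)
        genome[chrom] = genome[chrom][:start] + inserted + genome[chrom][end:]
        occupied[chrom].append((start, end))
        loci.append(PlantedLocus(
            name=f"syn-miR{9000 + k}", chrom=chrom, start=start, end=end,
            strand=strand, mature_seq=mature, arm=arm, star_seq=star,
            precursor_seq=precursor, mature_offset=moff,
            duplex_mismatches=mm,
        ))

    truth = SyntheticTruth(
        seed=seed, genome_path=None, planted_loci=loci,
        library_expression=assign_library_expression(loci, seed),
        contaminant_fraction=0.25,
    )
    return genome, truth


def assign_library_expression(
    loci: list[PlantedLocus], seed: int
) -> dict[tuple[str, str], float]:
    """Programmed per-library RPM per locus: a log-uniform base abundance
    (200-2000 RPM) with per-locus tissue and salt-response multipliers drawn
    from {1/3, 1, 3}, mimicking tissue-specific and salt-responsive
    expression."""
    rng = np.random.default_rng([seed, _STREAM_EXPRESSION])
    expr: dict[tuple[str, str], float] = {}
    factors = np.array([1 / 3, 1.0, 3.0])
    for loc in loci:
        base = float(np.exp(rng.uniform(np.log(200), np.log(2000))))
        shoot = float(rng.choice(factors))       # shoot vs root
        salt_r = float(rng.choice(factors))      # treated vs control, root
        salt_s = float(rng.choice(factors))      # treated vs control, shoot
        expr[(loc.name, "CR")] = round(base, 3)
        expr[(loc.name, "TR")] = round(base * salt_r, 3)
        expr[(loc.name, "CS")] = round(base * shoot, 3)
        expr[(loc.name, "TS")] = round(base * shoot * salt_s, 3)
    total = {lib: sum(expr[(l.name, lib)] for l in loci) for lib in LIBRARIES}
    for lib, t in total.items():
        if t > 1e6:
            raise ValueError(f"programmed RPM in {lib} exceeds 1e6 ({t:.0f})")
    return expr


def make_ncrna_db(seed: int = 0, n_trna: int = 12, n_rrna: int = 6,
                  n_snorna: int = 6) -> list[tuple[str, str]]:
    """Synthetic contaminant ncRNA set (tRNA-, rRNA-, snoRNA-sized random
    sequences) with class-prefixed identifiers."""
    rng = np.random.default_rng([seed, _STREAM_NCRNA])
    db = []
    for i in range(n_trna):
        db.append((f"tRNA_{i + 1:03d}", random_seq(rng, int(rng.integers(70, 91)), 0.55)))
    for i in range(n_rrna):
        db.append((f"rRNA_{i + 1:03d}", random_seq(rng, int(rng.integers(110, 161)), 0.52)))
    for i in range(n_snorna):
        db.append((f"snoRNA_{i + 1:03d}", random_seq(rng, int(rng.integers(60, 101)), 0.48)))
    return db


def make_catalog(
    seed: int = 0,
    n_decoys: int = 50,
    known: list[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Mature-miRNA catalog with miRBase-style names: ``known`` entries
    (name, DNA sequence) plus random decoy matures."""
    rng = np.random.default_rng([seed, _STREAM_CATALOG])
    catalog = list(known or [])
    suffixes = "abcdefgh"
    for i in range(n_decoys):
        fam = int(rng.integers(150, 999))
        name = f"osa-miR{fam}{suffixes[int(rng.integers(0, len(suffixes)))]}"
        catalog.append((name, random_seq(rng, int(rng.integers(20, 25)), 0.5)))
    # deduplicate names deterministically
    seen: dict[str, str] = {}
    for name, s in catalog:
        while name in seen:
            name += "x"
        seen[name] = s
    return sorted(seen.items())


def make_transcriptome(
    loci: list[PlantedLocus],
    seed: int = 0,
    n_transcripts: int = 8,
    length: int = 400,
    site_mismatches: tuple[int, ...] = (0, 1),
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Synthetic transcripts with planted target sites (perfect reverse
    complements of planted matures, optionally with one non-seed mismatch).

    Returns (transcripts, planted_sites) where each planted site records the
    transcript, position, miRNA and number of mismatches.
    """
    rng = np.random.default_rng([seed, _STREAM_TRANSCRIPTOME])
    transcripts = [
        (f"TX{i + 1:03d}", random_seq(rng, length, 0.47))
        for i in range(n_transcripts)
    ]
    sites = []
    for j, loc in enumerate(loci):
        t_idx = j % n_transcripts
        name, seq = transcripts[t_idx]
        site = revcomp(loc.mature_seq)
        mm = int(site_mismatches[j % len(site_mismatches)])
        if mm:
            # non-seed target mismatch: site index p pairs miRNA position
            # len(site)-p (1-based from the miRNA 5' end), so p < len-14
            # lies outside the doubled 2-13 seed region
            p = int(rng.integers(0, max(1, len(site) - 14)))
            m_base = loc.mature_seq[len(site) - p - 1]
            site = site[:p] + _NONPAIRING[m_base] + site[p + 1:]
        pos = int(rng.integers(50, length - len(site) - 50))
        seq = seq[:pos] + site + seq[pos + len(site):]
        transcripts[t_idx] = (name, seq)
        sites.append({
            "transcript": name, "position": pos, "mirna": loc.name,
            "mature_seq": loc.mature_seq, "mismatches": mm,
        })
    return transcripts, sites


def simulate_reads(
    truth: SyntheticTruth,
    depth: int = 100_000,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    ncrna_db: list[tuple[str, str]] | None = None,
    genome: dict[str, str] | None = None,
    error_rate: float = 0.0,
) -> tuple[dict[str, Path] | dict[str, list[str]], dict[tuple[str, str], int]]:
    """Simulate the four adapter-ligated FASTQ libraries.

    Each read is an sRNA insert + 3' adapter + random fill, truncated to the
    50 nt sequencer read length, with constant Phred+33 quality. Inserts are
    drawn from planted matures (exact per-library quotas from the programmed
    RPM), contaminant ncRNA windows (``contaminant_fraction``) and random
    genomic background with the 23-24 nt length peak.

    Returns (per-library FASTQ paths, or in-memory read lists when
    ``out_dir`` is None) and the per-(locus, library) planted read counts.
    """
    if depth < 1000:
        raise ValueError(f"depth must be >= 1000, got {depth}")
    seed = truth.seed if seed is None else seed
    ncrna_db = ncrna_db if ncrna_db is not None else make_ncrna_db(seed)
    adapter = truth.adapter
    qual = "I" * READ_LENGTH

    outputs: dict[str, object] = {}
    planted_counts: dict[tuple[str, str], int] = {}
    for lib in LIBRARIES:
        rng = np.random.default_rng([seed, _STREAM_READS[lib]])
        n_contam = round(truth.contaminant_fraction * depth)
        n_usable = depth - n_contam
        inserts: list[str] = []
        for loc in truth.planted_loci:
            rpm = truth.library_expression[(loc.name, lib)]
            k = round(rpm * n_usable / 1e6)
            planted_counts[(loc.name, lib)] = k
            inserts.extend([loc.mature_seq] * k)
        n_background = n_usable - len(inserts)
        if n_background < 0:
            raise ValueError("programmed miRNA reads exceed library depth")

        # contaminant inserts: random windows of db sequences
        if n_contam and ncrna_db:
            idx = rng.integers(0, len(ncrna_db), size=n_contam)
            lens = _length_sampler(rng, n_contam)
            for i, L in zip(idx, lens):
                s = ncrna_db[int(i)][1]
                L = int(min(L, len(s)))
                p = int(rng.integers(0, len(s) - L + 1))
                inserts.append(s[p:p + L])

        # background: random genome windows (or random sequence w/o genome)
        if n_background:
            lens = _length_sampler(rng, n_background)
            if genome:
                chroms = list(genome)
                cidx = rng.integers(0, len(chroms), size=n_background)
                strands = rng.random(n_background) < 0.5
                for ci, L, fwd in zip(cidx, lens, strands):
                    cseq = genome[chroms[int(ci)]]
                    p = int(rng.integers(0, len(cseq) - int(L)))
                    w = cseq[p:p + int(L)]
                    inserts.append(w if fwd else revcomp(w))
            else:
                for L in lens:
                    inserts.append(random_seq(rng, int(L), 0.45))

        rng.shuffle(inserts)
        reads = []
        fill_pool = random_seq(rng, READ_LENGTH)
        for i, ins in enumerate(inserts):
            r = ins + adapter
            if len(r) < READ_LENGTH:
                r += fill_pool[:READ_LENGTH - len(r)]
            r = r[:READ_LENGTH]
            if error_rate:
                r = _apply_errors(r, rng, error_rate)
            reads.append((f"{lib}_{i + 1}", r))

        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            path = out_dir / f"{lib}.fastq"
            with open(path, "w") as fh:
                for rid, r in reads:
                    fh.write(f"@{rid}\n{r}\n+\n{qual}\n")
            outputs[lib] = path
        else:
            outputs[lib] = [r for _, r in reads]

    return outputs, planted_counts


def _apply_errors(read: str, rng: np.random.Generator, rate: float) -> str:
    n_err = rng.binomial(len(read), rate)
    if not n_err:
        return read
    chars = list(read)
    for p in rng.integers(0, len(read), size=n_err):
        chars[int(p)] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(chars)


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


def write_genome(genome: dict[str, str], path: str | Path) -> Path:
    return write_fasta(sorted(genome.items()), path)
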