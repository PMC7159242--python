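"""Published reference values for the nine Northern-validated novel rice
miRNAs (osa-miR12474 .. osa-miR12482) and the four Pokkali seedling sRNA
library read-accounting summaries (control root CR, control shoot CS,
NaCl-treated root TR, NaCl-treated shoot TS).

These printed values serve as fixed inputs for arithmetic cross-checks of
the hairpin statistics (notably the MFE index) and of the read-accounting
report; they are not recomputed from raw data, which was never deposited.

Notes on internal consistency of the printed table:

* The MFE printed for osa-miR12475 appears without a sign in part of the
  source text; |MFE| = 67.7 kcal/mol is used throughout.
* The printed MFEI for osa-miR12477 (0.90) and osa-miR12478 (0.67) do not
  satisfy the MFEI identity (|MFE|/PL*100)/(G+C%) from their own printed
  MFE/PL/A+U values; the ``mfei_consistent`` flag marks rows whose printed
  MFEI agrees with the identity to within 0.02.
"""

from __future__ import annotations

import pandas as pd

# name, mature sequence (DNA), max abundance (RPM), mature length, star
# sequence or None, miRNA/miRNA* mismatches or None, precursor length (nt),
# A+U (%), MFE (kcal/mol), printed MFEI, mfei_consistent
_NOVEL_ROWS = [
    ("osa-miR12474", "GCCCCGCGTCGCACGGATTCGT", 2212.9, 22,
     "CTGAATCCTTTGCAGACGACT", 4, 127, 37.0, -57.33, 0.71, True),
    ("osa-miR12475", "ACCGAGGCGCGTCAATTGCTG", 27.54, 21,
     "AATGACGCAGCTTATGAGGTT", 4, 175, 46.3, -67.7, 0.72, True),
    ("osa-miR12476", "ATTAATAGGGACAGTCGGGGGC", 10.52, 22,
     None, None, 114, 61.4, -34.9, 0.81, True),
    ("osa-miR12478", "CGGGGATGGAGCGACAGAAGCA", 56.22, 22,
     None, None, 100, 51.2, -34.1, 0.67, False),
    ("osa-miR12477", "TTGAGTGCAGCGTTGATGAACC", 24.33, 22,
     "TTCACCAGCACTGCACCCAATC", 3, 129, 38.0, -56.7, 0.90, False),
    ("osa-miR12479", "TTAGTTCACATCAATCTTCCT", 8.27, 21,
     None, None, 99, 55.6, -58.9, 1.34, True),
    ("osa-miR12480", "CAGCCCCGCGTCGCACGGATTCGT", 15.10, 24,
     "GGCTGAATCCTTTGCAGACGACTT", 6, 127, 37.0, -56.33, 0.71, True),
    ("osa-miR12481", "TATTATAAGACGTTTTGACT", 7.98, 20,
     None, None, 115, 71.3, -53.6, 1.62, True),
    ("osa-miR12482", "AGCAAGATATTGGGTATTTCTTTT", 0.72, 24,
     "CTAGAAATACCCAATATCTTGCTG", 3, 70, 71.4, -34.4, 1.72, True),
]

_NOVEL_COLUMNS = [
    "name", "sequence", "max_rpm", "length", "star", "duplex_mismatches",
    "precursor_length", "au_pct", "mfe", "mfei", "mfei_consistent",
]


def novel_mirna_table() -> pd.DataFrame:
    """The nine published novel rice miRNA rows with hairpin statistics."""
    return pd.DataFrame(_NOVEL_ROWS, columns=_NOVEL_COLUMNS)


# Library read accounting (reads per stage). Keys are the published stage
# descriptions collapsed to short labels.
LIBRARY_ACCOUNTING = pd.DataFrame(
    {
        "CR": [21291582, 21232204, 19549175, 19548882, 18236576, 11348615, 6887961, 29, 118, 147],
        "TR": [22498709, 22467178, 21090549, 21090188, 20103872, 7976996, 12126876, 25, 236, 261],
        "CS": [24465280, 24412174, 24182661, 24182301, 22753639, 9636726, 13116913, 35, 383, 418],
        "TS": [22021240, 21993648, 21342069, 21341350, 18112677, 8347673, 9765004, 39, 318, 357],
    },
    index=[
        "raw_reads", "hq_reads", "trimmed_len_filtered", "post_qc2",
        "non_noncode", "discarded", "usable_reads",
        "known_mirna", "novel_mirna", "total_mirna",
    ],
)

# Non-redundant 16-35 nt tag counts per library.
UNIQUE_TAGS = {"CR": 1143060, "CS": 1664461, "TR": 1219751, "TS": 1035994}
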