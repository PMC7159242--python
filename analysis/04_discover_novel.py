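"""Novel miRNA discovery: map abundant unannotated tags to the genome,
excise candidate windows, fold them and apply the hairpin criteria
(precursor >= 60 nt, single-loop stem, mature in one arm, duplex mismatches
<= 6, MFE <= -15 kcal/mol, MFEI >= 0.64, A+U 20-85%), then compare the calls
against the planted truth.

Reads results/analysis/{preprocess,sim,conserved}; writes
results/analysis/novel/ (novel_candidates.tsv, novel_loci.gff3,
novel_precursors.fasta, novel_structures.txt).
"""

import sys
sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))

import pandas as pd

from common import config
from saltmir.pipeline import stage_novel
from saltmir.preprocess import read_fasta


def main() -> None:
    cfg = config()
    out = cfg.out_dir
    tags = pd.read_csv(out / "preprocess" / "tags.tsv", sep="\t")
    genome = dict(read_fasta(out / "sim" / "genome.fasta"))
    conserved = pd.read_csv(out / "conserved" / "conserved.tsv", sep="\t")
    annotated = set(conserved["tag"]) if len(conserved) else set()
    res = stage_novel(cfg, tags, annotated, genome, out / "novel")
    tab = res["table"]
    called = tab[tab["all_pass"]]
    print(f"candidates evaluated: {len(tab)}; called novel: {len(called)}")
    cols = ["name", "sequence", "max_rpm", "length", "duplex_mismatches",
            "precursor_length", "au_pct", "mfe", "mfei"]
    print(called[cols].to_string(index=False))

    truth = pd.read_csv(out / "sim" / "truth.tsv", sep="\t")
    recovered = truth["mature_seq"].isin(set(called["sequence"]))
    print(f"\nplanted hairpins recovered: {int(recovered.sum())}/{len(truth)}")


if __name__ == "__main__":
    main()
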