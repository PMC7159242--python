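"""Score the called novel miRNAs against the transcriptome with the plant
expectation score (mismatch 1, G:U 0.5, gap 2, seed positions 2-13 doubled;
cutoff <= 3.0) and report predicted cleavage positions, then check the hits
against the planted target sites.

Reads results/analysis/{novel,sim}; writes results/analysis/targets/targets.tsv.
"""

import sys
sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))

import pandas as pd

from common import config
from saltmir.pipeline import stage_targets


def main() -> None:
    cfg = config()
    out = cfg.out_dir
    tab = pd.read_csv(out / "novel" / "novel_candidates.tsv", sep="\t")
    called = tab[tab["all_pass"]]
    mirnas = list(zip(called["name"], called["sequence"]))
    table = stage_targets(cfg, mirnas, out / "sim" / "transcripts.fasta",
                          out / "targets")
    print(f"target hits at expectation <= {cfg.thresholds.target_cutoff}: "
          f"{len(table)}")
    if len(table):
        print(table[["mirna", "transcript", "start", "end", "expectation",
                     "cleavage"]].to_string(index=False))

    planted = pd.read_csv(out / "sim" / "planted_sites.tsv", sep="\t")
    seq_to_name = dict(zip(called["sequence"], called["name"]))
    found = 0
    for site in planted.itertuples(index=False):
        name = seq_to_name.get(site.mature_seq)
        if name is None:
            continue
        sel = table[(table["mirna"] == name)
                    & (table["transcript"] == site.transcript)
                    & (table["start"] == site.position)]
        found += int(len(sel) > 0)
    print(f"planted target sites recovered: {found}/{len(planted)}")


if __name__ == "__main__":
    main()
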