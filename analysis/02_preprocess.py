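"""Run the filter cascade on the four simulated libraries: quality gate,
3' adapter trimming, second quality gate, ncRNA contaminant removal,
16-35 nt length / complexity filter, and collapsing to unique tags with RPM.

Reads results/analysis/sim/*.fastq; writes results/analysis/preprocess/
(tags.tsv, library_stats.tsv, length_histogram.tsv).
"""

import sys
sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))

from common import config
from saltmir.pipeline import stage_preprocess


def main() -> None:
    cfg = config()
    sim_dir = cfg.out_dir / "sim"
    fastq = {lib: sim_dir / f"{lib}.fastq" for lib in ("CR", "CS", "TR", "TS")}
    res = stage_preprocess(cfg, fastq, sim_dir / "ncrna.fasta",
                           cfg.simulate.adapter, cfg.out_dir / "preprocess")
    print(res["report"].to_string())
    peak = res["histogram"].set_index("length").sum(axis=1).idxmax()
    print(f"\nunique tags: {len(res['tags'])}; modal insert length: {peak} nt")


if __name__ == "__main__":
    main()
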