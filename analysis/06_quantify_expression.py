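"""Relative expression quantification across the three measurement
modalities: Pfaffl-corrected RT-qPCR ratios with paired t-tests (synthetic
Ct tables: LAO programmed 0.4-fold, Myb 1.6-fold upon treatment, n = 6,
sigma(Ct) = 0.2), U6-normalised Northern densitometry folds, and
dual-luciferase F/R comparisons with Welch tests.

Writes results/analysis/quantify/ (three tidy TSVs with ratios, p-values and
significance stars).
"""

import sys
sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))

from common import config
from saltmir.pipeline import stage_quantify


def main() -> None:
    cfg = config()
    res = stage_quantify(cfg, cfg.out_dir / "quantify")
    print("RT-qPCR (Pfaffl ratios, treated vs control):")
    print(res["qpcr"].to_string(index=False))
    print("\nNorthern densitometry (U6-normalised folds):")
    print(res["densitometry"].to_string(index=False))
    print("\nDual-luciferase (F/R ratios, Welch test):")
    print(res["luciferase"].to_string(index=False))


if __name__ == "__main__":
    main()
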