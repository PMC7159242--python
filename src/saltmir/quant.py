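"""Relative expression quantification for the three measurement modalities:
RT-qPCR (efficiency-corrected Pfaffl ratios with paired t-tests), Northern
densitometry (U6-normalised fold changes) and dual-luciferase assays
(firefly/Renilla ratios with a Welch two-sample test).

Sign convention: dCt = mean Ct(control) - mean Ct(treated), so a gene
upregulated by the treatment yields a ratio > 1. Amplification efficiencies
default to 2.0 (perfect doubling per cycle) when no standard-curve estimate
is supplied, in which case the Pfaffl ratio reduces to 2^(-ddCt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_EFFICIENCY = 2.0


def pfaffl_ratio(e_target: float, dct_target: float,
                 e_ref: float = DEFAULT_EFFICIENCY, dct_ref: float = 0.0) -> float:
    """Efficiency-corrected relative expression:
    ratio = E_target^dCt_target / E_ref^dCt_ref,
    with dCt = mean Ct(control) - mean Ct(treated) per gene."""
    for e in (e_target, e_ref):
        if not 1.0 < e <= 2.0:
            raise ValueError(f"amplification efficiency must be in (1, 2], got {e}")
    return e_target ** dct_target / e_ref ** dct_ref


def paired_t(x: list[float], y: list[float]) -> float:
    """Two-sided paired t-test p-value.

    All-zero differences (identical vectors) give p = 1.0 exactly; fewer
    than two pairs is an error.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.allclose(d, 0.0):
        return 1.0
    if np.allclose(d, d[0]):
        # identical nonzero differences: t -> inf
        return 0.0
    return float(stats.ttest_rel(x, y).pvalue)


def densitometry_relative(band_c: float, u6_c: float,
                          band_t: float, u6_t: float) -> float:
    """Treated-over-control fold change of a Northern band after U6 lane
    normalisation: (band_t/u6_t) / (band_c/u6_c)."""
    for v in (band_c, u6_c, band_t, u6_t):
        if v <= 0:
            raise ValueError("band intensities must be positive")
    return (band_t / u6_t) / (band_c / u6_c)


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    return ""


@dataclass
class RelativeExpression:
    gene: str
    tissue: str
    ratio: float
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def qpcr_relative_expression(
    qpcr: pd.DataFrame,
    reference_gene: str = "actin",
) -> pd.DataFrame:
    """Per-gene, per-tissue Pfaffl ratios (treated vs control) with a paired
    t-test on per-replicate dCt (target - reference Ct) pairs.

    Expects tidy columns: gene, tissue, condition ('control'|'treated'),
    replicate, ct, efficiency. Replicates are paired by replicate index
    (the design pairs technical triplicates across cDNA preparations, n=6).
    """
    required = {"gene", "tissue", "condition", "replicate", "ct", "efficiency"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    out = []
    for (gene, tissue), grp in qpcr.groupby(["gene", "tissue"]):
        if gene == reference_gene:
            continue
        ref = qpcr[(qpcr["gene"] == reference_gene) & (qpcr["tissue"] == tissue)]
        if ref.empty:
            raise ValueError(f"no reference gene rows for tissue {tissue}")

        def _mean_ct(df: pd.DataFrame, cond: str) -> float:
            return float(df[df["condition"] == cond]["ct"].mean())

        def _cts(df: pd.DataFrame, cond: str) -> np.ndarray:
            sel = df[df["condition"] == cond].sort_values("replicate")
            return sel["ct"].to_numpy(float)

        e_t = float(grp["efficiency"].iloc[0])
        e_r = float(ref["efficiency"].iloc[0])
        dct_t = _mean_ct(grp, "control") - _mean_ct(grp, "treated")
        dct_r = _mean_ct(ref, "control") - _mean_ct(ref, "treated")
        ratio = pfaffl_ratio(e_t, dct_t, e_r, dct_r)

        # paired test on per-replicate dCt = Ct(target) - Ct(reference)
        dct_control = _cts(grp, "control") - _cts(ref, "control")
        dct_treated = _cts(grp, "treated") - _cts(ref, "treated")
        p = paired_t(list(dct_control), list(dct_treated))
        out.append({
            "gene": gene, "tissue": tissue, "ratio": ratio,
            "p_value": p, "stars": significance_stars(p),
            "n_pairs": len(dct_control),
        })
    return pd.DataFrame(out)


def densitometry_table(dens: pd.DataFrame) -> pd.DataFrame:
    """U6-normalised treated/control folds from a densitometry table with
    columns mirna, band_c, u6_c, band_t, u6_t."""
    folds = [
        densitometry_relative(r.band_c, r.u6_c, r.band_t, r.u6_t)
        for r in dens.itertuples(index=False)
    ]
    return pd.DataFrame({"mirna": dens["mirna"], "fold": folds})


def luciferase_compare(assays: pd.DataFrame, pair: str) -> dict:
    """Per-leaf F-Luc/R-Luc ratios for one sensor/overexpressor pair and a
    Welch two-sample two-sided t-test of sensor_only vs
    sensor_plus_overexpressor groups.

    Expects columns: pair, group, leaf, f_luc, r_luc, with at least 3 leaves
    per group and strictly positive R-Luc activities.
    """
    sel = assays[assays["pair"] == pair]
    if (sel["r_luc"] <= 0).any():
        raise ValueError("R-Luc activity must be positive in every leaf")
    ratios = sel["f_luc"] / sel["r_luc"]
    groups = {}
    for g in ("sensor_only", "sensor_plus_overexpressor"):
        r = ratios[sel["group"] == g]
        if len(r) < 3:
            raise ValueError(f"group {g} has fewer than 3 leaves for pair {pair}")
        groups[g] = r.to_numpy(float)
    a, b = groups["sensor_only"], groups["sensor_plus_overexpressor"]
    if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and math.isclose(a.mean(), b.mean()):
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return {
        "pair": pair,
        "mean_sensor_only": float(a.mean()),
        "sd_sensor_only": float(a.std(ddof=1)),
        "mean_with_overexpressor": float(b.mean()),
        "sd_with_overexpressor": float(b.std(ddof=1)),
        "n_sensor_only": int(len(a)),
        "n_with_overexpressor": int(len(b)),
        "p_value": p,
        "stars": significance_stars(p),
    }


def simulate_qpcr_table(
    genes: dict[str, float],
    seed: int = 0,
    tissues: tuple[str, ...] = ("root", "shoot"),
    n_bio: int = 2,
    n_tech: int = 3,
    ct_sd: float = 0.2,
    base_ct: float = 24.0,
    efficiency: float = DEFAULT_EFFICIENCY,
    reference_gene: str = "actin",
) -> pd.DataFrame:
    """Synthetic tidy qPCR table with programmed treated/control fold changes
    per gene (``genes`` maps gene -> fold) and Gaussian Ct noise (default
    sd 0.2 cycles), 2 biological x 3 technical replicates (n = 6)."""
    rng = np.random.default_rng(seed)
    rows = []
    n = n_bio * n_tech
    for tissue in tissues:
        for gene, fold in {**genes, reference_gene: 1.0}.items():
            shift = -math.log(fold, efficiency)  # treated Ct shift
            for cond, delta in (("control", 0.0), ("treated", shift)):
                cts = base_ct + delta + rng.normal(0.0, ct_sd, size=n)
                for rep, ct in enumerate(cts, start=1):
                    rows.append({
                        "gene": gene, "tissue": tissue, "condition": cond,
                        "replicate": rep, "ct": round(float(ct), 3),
                        "efficiency": efficiency,
                    })
    return pd.DataFrame(rows)


def simulate_luciferase_table(
    pairs: dict[str, float],
    seed: int = 0,
    n_leaves: int = 9,
    base_ratio: float = 1.0,
    cv: float = 0.1,
) -> pd.DataFrame:
    """Synthetic dual-luciferase table: ``pairs`` maps construct pair ->
    repression factor of the F/R ratio in the overexpressor group (0.5 means
    halved), with multiplicative noise of coefficient of variation ``cv``."""
    rng = np.random.default_rng(seed)
    rows = []
    for pair, repression in pairs.items():
        for group, mu in (("sensor_only", base_ratio),
                          ("sensor_plus_overexpressor", base_ratio * repression)):
            for leaf in range(1, n_leaves + 1):
                r_luc = float(rng.uniform(0.8, 1.2))
                ratio = mu * float(rng.normal(1.0, cv))
                rows.append({
                    "pair": pair, "group": group, "leaf": leaf,
                    "f_luc": round(max(ratio, 1e-6) * r_luc, 6),
                    "r_luc": round(r_luc, 6),
                })
    return pd.DataFrame(rows)


def simulate_densitometry_table(
    folds: dict[str, float], seed: int = 0, base: float = 1000.0, cv: float = 0.05
) -> pd.DataFrame:
    """Synthetic densitometry table with programmed miRNA fold changes."""
    rng = np.random.default_rng(seed)
    rows = []
    for mirna, fold in folds.items():
        u6_c = base * float(rng.normal(1.0, cv))
        u6_t = base * float(rng.normal(1.0, cv))
        band_c = 0.5 * base * float(rng.normal(1.0, cv))
        band_t = band_c * fold * (u6_t / u6_c) * float(rng.normal(1.0, cv))
        rows.append({
            "mirna": mirna, "band_c": round(band_c, 3), "u6_c": round(u6_c, 3),
            "band_t": round(band_t, 3), "u6_t": round(u6_t, 3),
        })
    return pd.DataFrame(rows)
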