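#!/usr/bin/env python
"""Calibrate the blots against their HeLa titrations and score localization.

Fits one standard curve per blot and analyte, back-calculates every band to
HeLa-equivalent amounts, normalizes to the fraction markers (COX IV, beta-
ACTIN) and computes the relative localization (mitochondrial over cytosolic,
log10) of BAX and BAK for every sample.  Also plots tumor vs non-tumor BAX
against BAK localization on double-log axes.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import baxloc as bl

OUT = Path("results/analysis")


def main() -> None:
    lanes = bl.blot_quant.read_lane_table(OUT / "lanes.tsv")
    amounts = bl.calibrate_lanes(lanes, through_origin=True)
    amounts.to_csv(OUT / "amounts.tsv", sep="\t", index=False, float_format="%.10g")
    loc = bl.score_localization(bl.marker_normalize(amounts))
    loc.to_csv(OUT / "localization.tsv", sep="\t", index=False, float_format="%.10g")
    print(f"calibrated {len(amounts)} bands, scored {len(loc)} "
          f"sample x analyte localizations -> {OUT/'localization.tsv'}")

    piv = loc.pivot_table(index="patient_id", columns=["analyte", "tissue"],
                          values="log10_rel_loc", aggfunc="first")
    fig, ax = plt.subplots(figsize=(5, 5))
    for tissue, marker in (("tumor", "o"), ("non_tumor", "s")):
        ax.scatter(piv[("BAX", tissue)], piv[("BAK", tissue)], marker=marker,
                   alpha=0.7, label=tissue.replace("_", "-"))
        r = bl.pearson_correlation(piv[("BAX", tissue)], piv[("BAK", tissue)])
        print(f"  BAX vs BAK localization ({tissue}): "
              f"R = {r.statistic:.3f}, p = {r.p_value:.2e}")
    ax.set_xlabel("relative BAX localization (log10)")
    ax.set_ylabel("relative BAK localization (log10)")
    ax.legend()
    (OUT / "figures").mkdir(exist_ok=True)
    fig.savefig(OUT / "figures" / "bax_vs_bak_localization.png", dpi=150)


if __name__ == "__main__":
    main()
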