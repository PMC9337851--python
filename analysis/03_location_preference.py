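#!/usr/bin/env python
"""Where do induced pits sit on the mitochondrial network?

Two parts.  First, the desk calculation from the published proportions:
72.7% of endpoint+edge pits at endpoints gives odds 2.66 against a 50/50
null; correcting by the surface-area fractions (5.3% endpoints / 94.6%
edges) gives an odds ratio of ~47.5 and a corrected preference of 97.9%.
Second, a full synthetic round trip: scenes are planted with a known
endpoint weight, pushed through detect -> segment -> skeletonize ->
assign -> stats, and the corrected odds ratio is compared with the
planted weight (bootstrap 95% interval).
"""

import json
from pathlib import Path

from mitopits.pipeline import RunConfig, run_study
from mitopits.stats import chi2_pvalue, corrected_preference, format_p, odds
from mitopits.synthetic import NetworkSpec, PlacementModel

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "03_preference"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # desk calculation from the published inputs
    p_hat, a_end, a_edge = 0.727, 0.053, 0.946
    or_corr, pref, _c, _p = corrected_preference(p_hat, a_end, a_edge)
    print("published-input arithmetic:")
    print(f"  uncorrected odds  p/(1-p)            = {odds(p_hat):.2f}")
    print(f"  chi2 = 61.4, df = 1  ->  p           = "
          f"{format_p(chi2_pvalue(61.4, 1))}")
    print(f"  area-corrected odds ratio            = {or_corr:.1f}")
    print(f"  corrected endpoint preference        = {pref:.1f}%")
    desk = {"odds_uncorrected": odds(p_hat), "odds_ratio_corrected": or_corr,
            "preference_corrected_pct": pref,
            "p_for_chi2_61_4_df1": chi2_pvalue(61.4, 1)}
    (OUT / "desk_numbers.json").write_text(json.dumps(desk, indent=2) + "\n")

    # synthetic recovery at the corrected-odds-ratio scale of the data
    cfg = RunConfig(
        master_seed=11, n_scenes=10,
        network=NetworkSpec(seed=0, n_components=10, branch_probability=0.1,
                            mean_edge_length_nm=3000.0,
                            field_size_px=(1024, 1024)),
        placement=PlacementModel(seed=0, n_spots=10, weight_endpoint=47.5,
                                 free_fraction=0.2),
    )
    report = run_study(cfg, OUT / "run_w47.5").report
    pref_block = report["preference"]
    lo, hi = pref_block["odds_ratio_corrected_ci95"]
    print("\nsynthetic round trip (planted endpoint weight 47.5):")
    print(f"  pooled counts                        = "
          f"{report['pooled_counts']}")
    print(f"  recovered corrected odds ratio       = "
          f"{pref_block['odds_ratio_corrected']:.1f}  "
          f"(95% bootstrap [{lo:.1f}, {hi:.1f}])")
    print(f"  recovered free fraction              = "
          f"{report['free_fraction_pct']:.1f}%  (planted 20%)")
    print(f"full report under {OUT}/run_w47.5/")


if __name__ == "__main__":
    main()
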