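"""Screen every feature against binary response (CR/PR vs SD/PD) with
univariate logistic regression, BH adjustment and the q < 0.1 / q < 0.25
significance tiers; binary features below 5% prevalence are excluded first.

Reads results/features.tsv and results/cohort/clinical.tsv,
writes results/associations.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from icbscreen.config import PipelineConfig
from icbscreen.io import read_clinical
from icbscreen.stats import logistic_screen, prevalence_filter

OUT = Path("results")


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(seed=seed)
    table = pd.read_csv(OUT / "features.tsv", sep="\t").set_index("sample_id")
    clinical = read_clinical(OUT / "cohort/clinical.tsv").set_index("sample_id")

    kinds = {c: ("binary" if c.startswith("subtype_") else "continuous")
             for c in table.columns}
    screened = prevalence_filter(table, kinds, cfg.min_prevalence)
    res = logistic_screen(
        screened, clinical["response"], cfg.fdr_significant, cfg.fdr_near_significant
    )
    res.reset_index().to_csv(OUT / "associations.tsv", sep="\t", index=False)

    called = res[res["tier"] != "ns"].sort_values("q")
    print(f"screened {len(res)} features; "
          f"{(res['tier'] == 'significant').sum()} significant (q<0.1), "
          f"{(res['tier'] == 'near-significant').sum()} near-significant (q<0.25)")
    if not called.empty:
        print(called[["odds_ratio", "ci_low", "ci_high", "p", "q", "tier"]]
              .round(4).to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
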