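"""Descriptive statistics of the usable census.

Reports shells per group, covariate moments, trait prevalences and the
entrance-size x intactness correlation (the two are generated
independently, so it should sit near zero).
"""

import pandas as pd

from common import RESULTS, pipeline


def main() -> None:
    pipeline().run_stage("summarize")
    stats = pd.read_csv(RESULTS / "summary_global.tsv", sep="\t").set_index("statistic")["value"]
    print(f"shells/group: {stats['shells_per_group_mean']:.1f} +/- {stats['shells_per_group_sd']:.1f} "
          f"(range {stats['shells_per_group_min']:.0f}-{stats['shells_per_group_max']:.0f})")
    print(f"entrance: {stats['entrance_cm_mean']:.2f} +/- {stats['entrance_cm_sd']:.2f} cm; "
          f"intactness: {stats['intactness_mean']:.1f} +/- {stats['intactness_sd']:.1f}% "
          f"(median {stats['intactness_median']:.0f}%)")
    print(f"smooth {100*stats['prop_smooth']:.1f}%, sponge {100*stats['prop_sponge']:.1f}%, "
          f"surface {stats['n_surface']:.0f} vs basement {stats['n_basement']:.0f}")
    print(f"corr(entrance, intactness) = {stats['corr_entrance_intactness']:.3f}")


if __name__ == "__main__":
    main()
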