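"""Which occupant class holds which shell: baseline-category multinomial.

One row per conspecific fish with its home shell's covariates; group
identity enters as fixed-effect dummies (suppressed in the output).
Releveling the baseline yields every pairwise class comparison.
"""

import pandas as pd

from common import RESULTS, pipeline


def main() -> None:
    pipeline().run_stage("fit-member-type")
    tab = pd.read_csv(RESULTS / "member_type_mnlogit.tsv", sep="\t")
    for (base, cat), block in tab.groupby(["baseline", "category"], sort=False):
        print(f"{base} (baseline) vs {cat}:")
        for _, row in block.iterrows():
            print(f"  {row.term:38s} {row.estimate:7.2f} +/- {row.se:5.2f}  p={row.p:.4f}")
    ent = tab[tab.term == "entrance_cm_s"]
    print("\nentrance-size coefficients by pair (negative = first class gets larger shells):")
    for _, row in ent.iterrows():
        print(f"  {row.baseline} vs {row.category}: {row.estimate:.2f}")


if __name__ == "__main__":
    main()
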