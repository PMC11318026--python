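"""Surface-vs-basement shell characteristics, and which group members
live in the basement.

Two further GLMMs: one modelling shell stratum from shell traits, and one
modelling the stratum of each fish's home shell from its class (dominant
male, subordinate male, female, juvenile) with pairwise Wald contrasts.
"""

import pandas as pd

from common import RESULTS, pipeline


def main() -> None:
    pipe = pipeline()
    pipe.run_stage("fit-location")
    pipe.run_stage("fit-member-location")
    surf = pd.read_csv(RESULTS / "surface_model.tsv", sep="\t")
    print("surface-shell characteristics (log-odds of being at the surface):")
    for _, row in surf.iterrows():
        print(f"  {row.term:24s} {row.estimate:7.2f} +/- {row.se:4.2f}  p={row.p:.4f}")
    con = pd.read_csv(RESULTS / "member_location_contrasts.tsv", sep="\t")
    print("\npairwise member-type contrasts (log-odds of basement residence):")
    for _, row in con.iterrows():
        print(f"  {row.level_a:17s} vs {row.level_b:17s} {row.estimate:6.2f} +/- {row.se:4.2f}  "
              f"z={row.z:5.2f}  p={row.p:.4f}")


if __name__ == "__main__":
    main()
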