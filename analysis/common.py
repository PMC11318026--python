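"""Shared run configuration for the numbered analysis drivers.

All drivers operate on one artifact directory (``results/run``) holding a
synthetic census generated at the study's default conditions (41 social
groups). Each driver executes its pipeline stage(s) and narrates what it
found; re-running a driver only needs the artifacts of the earlier ones.
"""

from pathlib import Path

from shellrank.pipeline import Pipeline, RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "run"
SEED = 20240812
N_RAND = 300  # permutation replicates for the attractiveness index


def pipeline() -> Pipeline:
    return Pipeline(RunConfig(outdir=str(RESULTS), seed=SEED, n_rand=N_RAND, simulate={}))
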