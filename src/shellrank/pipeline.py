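"""Stage-wise orchestration of the full shelter-quality analysis.

Stages (in order): simulate-or-load, filter, scale, summarize, occupancy
GLMM (with likelihood-ratio interaction selection), surface-vs-basement
characteristics GLMM, member-type location GLMM with pairwise contrasts,
occupant-class multinomial, attractiveness index, final multinomial on the
index, report. Every stage reads its inputs from files written by earlier
stages and writes its outputs before the next stage starts, so any single
stage can be re-run from the cached artifacts and reproduce the full-run
outputs byte for byte (wall-clock entries in the manifest aside).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from shellrank import data as sdata
from shellrank.design import ModelSpec
from shellrank.errors import DependencyError, ValidationError
from shellrank.glmm import GLMMFit, fit_glmm, lrt, vif, wald_contrasts
from shellrank.index import compute_index
from shellrank.mnlogit import MNLogitFit, fit_mnlogit, relevel
from shellrank.recovery import child_seed
from shellrank.simulate import OCCUPANCY_SPEC, SyntheticConfig, assign_occupant_classes, generate_table

#: occupancy model before interaction selection
BASE_OCCUPANCY_SPEC = ModelSpec(
    response="occupied",
    fixed=(
        "intactness_pct_s",
        "entrance_cm_s",
        "location",
        "shrimp",
        "crab",
        "sponge",
        "smooth",
    ),
    group="group_id",
)
#: the two-way interactions screened by likelihood-ratio tests
CANDIDATE_INTERACTIONS = (
    "intactness_pct_s:location",
    "entrance_cm_s:location",
    "intactness_pct_s:entrance_cm_s",
)

SURFACE_SPEC = ModelSpec(
    response="is_surface",
    fixed=("intactness_pct_s", "entrance_cm_s", "shrimp", "crab", "sponge", "smooth"),
    group="group_id",
)
MEMBER_LOCATION_SPEC = ModelSpec(
    response="is_basement", fixed=("member_type",), group="group_id"
)
MEMBER_TYPE_PREDICTORS = (
    "location",
    "intactness_pct_s",
    "entrance_cm_s",
    "shrimp",
    "smooth",
    "group_factor",
)

STAGES = (
    "simulate",
    "filter",
    "scale",
    "summarize",
    "fit-occupancy",
    "fit-location",
    "fit-member-location",
    "fit-member-type",
    "index",
    "final-mnlogit",
    "report",
)


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-serializable)."""

    outdir: str
    seed: int = 0
    n_rand: int = 1000
    strict: bool = False
    simulate: dict | None = None  # SyntheticConfig field overrides
    shells_csv: str | None = None
    occupants_csv: str | None = None
    alpha_interaction: float = 0.05

    def __post_init__(self):
        has_paths = self.shells_csv is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ValidationError(
                "config must give exactly one of {shells_csv [+ occupants_csv], simulate}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)  # {stage, status, seconds}
    seeds: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, seconds: float) -> None:
        self.stages.append({"stage": stage, "status": status, "seconds": round(seconds, 3)})

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "stages": self.stages, "seeds": self.seeds}, indent=2
        )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _need(path: Path) -> Path:
    if not path.exists():
        raise DependencyError(f"missing upstream artifact: {path}")
    return path


def _load_usable(out: Path) -> pd.DataFrame:
    return pd.read_csv(_need(out / "usable.csv"))


def _load_occupants(out: Path) -> pd.DataFrame:
    return pd.read_csv(_need(out / "occupants_usable.csv"))


def _occupant_analysis_table(out: Path) -> pd.DataFrame:
    tab = sdata.build_occupant_analysis_table(_load_usable(out), _load_occupants(out))
    if len(tab) == 0:
        raise ValidationError("no conspecific occupants in the usable table")
    return tab


def _glmm_table(fit: GLMMFit) -> pd.DataFrame:
    t = fit.coef_table()
    t["sigma_group"] = fit.sigma
    t["loglik"] = fit.loglik
    return t


def _pairwise_mnlogit_table(fit: MNLogitFit, hide_prefix: str = "group_factor") -> pd.DataFrame:
    """One block per baseline-vs-category pair over all category pairs,
    in the conventional reporting layout (group dummies suppressed)."""
    blocks = []
    cats = sorted(fit.category_names)
    for i, base in enumerate(cats):
        releveled = relevel(fit, base)
        tab = releveled.coef_table(hide_terms=(hide_prefix,))
        tab = tab[tab["category"].isin(cats[i + 1 :])]
        blocks.append(tab)
    return pd.concat(blocks, ignore_index=True)


class Pipeline:
    """Executes stages against an output directory of cached artifacts."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(config=vars(config).copy())

    # -- stages ---------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config
        if cfg.simulate is None:
            shells = sdata.load_shell_table(_need(Path(cfg.shells_csv)))
            occupants = (
                sdata.load_occupant_table(_need(Path(cfg.occupants_csv)))
                if cfg.occupants_csv
                else pd.DataFrame(columns=sdata.OCCUPANT_COLUMNS)
            )
        else:
            sim = SyntheticConfig(**{**cfg.simulate, "seed": cfg.seed})
            shells, truth = generate_table(sim)
            occupants = assign_occupant_classes(
                shells, gamma_gen=sim.gamma_gen, seed=child_seed(cfg.seed, 1)
            )
            self.manifest.seeds["simulate"] = cfg.seed
            self.manifest.seeds["assign_classes"] = child_seed(cfg.seed, 1)
            (self.out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
            shells = shells.drop(columns=[c for c in shells.columns if c.endswith("_s")])
        shells.to_csv(self.out / "shells.csv", index=False)
        occupants.to_csv(self.out / "occupants.csv", index=False)

    def stage_filter(self) -> None:
        shells = sdata.validate_shell_table(pd.read_csv(_need(self.out / "shells.csv")))
        occupants = pd.read_csv(_need(self.out / "occupants.csv"))
        usable, log = sdata.apply_usability_filter(shells)
        keys = set(zip(usable["group_id"].astype(str), usable["shell_id"].astype(str)))
        occ_usable = occupants[
            [
                (str(g), str(s)) in keys
                for g, s in zip(occupants["group_id"], occupants["shell_id"])
            ]
        ]
        usable = sdata.attach_occupancy(usable, occ_usable)
        usable.to_csv(self.out / "usable.csv", index=False)
        occ_usable.to_csv(self.out / "occupants_usable.csv", index=False)
        (self.out / "filter_log.json").write_text(log.to_json())

    def stage_scale(self) -> None:
        usable = _load_usable(self.out)
        scaled, params = sdata.scale_predictors(usable, ["intactness_pct", "entrance_cm"])
        scaled["is_surface"] = (scaled["location"] == "surface").astype(int)
        scaled["is_basement"] = 1 - scaled["is_surface"]
        scaled.to_csv(self.out / "usable.csv", index=False)
        (self.out / "scaling.json").write_text(params.to_json())

    def stage_summarize(self) -> None:
        usable = _load_usable(self.out)
        occupants = _load_occupants(self.out)
        with open(_need(self.out / "filter_log.json")) as fh:
            n_collected = json.load(fh)["n_in"]
        stats = sdata.summarize(usable, occupants, collected_n=n_collected)
        _write_tsv(stats.to_frame(), self.out / "summary_global.tsv")
        _write_tsv(stats.per_group, self.out / "summary_per_group.tsv")

    def stage_fit_occupancy(self) -> None:
        usable = _load_usable(self.out)
        base = fit_glmm(BASE_OCCUPANCY_SPEC, usable)
        kept, tests = [], []
        for term in CANDIDATE_INTERACTIONS:
            cand_spec = ModelSpec(
                BASE_OCCUPANCY_SPEC.response,
                BASE_OCCUPANCY_SPEC.fixed + (term,),
                group=BASE_OCCUPANCY_SPEC.group,
            )
            res = lrt(fit_glmm(cand_spec, usable), base)
            tests.append(
                {"interaction": term, "statistic": res.statistic, "df": res.df, "p": res.p_value}
            )
            if res.p_value < self.config.alpha_interaction:
                kept.append(term)
        final_spec = ModelSpec(
            BASE_OCCUPANCY_SPEC.response,
            BASE_OCCUPANCY_SPEC.fixed + tuple(kept),
            group=BASE_OCCUPANCY_SPEC.group,
        )
        fit = fit_glmm(final_spec, usable)
        _write_tsv(pd.DataFrame(tests), self.out / "occupancy_interaction_lrt.tsv")
        _write_tsv(_glmm_table(fit), self.out / "occupancy_model.tsv")
        gvif = vif(final_spec, usable)
        _write_tsv(
            pd.DataFrame([{"term": k, "gvif": v} for k, v in gvif.items()]),
            self.out / "occupancy_vif.tsv",
        )
        (self.out / "occupancy_model.json").write_text(
            json.dumps({"fixed": list(final_spec.fixed), **fit.to_dict()}, indent=2)
        )

    def stage_fit_location(self) -> None:
        usable = _load_usable(self.out)
        fit = fit_glmm(SURFACE_SPEC, usable)
        _write_tsv(_glmm_table(fit), self.out / "surface_model.tsv")

    def stage_fit_member_location(self) -> None:
        tab = _occupant_analysis_table(self.out)
        fit = fit_glmm(MEMBER_LOCATION_SPEC, tab)
        _write_tsv(_glmm_table(fit), self.out / "member_location_model.tsv")
        _write_tsv(wald_contrasts(fit, "member_type"), self.out / "member_location_contrasts.tsv")

    def stage_fit_member_type(self) -> None:
        tab = _occupant_analysis_table(self.out)
        fit = fit_mnlogit(
            tab, list(MEMBER_TYPE_PREDICTORS), response="member_type", baseline="dominant_male"
        )
        _write_tsv(_pairwise_mnlogit_table(fit), self.out / "member_type_mnlogit.tsv")

    def stage_index(self) -> None:
        usable = _load_usable(self.out)
        with open(_need(self.out / "occupancy_model.json")) as fh:
            fixed = json.load(fh)["fixed"]
        spec = ModelSpec("occupied", fixed, group="group_id")
        seed = child_seed(self.config.seed, 2)
        self.manifest.seeds["index"] = seed
        result = compute_index(
            usable, spec, n_rand=self.config.n_rand, seed=seed, strict=self.config.strict
        )
        _write_tsv(result.table, self.out / "attractiveness_index.tsv")
        (self.out / "index_manifest.json").write_text(json.dumps(result.manifest(), indent=2))

    def stage_final_mnlogit(self) -> None:
        tab = _occupant_analysis_table(self.out)
        idx = pd.read_csv(_need(self.out / "attractiveness_index.tsv"), sep="\t")
        tab = tab.merge(
            idx[["group_id", "shell_id", "z"]], on=["group_id", "shell_id"], how="left"
        )
        tab = tab[np.isfinite(tab["z"])]
        fit = fit_mnlogit(
            tab, ["z", "group_factor"], response="member_type", baseline="dominant_male"
        )
        _write_tsv(_pairwise_mnlogit_table(fit), self.out / "final_mnlogit.tsv")

    def stage_report(self) -> None:
        self.render_report()

    def render_report(self) -> dict:
        """Assemble the report bundle from stage artifacts; returns paths."""
        wanted = {
            "summary": "summary_global.tsv",
            "filter_log": "filter_log.json",
            "occupancy_model": "occupancy_model.tsv",
            "surface_model": "surface_model.tsv",
            "member_location_contrasts": "member_location_contrasts.tsv",
            "member_type_mnlogit": "member_type_mnlogit.tsv",
            "attractiveness_index": "attractiveness_index.tsv",
            "final_mnlogit": "final_mnlogit.tsv",
        }
        paths = {}
        for key, name in wanted.items():
            _need(self.out / name)
            paths[key] = name  # relative to the run directory, diffable
        (self.out / "report.json").write_text(json.dumps(paths, indent=2))
        return paths

    # -- driver ---------------------------------------------------------

    _METHODS = None

    def run_stage(self, stage: str) -> None:
        methods = {
            "simulate": self.stage_simulate,
            "filter": self.stage_filter,
            "scale": self.stage_scale,
            "summarize": self.stage_summarize,
            "fit-occupancy": self.stage_fit_occupancy,
            "fit-location": self.stage_fit_location,
            "fit-member-location": self.stage_fit_member_location,
            "fit-member-type": self.stage_fit_member_type,
            "index": self.stage_index,
            "final-mnlogit": self.stage_final_mnlogit,
            "report": self.stage_report,
        }
        if stage not in methods:
            raise ValidationError(f"unknown stage {stage!r}; expected one of {STAGES}")
        t0 = time.perf_counter()
        try:
            methods[stage]()
        except Exception:
            self.manifest.record(stage, "failed", time.perf_counter() - t0)
            (self.out / "manifest.json").write_text(self.manifest.to_json())
            raise
        self.manifest.record(stage, "ok", time.perf_counter() - t0)

    def run(self, stages=STAGES) -> RunManifest:
        for stage in stages:
            self.run_stage(stage)
        (self.out / "manifest.json").write_text(self.manifest.to_json())
        return self.manifest


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage in order; artifacts land in ``config.outdir``."""
    return Pipeline(config).run()
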