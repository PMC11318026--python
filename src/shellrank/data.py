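"""Shell-census data model: CSV I/O, validation, usability filtering,
predictor standardization and descriptive summaries.

A census table has one row per *Neothauma* shell found on a social group's
territory: its stratum (surface vs basement), intactness rating (30-100% in
10% steps), entrance diameter (cm, the shell-size proxy), wall texture,
sponge cover, crustacean occupants, and an exclusion flag for shells that
are not actually available as shelters (live snail, sediment-blocked, or
held by a heterospecific fish). Occupant records live in a companion table,
one row per animal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from shellrank.errors import DegeneratePredictorError, SchemaError, ValidationError

SHELL_COLUMNS = [
    "group_id",
    "shell_id",
    "location",
    "intactness_pct",
    "entrance_cm",
    "smooth",
    "sponge",
    "shrimp",
    "crab",
    "excluded_reason",
]
OCCUPANT_COLUMNS = ["group_id", "shell_id", "kind", "body_size_cm"]

LOCATIONS = ("surface", "basement")
EXCLUSION_REASONS = ("none", "live_snail", "sediment_blocked", "heterospecific_fish")
#: occupant classes counted as conspecific residents (these define occupancy)
CONSPECIFIC_KINDS = ("dominant_male", "subordinate_male", "female", "juvenile")
OCCUPANT_KINDS = CONSPECIFIC_KINDS + ("heterospecific_fish", "shrimp", "crab")
BOOL_COLUMNS = ("smooth", "sponge", "shrimp", "crab")


def load_shell_table(path, schema: dict | None = None) -> pd.DataFrame:
    """Read and validate a shell census CSV.

    ``schema`` optionally maps canonical column names to the names used in
    the file. Raises :class:`SchemaError` when a required column is absent
    and :class:`ValidationError` (naming the offending row) for invariant
    violations.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return validate_shell_table(df)


def validate_shell_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"shell table missing columns: {', '.join(missing)}")
    df = df.copy()

    dup = df.duplicated(subset=["group_id", "shell_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"duplicate (group_id, shell_id) at row {i}: "
            f"({df['group_id'].iloc[i]!r}, {df['shell_id'].iloc[i]!r})"
        )

    intact = pd.to_numeric(df["intactness_pct"], errors="coerce")
    bad = ~(intact.between(30, 100) & (intact % 10 == 0))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"intactness_pct must be a multiple of 10 in [30, 100]; "
            f"row {i} has {df['intactness_pct'].iloc[i]!r}"
        )
    df["intactness_pct"] = intact.astype(int)

    ent = pd.to_numeric(df["entrance_cm"], errors="coerce")
    bad = ~(ent > 0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"entrance_cm must be > 0; row {i} has {df['entrance_cm'].iloc[i]!r}")
    df["entrance_cm"] = ent.astype(float)

    for col, allowed in (("location", LOCATIONS), ("excluded_reason", EXCLUSION_REASONS)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"{col} must be one of {allowed}; row {i} has {df[col].iloc[i]!r}")

    for col in BOOL_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if not vals.isin([0, 1]).all():
            raise ValidationError(f"{col} must be encoded 0/1")
        df[col] = vals.astype(int)
    return df


def load_occupant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCCUPANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"occupant table missing columns: {', '.join(missing)}")
    bad = ~df["kind"].isin(OCCUPANT_KINDS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"unknown occupant kind at row {i}: {df['kind'].iloc[i]!r}")
    size = pd.to_numeric(df["body_size_cm"], errors="coerce")
    if ((size <= 0) & df["body_size_cm"].notna()).any():
        raise ValidationError("body_size_cm must be > 0 when present")
    df = df.copy()
    df["body_size_cm"] = size
    return df


def attach_occupancy(shells: pd.DataFrame, occupants: pd.DataFrame | None) -> pd.DataFrame:
    """Add the binary ``occupied`` column: 1 iff at least one conspecific
    (dominant/subordinate male, female or juvenile) lives in the shell.
    A shell shared by several fish still counts as one occupied shell.
    """
    shells = shells.copy()
    if occupants is None or len(occupants) == 0:
        shells["occupied"] = 0
        return shells
    consp = occupants[occupants["kind"].isin(CONSPECIFIC_KINDS)]
    keys = set(zip(consp["group_id"], consp["shell_id"]))
    shells["occupied"] = [
        int((g, s) in keys) for g, s in zip(shells["group_id"], shells["shell_id"])
    ]
    return shells


def build_occupant_analysis_table(
    shells: pd.DataFrame, occupants: pd.DataFrame
) -> pd.DataFrame:
    """One row per conspecific fish with its home shell's covariates.

    Shells shared by several fish contribute one row per fish. Adds
    ``member_type`` (the fish's class), ``is_basement``/``is_surface``
    indicators, and ``group_factor`` (group ID as a categorical string for
    fixed-effect dummies).
    """
    consp = occupants[occupants["kind"].isin(CONSPECIFIC_KINDS)].copy()
    merged = consp.merge(shells, on=["group_id", "shell_id"], how="inner", validate="m:1")
    merged = merged.rename(columns={"kind": "member_type"})
    merged["is_surface"] = (merged["location"] == "surface").astype(int)
    merged["is_basement"] = 1 - merged["is_surface"]
    merged["group_factor"] = merged["group_id"].astype(str)
    return merged.reset_index(drop=True)


@dataclass
class FilterLog:
    """Tally of shells removed by the usability filter, per reason."""

    n_in: int
    n_out: int
    removed: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"n_in": self.n_in, "n_out": self.n_out, "removed": self.removed})


def apply_usability_filter(shells: pd.DataFrame) -> tuple[pd.DataFrame, FilterLog]:
    """Drop shells that are not available as shelters.

    Shells flagged as belonging to a live snail, blocked by sediment/other
    shells, or occupied by a heterospecific fish are removed; the log
    satisfies ``n_in == n_out + sum(removed.values())`` exactly.
    """
    keep = shells["excluded_reason"] == "none"
    removed = {
        reason: int((shells["excluded_reason"] == reason).sum())
        for reason in EXCLUSION_REASONS
        if reason != "none"
    }
    out = shells[keep].reset_index(drop=True)
    return out, FilterLog(n_in=len(shells), n_out=len(out), removed=removed)


@dataclass(frozen=True)
class ScalingParams:
    """Standardization constants (mean, sample SD with n-1 denominator) per
    variable, retained so the identical transform can be re-applied to any
    later table (including every permutation refit)."""

    params: dict  # var -> (mean, sd)

    def apply(self, df: pd.DataFrame, suffix: str = "_s") -> pd.DataFrame:
        df = df.copy()
        for var, (m, s) in self.params.items():
            df[var + suffix] = (pd.to_numeric(df[var]) - m) / s
        return df

    def unscale(self, values, var: str):
        m, s = self.params[var]
        return np.asarray(values, dtype=float) * s + m

    def to_json(self) -> str:
        return json.dumps({k: {"mean": m, "sd": s} for k, (m, s) in self.params.items()})


def scale_predictors(
    df: pd.DataFrame, variables: list[str], suffix: str = "_s"
) -> tuple[pd.DataFrame, ScalingParams]:
    """Standardize continuous predictors to mean 0, sample SD 1.

    Returns the table with added ``<var>_s`` columns plus the constants
    used, so downstream refits reuse the same transform verbatim.
    Raises :class:`DegeneratePredictorError` on zero-variance input.
    """
    params = {}
    for var in variables:
        if var not in df.columns:
            raise SchemaError(f"cannot scale missing column {var!r}")
        x = pd.to_numeric(df[var]).to_numpy(float)
        m = float(np.mean(x))
        s = float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
        # an SD at round-off scale of the mean is zero variance in practice
        if not np.isfinite(s) or s <= 1e-12 * max(1.0, abs(m)):
            raise DegeneratePredictorError(f"predictor {var!r} has zero or undefined variance")
        params[var] = (m, s)
    sp = ScalingParams(params)
    return sp.apply(df, suffix=suffix), sp


@dataclass
class SummaryStats:
    """Global and per-group descriptive statistics for a usable census."""

    n_shells: int
    n_groups: int
    global_stats: dict
    per_group: pd.DataFrame
    occupant_census: dict
    corr_entrance_intactness: float  # NaN when undefined (n < 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"statistic": k, "value": v} for k, v in self.global_stats.items()]
        rows.append(
            {"statistic": "corr_entrance_intactness", "value": self.corr_entrance_intactness}
        )
        return pd.DataFrame(rows)


def _moments(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    return {
        "mean": float(np.mean(x)) if x.size else float("nan"),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else float("nan"),
        "min": float(np.min(x)) if x.size else float("nan"),
        "max": float(np.max(x)) if x.size else float("nan"),
        "median": float(np.median(x)) if x.size else float("nan"),
    }


def summarize(
    shells: pd.DataFrame,
    occupants: pd.DataFrame | None = None,
    collected_n: int | None = None,
) -> SummaryStats:
    """Descriptive summary of a (usable) shell table.

    ``collected_n`` optionally supplies the pre-filter census size so that
    trait prevalences are reported against both denominators (the usable
    set and the full collection).
    """
    n = len(shells)
    groups = shells.groupby("group_id", sort=True)
    per_group = groups.agg(
        n_shells=("shell_id", "size"),
        n_surface=("location", lambda s: int((s == "surface").sum())),
        mean_entrance_cm=("entrance_cm", "mean"),
        mean_intactness=("intactness_pct", "mean"),
    )
    if "occupied" in shells.columns:
        per_group["n_occupied"] = groups["occupied"].sum()

    g: dict = {"n_shells": n, "n_groups": len(per_group)}
    counts = per_group["n_shells"].to_numpy(float)
    g.update({f"shells_per_group_{k}": v for k, v in _moments(counts).items()})
    g.update({f"entrance_cm_{k}": v for k, v in _moments(shells["entrance_cm"]).items()})
    g.update({f"intactness_{k}": v for k, v in _moments(shells["intactness_pct"]).items()})
    for col in ("smooth", "sponge", "shrimp", "crab"):
        c = int(shells[col].sum())
        g[f"n_{col}"] = c
        g[f"prop_{col}"] = c / n if n else float("nan")
        if collected_n:
            g[f"prop_{col}_of_collected"] = c / collected_n
    g["n_surface"] = int((shells["location"] == "surface").sum())
    g["n_basement"] = int((shells["location"] == "basement").sum())
    if "occupied" in shells.columns:
        g["n_occupied"] = int(shells["occupied"].sum())
        g["prop_occupied"] = g["n_occupied"] / n if n else float("nan")

    census: dict = {}
    if occupants is not None and len(occupants):
        census = occupants["kind"].value_counts().to_dict()
        census = {k: int(v) for k, v in census.items()}

    if n > 1 and shells["entrance_cm"].nunique() > 1 and shells["intactness_pct"].nunique() > 1:
        corr = float(
            np.corrcoef(shells["entrance_cm"], shells["intactness_pct"].astype(float))[0, 1]
        )
    else:
        corr = float("nan")

    return SummaryStats(
        n_shells=n,
        n_groups=len(per_group),
        global_stats=g,
        per_group=per_group.reset_index(),
        occupant_census=census,
        corr_entrance_intactness=corr,
    )
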