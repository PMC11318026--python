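"""Synthetic shell-census generator matched to the field study's conditions.

Emulates 41 social groups on a Lake Tanganyika shell bed: shells per group
follow a truncated negative binomial (mean 25.8, SD 15.8, range 4-76),
entrance size a truncated rounded normal (2.00 +/- 0.22 cm, 1.1-2.7),
intactness a rounded-to-10 clipped normal (76.7 +/- 23.0, floor 30), and
binary shell traits have the prevalences reported for the usable census
(surface 775/1057, smooth 7.2%, sponge 4.6%, shrimp 43/1057, crab 35/1057).

Occupancy is drawn from the logistic random-intercept model whose slopes
default to the occupancy-model estimates, with the intercept solved
numerically so the expected marginal occupancy is 226/1057; occupant
classes are then assigned from a baseline-category logit with the
occupant-class coefficient defaults (group effects zero). The generating
truth is returned alongside the table so that parameter-recovery tests can
compare fitted coefficients with what generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit, softmax

from shellrank.data import scale_predictors
from shellrank.design import ModelSpec, build_design
from shellrank.errors import ValidationError

#: final shell-occupancy model: intactness x location interaction retained
OCCUPANCY_SPEC = ModelSpec(
    response="occupied",
    fixed=(
        "intactness_pct_s",
        "entrance_cm_s",
        "location",
        "shrimp",
        "crab",
        "sponge",
        "smooth",
        "intactness_pct_s:location",
    ),
    group="group_id",
)

#: occupancy-model generating slopes (log-odds; continuous terms per SD)
DEFAULT_BETA_GEN = {
    "intactness_pct_s": 1.21,
    "entrance_cm_s": 0.17,
    "location[surface]": 0.0,  # main effect unreported; free default
    "shrimp": -0.93,
    "crab": -1.94,
    "sponge": -0.98,
    "smooth": -0.43,
    "intactness_pct_s:location[surface]": 0.66,
}

#: occupant-class model design (class assignment and refits share it)
CLASS_PREDICTORS = ("location", "intactness_pct_s", "entrance_cm_s", "shrimp", "smooth")

#: generating occupant-class coefficients vs the dominant-male baseline
#: (columns: intercept, surface, intactness_s, entrance_s, shrimp, smooth)
DEFAULT_GAMMA_GEN = {
    "subordinate_male": {
        "(Intercept)": -0.35,
        "location[surface]": 0.20,
        "intactness_pct_s": 1.88,
        "entrance_cm_s": -1.20,
        "shrimp": 1.74,
        "smooth": 0.72,
    },
    "female": {
        "(Intercept)": 4.08,
        "location[surface]": -0.25,
        "intactness_pct_s": -2.62,
        "entrance_cm_s": -1.63,
        "shrimp": 2.96,
        "smooth": 0.90,
    },
    "juvenile": {
        "(Intercept)": 6.13,
        "location[surface]": -0.95,
        "intactness_pct_s": -4.89,
        "entrance_cm_s": -2.26,
        "shrimp": 1.94,
        "smooth": 0.13,
    },
}

#: standard-length laws per occupant class (cm), used for body sizes only
BODY_SIZE_LAWS = {
    "dominant_male": (2.73, 0.16),
    "subordinate_male": (2.38, 0.14),
    "female": (1.92, 0.10),
    "juvenile": (1.64, 0.28),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults are the study conditions."""

    n_groups: int = 41
    shells_per_group_mean: float = 25.8
    shells_per_group_sd: float = 15.8
    shells_per_group_range: tuple[int, int] = (4, 76)
    entrance_mean: float = 2.00
    entrance_sd: float = 0.22
    entrance_range: tuple[float, float] = (1.1, 2.7)
    intactness_mean: float = 76.7
    intactness_sd: float = 23.0
    intactness_range: tuple[int, int] = (30, 100)
    p_surface: float = 775.0 / 1057.0
    p_smooth: float = 0.072
    p_sponge: float = 0.046
    p_shrimp: float = 43.0 / 1057.0
    p_crab: float = 35.0 / 1057.0
    beta_gen: dict = field(default_factory=lambda: dict(DEFAULT_BETA_GEN))
    target_occupancy: float = 226.0 / 1057.0
    sigma_group: float = 0.5
    gamma_gen: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GAMMA_GEN.items()})
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_surface", "p_smooth", "p_sponge", "p_shrimp", "p_crab", "target_occupancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        for name in ("shells_per_group_range", "entrance_range", "intactness_range"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValidationError(f"{name} bounds out of order: ({lo}, {hi})")
        if self.n_groups < 2:
            raise ValidationError("need at least 2 groups")
        if self.sigma_group < 0:
            raise ValidationError("sigma_group must be >= 0")

    def with_null_effects(self) -> "SyntheticConfig":
        """Copy with every occupancy slope set to zero (null calibration)."""
        return replace(self, beta_gen={k: 0.0 for k in self.beta_gen})


@dataclass
class SyntheticTruth:
    """What actually generated a table, for recovery tests."""

    beta: dict  # generating slopes by design-column name
    intercept: float
    sigma: float
    u_groups: np.ndarray  # drawn random intercepts, by group order
    group_ids: list
    gamma: dict
    target_occupancy: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "intercept": self.intercept,
            "sigma": self.sigma,
            "u_groups": self.u_groups.tolist(),
            "group_ids": list(self.group_ids),
            "gamma": self.gamma,
            "target_occupancy": self.target_occupancy,
            "seed": self.seed,
        }


def _truncated_negbinom(rng, mean, sd, lo, hi, size):
    var = sd * sd
    if var <= mean:
        raise ValidationError("shells-per-group SD implies underdispersion; need var > mean")
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    out = np.empty(size, dtype=int)
    filled = 0
    while filled < size:
        draw = rng.negative_binomial(r, p, size=2 * (size - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def solve_intercept(eta: np.ndarray, sigma: float, target: float, n_nodes: int = 41) -> float:
    """Intercept beta0 such that mean_i E_u[expit(beta0 + eta_i + u)] = target."""
    z, w = hermegauss(n_nodes)
    w = w / np.sqrt(2.0 * np.pi)

    def marginal_mean(b0):
        return float(np.mean(expit(b0 + eta[:, None] + sigma * z[None, :]) @ w)) - target

    return float(brentq(marginal_mean, -20.0, 20.0, xtol=1e-10))


def generate_table(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic usable shell census plus its generating truth.

    The returned table carries the scaled covariate columns
    (``*_s``, standardized on this table, as the analysis pipeline would)
    and the drawn ``occupied`` flag.
    """
    config = config or SyntheticConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    lo, hi = config.shells_per_group_range
    n_shells = _truncated_negbinom(
        rng, config.shells_per_group_mean, config.shells_per_group_sd, lo, hi, config.n_groups
    )
    group_ids = [f"G{i + 1:02d}" for i in range(config.n_groups)]
    gid = np.repeat(group_ids, n_shells)
    n = int(n_shells.sum())

    elo, ehi = config.entrance_range
    entrance = np.round(_truncated_normal(rng, config.entrance_mean, config.entrance_sd, elo, ehi, n), 1)
    ilo, ihi = config.intactness_range
    intact = np.clip(
        np.round(rng.normal(config.intactness_mean, config.intactness_sd, size=n) / 10.0) * 10.0,
        ilo,
        ihi,
    ).astype(int)

    shells = pd.DataFrame(
        {
            "group_id": gid,
            "shell_id": [f"S{j + 1:03d}" for cnt in n_shells for j in range(cnt)],
            "location": np.where(rng.random(n) < config.p_surface, "surface", "basement"),
            "intactness_pct": intact,
            "entrance_cm": entrance,
            "smooth": (rng.random(n) < config.p_smooth).astype(int),
            "sponge": (rng.random(n) < config.p_sponge).astype(int),
            "shrimp": (rng.random(n) < config.p_shrimp).astype(int),
            "crab": (rng.random(n) < config.p_crab).astype(int),
            "excluded_reason": "none",
        }
    )
    shells, _ = scale_predictors(shells, ["intactness_pct", "entrance_cm"])

    d = build_design(OCCUPANCY_SPEC, shells, response=False)
    beta = np.zeros(d.p)
    for name, val in config.beta_gen.items():
        if name not in d.columns:
            raise ValidationError(f"beta_gen names unknown design column {name!r}")
        beta[d.columns.index(name)] = val
    eta = d.X @ beta  # intercept column multiplies 0 here
    beta0 = solve_intercept(eta, config.sigma_group, config.target_occupancy)

    u = rng.normal(0.0, config.sigma_group, size=config.n_groups)
    p_occ = expit(beta0 + eta + u[d.groups])
    shells["occupied"] = (rng.random(n) < p_occ).astype(int)

    truth = SyntheticTruth(
        beta=dict(config.beta_gen),
        intercept=beta0,
        sigma=config.sigma_group,
        u_groups=u,
        group_ids=[d.group_levels[i] for i in range(config.n_groups)],
        gamma={k: dict(v) for k, v in config.gamma_gen.items()},
        target_occupancy=config.target_occupancy,
        seed=seed,
    )
    return shells, truth


def class_probabilities(shells: pd.DataFrame, gamma_gen: dict) -> tuple[pd.DataFrame, list]:
    """Softmax category law for each shell under the generating coefficients.

    Returns the (n, 4) probability frame (dominant-male baseline first) for
    the given shells, in the class order used by the sampler.
    """
    spec = ModelSpec(response="occupied", fixed=CLASS_PREDICTORS)
    # evaluation only: a trait constant over these shells is harmless here
    d = build_design(spec, shells, response=False, check_rank=False)
    classes = ["dominant_male"] + list(gamma_gen.keys())
    eta = np.zeros((len(shells), len(classes)))
    for k, cls in enumerate(classes[1:], start=1):
        gvec = np.zeros(d.p)
        for name, val in gamma_gen[cls].items():
            if name not in d.columns:
                # a factor level absent from these shells has no column;
                # its coefficient would multiply zero everywhere
                continue
            gvec[d.columns.index(name)] = val
        eta[:, k] = d.X @ gvec
    probs = softmax(eta, axis=1)
    return pd.DataFrame(probs, columns=classes, index=shells.index), classes


def assign_occupant_classes(
    shells: pd.DataFrame,
    gamma_gen: dict | None = None,
    seed: int = 0,
    body_sizes: bool = True,
) -> pd.DataFrame:
    """Draw one occupant per occupied shell from the baseline-category logit.

    Group effects are zero in the generating law (the class model sees group
    identity only through the fitted dummies). Returns an occupant table
    (group_id, shell_id, kind, body_size_cm).
    """
    gamma_gen = gamma_gen if gamma_gen is not None else {k: dict(v) for k, v in DEFAULT_GAMMA_GEN.items()}
    rng = np.random.default_rng(seed)
    occ = shells[shells["occupied"] == 1]
    if len(occ) == 0:
        return pd.DataFrame(columns=["group_id", "shell_id", "kind", "body_size_cm"])
    probs, classes = class_probabilities(occ, gamma_gen)
    cum = probs.to_numpy().cumsum(axis=1)
    draws = rng.random(len(occ))
    codes = (draws[:, None] > cum).sum(axis=1)
    kinds = np.array(classes, dtype=object)[codes]
    if body_sizes:
        mu = np.array([BODY_SIZE_LAWS[k][0] for k in kinds])
        sd = np.array([BODY_SIZE_LAWS[k][1] for k in kinds])
        sizes = np.round(np.clip(rng.normal(mu, sd), 1.0, None), 1)
    else:
        sizes = np.full(len(occ), np.nan)
    return pd.DataFrame(
        {
            "group_id": occ["group_id"].to_numpy(),
            "shell_id": occ["shell_id"].to_numpy(),
            "kind": kinds,
            "body_size_cm": sizes,
        }
    )
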