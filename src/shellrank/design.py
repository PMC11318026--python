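"""Model specification and fixed-effects design-matrix construction.

A small treatment-coded design builder shared by the occupancy GLMM, the
multinomial occupant-class model, the Wald contrast machinery and the
permutation refits, so that column names and reference levels are identical
everywhere a model is (re)fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from shellrank.errors import AliasingError, SchemaError

#: reference levels used throughout the analysis unless overridden:
#: basement shells, rough walls and dominant males are the baselines.
DEFAULT_REFERENCES = {
    "location": "basement",
    "wall_texture": "rough",
    "member_type": "dominant_male",
}


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a (generalized) linear model formula.

    Parameters
    ----------
    response:
        Name of the response column (binary 0/1 for the GLMM, categorical
        for the multinomial model).
    fixed:
        Fixed-effect terms: column names for main effects, ``"a:b"`` for a
        two-way interaction between declared main effects.
    group:
        Column holding the social-group identifier for the random intercept
        (``None`` for models without one).
    references:
        Reference level per categorical predictor; merged over
        :data:`DEFAULT_REFERENCES`.
    """

    response: str
    fixed: tuple[str, ...]
    group: str | None = None
    references: dict = field(default_factory=dict)

    def __init__(self, response, fixed, group=None, references=None):
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "fixed", tuple(fixed))
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "references", dict(references or {}))

    @property
    def main_effects(self) -> list[str]:
        return [t for t in self.fixed if ":" not in t]

    @property
    def interactions(self) -> list[str]:
        return [t for t in self.fixed if ":" in t]

    def validate(self) -> None:
        declared = set(self.main_effects)
        for term in self.interactions:
            parts = term.split(":")
            if len(parts) != 2:
                raise SchemaError(f"only two-way interactions supported: {term!r}")
            for p in parts:
                if p not in declared:
                    raise SchemaError(
                        f"interaction {term!r} references undeclared main effect {p!r}"
                    )

    def drop_term(self, term: str) -> "ModelSpec":
        """Spec without ``term`` (used for LRT model reduction)."""
        if term not in self.fixed:
            raise SchemaError(f"term {term!r} not in spec")
        return ModelSpec(
            self.response,
            [t for t in self.fixed if t != term],
            group=self.group,
            references=self.references,
        )


@dataclass
class Design:
    """Realized fixed-effects design for one data table."""

    X: np.ndarray  # (n, p) including leading intercept column
    columns: list[str]
    term_columns: dict  # term -> list of column indices into X
    y: np.ndarray | None  # response (float 0/1 or category codes)
    y_levels: list | None  # category labels when the response is categorical
    groups: np.ndarray | None  # integer group codes, aligned with rows
    group_levels: list | None
    factor_levels: dict  # categorical predictor -> ordered levels (ref first)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _reference_for(spec: ModelSpec, col: str, levels: list) -> str:
    # a configured reference need not occur in the rows at hand (subset
    # tables used for prediction); an explicitly requested one must exist
    ref = spec.references.get(col)
    if ref is not None and ref not in levels:
        raise SchemaError(f"reference level {ref!r} absent from column {col!r}")
    if ref is None:
        ref = DEFAULT_REFERENCES.get(col)
    if ref is None:
        ref = levels[0]
    return ref


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)


def _main_effect_columns(spec: ModelSpec, df: pd.DataFrame, col: str):
    """Return (matrix, names, levels-or-None) for one main effect."""
    s = df[col]
    if _is_categorical(s):
        levels = sorted(pd.unique(s.dropna()).tolist())
        ref = _reference_for(spec, col, levels)
        levels = [ref] + [l for l in levels if l != ref]  # ref may be unobserved
        mats = [(s == l).to_numpy(float)[:, None] for l in levels[1:]]
        names = [f"{col}[{l}]" for l in levels[1:]]
        return np.hstack(mats) if mats else np.empty((len(s), 0)), names, levels
    return s.to_numpy(float)[:, None], [col], None


def build_design(
    spec: ModelSpec, df: pd.DataFrame, response: bool = True, check_rank: bool = True
) -> Design:
    """Build the treatment-coded fixed-effects matrix for ``df``.

    Raises :class:`SchemaError` for missing columns and, unless
    ``check_rank`` is off (evaluation-only designs), :class:`AliasingError`
    when the design is rank deficient (naming the aliased columns).
    """
    spec.validate()
    needed = set(spec.main_effects)
    if response:
        needed.add(spec.response)
    if spec.group is not None:
        needed.add(spec.group)
    missing = sorted(needed - set(df.columns))
    if missing:
        raise SchemaError(f"missing columns: {', '.join(missing)}")

    n = len(df)
    blocks = [np.ones((n, 1))]
    names = ["(Intercept)"]
    term_columns = {"(Intercept)": [0]}
    main_mats: dict[str, tuple[np.ndarray, list[str]]] = {}
    factor_levels: dict[str, list] = {}

    for col in spec.main_effects:
        mat, cnames, levels = _main_effect_columns(spec, df, col)
        main_mats[col] = (mat, cnames)
        if levels is not None:
            factor_levels[col] = levels
        start = sum(b.shape[1] for b in blocks)
        term_columns[col] = list(range(start, start + mat.shape[1]))
        blocks.append(mat)
        names.extend(cnames)

    for term in spec.interactions:
        a, b = term.split(":")
        ma, na = main_mats[a]
        mb, nb = main_mats[b]
        cols, cnames = [], []
        for i, nia in enumerate(na):
            for j, njb in enumerate(nb):
                cols.append((ma[:, i] * mb[:, j])[:, None])
                cnames.append(f"{nia}:{njb}")
        mat = np.hstack(cols)
        start = sum(bk.shape[1] for bk in blocks)
        term_columns[term] = list(range(start, start + mat.shape[1]))
        blocks.append(mat)
        names.extend(cnames)

    X = np.hstack(blocks)
    if check_rank:
        _check_rank(X, names)

    y = y_levels = None
    if response:
        s = df[spec.response]
        if _is_categorical(s):
            y_levels = sorted(pd.unique(s.dropna()).tolist())
            y = pd.Categorical(s, categories=y_levels).codes.astype(int)
        else:
            y = s.to_numpy(float)

    groups = group_levels = None
    if spec.group is not None:
        cat = pd.Categorical(df[spec.group].astype(str))
        groups = cat.codes.astype(np.int64)
        group_levels = list(cat.categories)

    return Design(X, names, term_columns, y, y_levels, groups, group_levels, factor_levels)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise AliasingError(f"rank-deficient design; aliased columns: {', '.join(bad)}")
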