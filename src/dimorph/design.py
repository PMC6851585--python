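"""Fixed-effect design matrices with per-term bookkeeping.

Treatment (reference-level) coding throughout. Keeping explicit term slices
makes joint Wald tests per model term and marginal prediction rows trivial,
which formula back-ends hide; categorical levels are remembered so prediction
rows can average non-focal factors on the link scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignInfo", "build_design", "prediction_row"]


@dataclass
class DesignInfo:
    """Column layout of a fixed-effect design matrix.

    Attributes
    ----------
    terms : list of tuple of str
        Model terms in order; ``()`` is the intercept, ``("sex",)`` a main
        effect, ``("sex", "stage")`` an interaction.
    term_slices : dict
        Term -> ``slice`` into the columns.
    levels : dict
        Categorical variable -> ordered list of levels (first = reference).
    numeric : list of str
        Names of numeric covariates appearing in the design.
    column_names : list of str
    """

    terms: list = field(default_factory=list)
    term_slices: dict = field(default_factory=dict)
    levels: dict = field(default_factory=dict)
    numeric: list = field(default_factory=list)
    column_names: list = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)


def _encode_factor(values: pd.Series, levels: list) -> tuple[np.ndarray, list]:
    """Dummy-code a factor against its first level; columns for levels[1:]."""
    arr = np.zeros((len(values), len(levels) - 1))
    codes = pd.Categorical(values, categories=levels).codes
    if (codes < 0).any():
        bad = sorted(set(values[codes < 0]))
        raise ValueError(f"unknown factor levels {bad}; known: {levels}")
    for j in range(1, len(levels)):
        arr[:, j - 1] = codes == j
    names = [str(lv) for lv in levels[1:]]
    return arr, names


def build_design(
    data: pd.DataFrame,
    terms: list,
    categorical: dict | None = None,
) -> tuple[np.ndarray, DesignInfo]:
    """Build a fixed-effect design matrix.

    Parameters
    ----------
    data : DataFrame with one row per observation.
    terms : list
        Each entry a variable name (main effect) or tuple of names
        (interaction). An intercept is always included first.
    categorical : dict, optional
        Variable -> explicit level order. Variables of object/categorical
        dtype are treated as factors automatically (sorted levels, first is
        the reference); numeric columns enter linearly.
    """
    categorical = dict(categorical or {})
    norm_terms = [()]
    for t in terms:
        norm_terms.append((t,) if isinstance(t, str) else tuple(t))

    info = DesignInfo()
    blocks = [np.ones((len(data), 1))]
    info.terms.append(())
    info.term_slices[()] = slice(0, 1)
    info.column_names.append("Intercept")
    col = 1

    def var_matrix(name: str) -> tuple[np.ndarray, list]:
        s = data[name]
        is_factor = name in categorical or not pd.api.types.is_numeric_dtype(s)
        if is_factor:
            levels = categorical.get(name) or sorted(pd.unique(s))
            if name not in info.levels:
                info.levels[name] = list(levels)
            arr, lvl_names = _encode_factor(s, info.levels[name])
            return arr, [f"{name}[{n}]" for n in lvl_names]
        if name not in info.numeric:
            info.numeric.append(name)
        return np.asarray(s, dtype=float)[:, None], [name]

    for term in norm_terms[1:]:
        mats, name_sets = zip(*(var_matrix(v) for v in term))
        block = mats[0]
        names = list(name_sets[0])
        for m, ns in zip(mats[1:], name_sets[1:]):
            block = np.einsum("ij,ik->ijk", block, m).reshape(len(data), -1)
            names = [f"{a}:{b}" for a in names for b in ns]
        if block.shape[1] == 0:
            raise ValueError(f"term {term} produced no columns")
        blocks.append(block)
        info.terms.append(term)
        info.term_slices[term] = slice(col, col + block.shape[1])
        info.column_names.extend(names)
        col += block.shape[1]

    return np.hstack(blocks), info


def prediction_row(info: DesignInfo, at: dict, numeric_at: dict | None = None) -> np.ndarray:
    """Design row for a prediction at ``at``, marginalising other variables.

    Factors named in ``at`` are set to the given level. Factors not named are
    averaged uniformly over their levels *on the link scale* (each level gets
    weight 1/L, so each non-reference dummy contributes 1/L). Numeric
    covariates take the value in ``numeric_at`` (default 0.0, i.e. centred
    covariates are predicted at their mean).
    """
    numeric_at = dict(numeric_at or {})

    def var_row(name: str) -> np.ndarray:
        if name in info.levels:
            levels = info.levels[name]
            row = np.zeros(len(levels) - 1)
            if name in at:
                lev = at[name]
                if lev not in levels:
                    raise ValueError(f"unknown level {lev!r} for {name}")
                idx = levels.index(lev)
                if idx > 0:
                    row[idx - 1] = 1.0
            else:
                row[:] = 1.0 / len(levels)
            return row
        return np.array([float(numeric_at.get(name, 0.0))])

    out = np.zeros(info.n_columns)
    for term in info.terms:
        if term == ():
            out[0] = 1.0
            continue
        row = var_row(term[0])
        for v in term[1:]:
            row = np.outer(row, var_row(v)).ravel()
        out[info.term_slices[term]] = row
    return out
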