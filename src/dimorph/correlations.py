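"""Intersex and intertrait correlation structure on population means.

All correlations are Spearman rank correlations across populations of
model-predicted trait means, computed per life-cycle stage: intertrait
correlations within each sex, intersex correlations of the same trait
between the sexes, partial correlations controlling for the remaining
traits (rank-transformed; residual-based and precision-matrix routes agree
and both are implemented), and a population-subsample bootstrap comparing
sex-specific correlations via non-overlap of their percentile intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationEntry",
    "BootstrapComparison",
    "population_trait_means",
    "spearman_matrix",
    "partial_spearman",
    "bootstrap_sex_difference",
    "dimorphism_vs_intersex",
]


@dataclass
class CorrelationEntry:
    """One correlation: a trait pair in a context (female/male/intersex)."""

    trait_a: str
    trait_b: str
    context: str  # "female" | "male" | "intersex"
    r_s: float
    p_value: float
    partial: bool = False
    controls: list = field(default_factory=list)
    stage: str = ""

    def as_dict(self) -> dict:
        return {
            "trait_a": self.trait_a, "trait_b": self.trait_b,
            "context": self.context, "stage": self.stage, "r_s": self.r_s,
            "p": self.p_value, "partial": self.partial,
            "controls": ";".join(self.controls),
        }


@dataclass
class BootstrapComparison:
    """Sex-specific bootstrap CIs for one trait-pair correlation."""

    trait_a: str
    trait_b: str
    ci_F: tuple
    ci_M: tuple
    n_boot: int
    subsample: int
    seed: int
    significant: bool
    r_F: float = np.nan
    r_M: float = np.nan
    diff_p: float = np.nan  # extension: percentile p for r_F - r_M != 0


# ---------------------------------------------------------------------------
def population_trait_means(models: dict, stage: str) -> pd.DataFrame:
    """Assemble the populations x (trait, sex) predicted-mean matrix.

    ``models`` maps ``(trait, stage, "population")`` to fitted trait models
    (see :mod:`dimorph.traitmodels`); traits missing one sex are dropped
    with a warning. Columns are a MultiIndex (trait, sex).
    """
    blocks = {}
    for (trait, st, scope), model in models.items():
        if st != stage or scope != "population":
            continue
        rows = {}
        ok = True
        for pop in model.groups():
            try:
                pm_F, pm_M, _ = model.sex_means(pop)
            except KeyError:
                warnings.warn(f"{trait}/{stage}: sex missing for {pop}; "
                              "trait dropped")
                ok = False
                break
            rows[pop] = {"F": pm_F.estimate, "M": pm_M.estimate}
        if ok and rows:
            df = pd.DataFrame(rows).T
            blocks[trait] = df
    if not blocks:
        raise ValueError(f"no population-scope models for stage {stage!r}")
    mat = pd.concat(blocks, axis=1)  # columns (trait, sex)
    mat.index.name = "pop_id"
    return mat


def _spearman(x, y):
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def spearman_matrix(matrix: pd.DataFrame, stage: str = "") -> list:
    """Per-sex intertrait and per-trait intersex Spearman correlations.

    ``matrix`` is populations x (trait, sex). Constant traits yield
    flagged NaN entries.
    """
    traits = sorted({t for t, _ in matrix.columns})
    if len(matrix) < 4:
        raise ValueError(f"need >=4 populations, got {len(matrix)}")
    out = []

    def entry(a, b, context, xa, xb):
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            warnings.warn(f"constant trait in {context} {a}~{b}; undefined")
            r, p = np.nan, np.nan
        else:
            r, p = _spearman(xa, xb)
        out.append(CorrelationEntry(a, b, context, r, p, stage=stage))

    for i, a in enumerate(traits):
        entry(a, a, "intersex", matrix[(a, "F")].to_numpy(),
              matrix[(a, "M")].to_numpy())
        for b in traits[i + 1:]:
            for context, sex in (("female", "F"), ("male", "M")):
                entry(a, b, context, matrix[(a, sex)].to_numpy(),
                      matrix[(b, sex)].to_numpy())
    return out


# ---------------------------------------------------------------------------
def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def partial_spearman(
    matrix: pd.DataFrame,
    pair: tuple,
    controls: list,
    context: str = "female",
    stage: str = "",
    method: str = "residual",
) -> CorrelationEntry:
    """Partial Spearman correlation of ``pair`` given ``controls``.

    All variables are rank-transformed first. ``method`` selects the
    residual-based route (Pearson correlation of the rank residuals after
    regressing out the controls) or the precision-matrix route
    (-P_xy / sqrt(P_xx P_yy) from the inverse rank-correlation matrix);
    the two agree to numerical precision. For the intersex context the
    controls are the cross-sex averages of the remaining traits and the
    pair is the same trait in the two sexes.
    """
    a, b = pair
    if context == "intersex":
        x = matrix[(a, "F")].to_numpy(dtype=float)
        y = matrix[(b, "M")].to_numpy(dtype=float)
        C = np.column_stack([
            matrix[[(t, "F"), (t, "M")]].mean(axis=1).to_numpy(dtype=float)
            for t in controls
        ]) if controls else np.empty((len(matrix), 0))
    else:
        sex = "F" if context == "female" else "M"
        x = matrix[(a, sex)].to_numpy(dtype=float)
        y = matrix[(b, sex)].to_numpy(dtype=float)
        C = np.column_stack([
            matrix[(t, sex)].to_numpy(dtype=float) for t in controls
        ]) if controls else np.empty((len(matrix), 0))

    n, k = len(x), C.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > controls + 3 populations (n={n}, k={k})")
    rx, ry = _rank(x), _rank(y)
    rC = _rank(C) if k else C
    if k == 0:
        r = float(np.corrcoef(rx, ry)[0, 1])
    elif method == "residual":
        Z = np.column_stack([np.ones(n), rC])
        coef_x, *_ = np.linalg.lstsq(Z, rx, rcond=None)
        coef_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
        ex, ey = rx - Z @ coef_x, ry - Z @ coef_y
        denom = np.linalg.norm(ex) * np.linalg.norm(ey)
        if denom == 0:
            raise np.linalg.LinAlgError("degenerate residuals")
        r = float(ex @ ey / denom)
    elif method == "precision":
        R = np.corrcoef(np.column_stack([rx, ry, rC]), rowvar=False)
        try:
            P = np.linalg.inv(R)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"singular control set for {pair}: {e}") from e
        r = float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(np.clip(r, -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), dof))
    return CorrelationEntry(a, b, context, r, p, partial=bool(k),
                            controls=list(controls), stage=stage)


def partial_matrix(matrix: pd.DataFrame, stage: str = "") -> list:
    """All partial correlations, each controlling for the remaining traits."""
    traits = sorted({t for t, _ in matrix.columns})
    out = []
    for i, a in enumerate(traits):
        rest = [t for t in traits if t != a]
        out.append(partial_spearman(matrix, (a, a), rest, "intersex", stage))
        for b in traits[i + 1:]:
            rest = [t for t in traits if t not in (a, b)]
            for context in ("female", "male"):
                out.append(partial_spearman(matrix, (a, b), rest, context, stage))
    return out


# ---------------------------------------------------------------------------
def bootstrap_sex_difference(
    matrix: pd.DataFrame,
    pair: tuple,
    n_boot: int = 1000,
    subsample: int = 25,
    seed: int = 0,
    replace: bool = True,
) -> BootstrapComparison:
    """Population-subsample bootstrap comparing a trait-pair correlation
    between the sexes.

    Each replicate draws ``subsample`` populations (with replacement by
    default; ``replace=False`` gives delete-d subsampling) and recomputes
    each sex's Spearman correlation for the pair from the same subsample;
    95% percentile intervals are formed per sex and the difference is
    called significant when the two intervals do not overlap — a
    deliberately conservative rule. A percentile p-value for r_F - r_M
    (labelled extension) is reported alongside.

    Delete-d subsampling at d much smaller than the number of populations
    understates sampling variability (consecutive subsamples share most of
    their populations), which makes the non-overlap rule anti-conservative;
    the resampling default is therefore the with-replacement draw.
    """
    a, b = pair
    n_pop = len(matrix)
    if subsample > n_pop:
        raise ValueError(f"subsample {subsample} exceeds populations {n_pop}")
    cols = {s: (matrix[(a, s)].to_numpy(dtype=float),
                matrix[(b, s)].to_numpy(dtype=float)) for s in "FM"}
    rng = np.random.default_rng(seed)
    if replace:
        idx = rng.integers(0, n_pop, size=(n_boot, subsample))
    else:
        idx = np.argsort(rng.random((n_boot, n_pop)), axis=1)[:, :subsample]

    def boot_rs(x, y):
        xs, ys = x[idx], y[idx]  # (n_boot, subsample)
        rxs = stats.rankdata(xs, axis=1)
        rys = stats.rankdata(ys, axis=1)
        rxs = rxs - rxs.mean(axis=1, keepdims=True)
        rys = rys - rys.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxs**2).sum(axis=1) * (rys**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (rxs * rys).sum(axis=1) / denom, np.nan)

    r_F = boot_rs(*cols["F"])
    r_M = boot_rs(*cols["M"])
    ci_F = tuple(np.nanpercentile(r_F, [2.5, 97.5]))
    ci_M = tuple(np.nanpercentile(r_M, [2.5, 97.5]))
    significant = bool(ci_F[0] > ci_M[1] or ci_M[0] > ci_F[1])
    diff = r_F - r_M
    frac = float(np.nanmean(diff > 0))
    diff_p = float(min(1.0, 2 * min(frac, 1 - frac)))
    return BootstrapComparison(
        trait_a=a, trait_b=b,
        ci_F=(float(ci_F[0]), float(ci_F[1])),
        ci_M=(float(ci_M[0]), float(ci_M[1])),
        n_boot=n_boot, subsample=subsample, seed=seed,
        significant=significant,
        r_F=float(_spearman(*cols["F"])[0]),
        r_M=float(_spearman(*cols["M"])[0]),
        diff_p=diff_p,
    )


# ---------------------------------------------------------------------------
def dimorphism_vs_intersex(estimates: list, intersex: list) -> CorrelationEntry:
    """Spearman correlation between |%SD| and the intersex correlation
    across matched trait/stage pairs."""
    sd_map = {(e.trait, e.stage): abs(e.pct_sd) for e in estimates}
    pairs = [
        (sd_map[(c.trait_a, c.stage)], c.r_s)
        for c in intersex
        if c.context == "intersex" and (c.trait_a, c.stage) in sd_map
        and np.isfinite(c.r_s)
    ]
    if len(pairs) < 4:
        raise ValueError(f"need >=4 matched trait/stage pairs, got {len(pairs)}")
    x, y = map(np.asarray, zip(*pairs))
    r, p = _spearman(x, y)
    return CorrelationEntry("abs_pct_sd", "intersex_rs", "association", r, p)


def correlations_frame(entries: list) -> pd.DataFrame:
    """Long heatmap-ready export (female above/male below diagonal,
    intersex on the diagonal in the wide rendering)."""
    return pd.DataFrame([e.as_dict() for e in entries])
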