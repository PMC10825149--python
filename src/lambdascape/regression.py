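"""Competitor-dependent epistasis regression.

Fitness measurements from the mixed-host competitions are modelled as a
sparse linear function of genotype and competitor context.  The design
matrix has exactly 148 binary features:

* 1 intercept;
* 8 mutation indicators ("G"): sites 2 and 3 share one indicator because
  they introduce the same amino-acid change (alone or combined);
* 3 competitor indicators ("C"): generalist EvoC, L-specialist,
  O-specialist (all three kept; the L1 penalty resolves the collinearity
  with the intercept);
* 28 pairwise epistasis terms ("GxG", lexicographic site pairs);
* 24 competitor-by-mutation terms ("CxG", competitor-major order);
* 84 competitor-by-epistasis terms ("CxGxG", competitor-major then
  lexicographic).

The LASSO path is computed on internally standardized features (the
penalty is scale-sensitive) with an unpenalized intercept, the
regularization strength is selected by AIC, BIC or grouped
cross-validation, and coefficients are reported on the original 0/1
feature scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, LassoLarsIC
from sklearn.model_selection import GroupKFold, KFold

from .core import N_SITES, ValidationError, genotype_index

COMPETITORS = ("EvoC", "L_specialist", "O_specialist")
_C_NAMES = ("C_EvoC", "C_L", "C_O")

# merged-site groups in gene order: sites 2 and 3 act as one term
SITE_GROUPS: tuple[tuple[int, ...], ...] = ((1,), (2, 3), (4,), (5,), (6,), (7,), (8,), (9,))
_G_NAMES = tuple(
    "G" + "_".join(str(s) for s in group) for group in SITE_GROUPS
)  # G1, G2_3, G4..G9
_PAIRS = tuple(combinations(range(len(SITE_GROUPS)), 2))  # 28 pairs

N_FEATURES = 1 + 8 + 3 + 28 + 24 + 84  # = 148


def feature_names() -> list[str]:
    """Fixed column order of the 148-feature design matrix."""
    names = ["intercept"]
    names += list(_G_NAMES)
    names += list(_C_NAMES)
    names += [f"{_G_NAMES[i]}x{_G_NAMES[j]}" for i, j in _PAIRS]
    names += [f"{c}:{g}" for c in _C_NAMES for g in _G_NAMES]
    names += [f"{c}:{_G_NAMES[i]}x{_G_NAMES[j]}" for c in _C_NAMES for i, j in _PAIRS]
    assert len(names) == N_FEATURES
    return names


def feature_block(name: str) -> str:
    """Block label (intercept/G/C/GxG/CxG/CxGxG) for a feature name."""
    if name == "intercept":
        return "intercept"
    if name.startswith("C_") and ":" not in name:
        return "C"
    if ":" in name:
        return "CxGxG" if "x" in name.split(":")[1] else "CxG"
    return "GxG" if "x" in name else "G"


def merged_site_indicator(genotype: str) -> np.ndarray:
    """Length-8 G-term vector; the merged term fires on site 2 or 3 (or both)."""
    bits = 1 << np.arange(N_SITES)
    g = genotype_index(genotype)
    return np.array(
        [1 if any(g & bits[s - 1] for s in group) else 0 for group in SITE_GROUPS],
        dtype=float,
    )


@dataclass
class DesignMatrix:
    """Feature matrix, response, and optional replicate grouping."""

    X: np.ndarray  # (n, 148) in {0, 1}
    y: np.ndarray
    feature_names: list[str]
    groups: np.ndarray | None = None
    n_dropped: int = 0


def build_design_matrix(
    observations: pd.DataFrame | Iterable[tuple],
) -> DesignMatrix:
    """Assemble the 148-column design matrix from fitness observations.

    ``observations`` is a DataFrame (or iterable of tuples) with columns
    ``genotype``, ``competitor``, ``S`` and optionally ``replicate`` (used
    to group cross-validation folds).  Rows with missing S are dropped and
    counted.  Only mixed-host measurements should be supplied; the matrix
    itself is agnostic.
    """
    if not isinstance(observations, pd.DataFrame):
        rows = list(observations)
        cols = ["genotype", "competitor", "S", "replicate"][: len(rows[0])] if rows else [
            "genotype",
            "competitor",
            "S",
        ]
        observations = pd.DataFrame(rows, columns=cols)
    unknown = set(observations["competitor"]) - set(COMPETITORS)
    if unknown:
        raise ValidationError(f"unknown competitor labels: {sorted(unknown)}")
    finite = np.isfinite(observations["S"].to_numpy(dtype=float))
    n_dropped = int((~finite).sum())
    observations = observations[finite]

    g_rows = np.vstack([merged_site_indicator(k) for k in observations["genotype"]])
    comp_idx = np.array([COMPETITORS.index(c) for c in observations["competitor"]])
    c_rows = np.eye(3)[comp_idx]
    gxg = np.stack([g_rows[:, i] * g_rows[:, j] for i, j in _PAIRS], axis=1)
    cxg = np.concatenate([c_rows[:, [c]] * g_rows for c in range(3)], axis=1)
    cxgxg = np.concatenate([c_rows[:, [c]] * gxg for c in range(3)], axis=1)
    X = np.concatenate(
        [np.ones((len(g_rows), 1)), g_rows, c_rows, gxg, cxg, cxgxg], axis=1
    )
    assert X.shape[1] == N_FEATURES

    groups = None
    if "replicate" in observations.columns:
        groups = pd.factorize(observations["replicate"])[0]
    return DesignMatrix(
        X=X,
        y=observations["S"].to_numpy(dtype=float),
        feature_names=feature_names(),
        groups=groups,
        n_dropped=n_dropped,
    )


@dataclass
class FittedModel:
    """Sparse linear fit; coefficients on the original 0/1 feature scale."""

    coef: pd.Series  # indexed by feature name, intercept included
    alpha: float
    criterion: str
    n_nonzero: int  # non-intercept features retained
    r2: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef.to_numpy()


def fit_sparse_model(
    design: DesignMatrix,
    criterion: str = "bic",
    n_folds: int = 5,
    seed: int = 0,
) -> FittedModel:
    """L1-penalized least squares with the penalty tuned by AIC/BIC/CV."""
    criterion = criterion.lower()
    if criterion not in {"aic", "bic", "cv"}:
        raise ValidationError("criterion must be one of aic, bic, cv")
    y = design.y
    if np.ptp(y) == 0:
        raise ValidationError("response is constant; nothing to fit")
    X = design.X[:, 1:]  # intercept handled unpenalized by the estimator
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    safe = np.where(scale > 0, scale, 1.0)
    Xs = (X - mean) / safe

    if criterion == "cv":
        if design.groups is not None and len(np.unique(design.groups)) >= n_folds:
            splits = list(GroupKFold(n_splits=n_folds).split(Xs, y, design.groups))
        else:
            splits = list(
                KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(Xs)
            )
        model = LassoCV(cv=splits, fit_intercept=True, random_state=seed).fit(Xs, y)
    else:
        model = LassoLarsIC(criterion=criterion, fit_intercept=True).fit(Xs, y)

    beta_std = np.where(scale > 0, model.coef_, 0.0)
    beta = beta_std / safe
    intercept = float(model.intercept_ - (beta_std * mean / safe).sum())
    coef = pd.Series(
        np.concatenate([[intercept], beta]), index=design.feature_names, name="coefficient"
    )
    fitted = X @ beta + (coef.iloc[0] )
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return FittedModel(
        coef=coef,
        alpha=float(model.alpha_),
        criterion=criterion,
        n_nonzero=int(np.count_nonzero(beta)),
        r2=1.0 - ss_res / ss_tot,
    )


def write_coefficients(model: FittedModel, path: str | Path) -> None:
    """Coefficient TSV (feature, block, value) for heatmap rendering."""
    frame = pd.DataFrame(
        {
            "feature": model.coef.index,
            "block": [feature_block(n) for n in model.coef.index],
            "coefficient": model.coef.to_numpy(),
        }
    )
    with open(path, "w") as handle:
        handle.write(f"#criterion={model.criterion}\n#alpha={model.alpha:.12g}\n")
        frame.to_csv(handle, sep="\t", index=False, float_format="%.12g")
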