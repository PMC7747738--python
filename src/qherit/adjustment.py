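"""Age and sex adjustment of phenotypes.

Phenotypes are adjusted by ordinary least squares on the fixed design
(intercept, female indicator, age, age^2, female*age, female*age^2) and
re-expressed as residual + grand mean, so adjusted values stay in the
phenotype's original units and keep the raw mean.  Rank-deficient designs
(e.g. a single-sex cohort) drop the offending columns deterministically,
left to right, and record what was dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import Cohort, PhenotypeVector

DESIGN_COLUMNS = ("intercept", "female", "age", "age2", "female_age", "female_age2")

#: relative residual norm below which a design column is declared collinear
_COLLINEAR_TOL = 1e-8


@dataclass
class AdjustmentModel:
    """Fitted age/sex adjustment, kept for audit.

    ``coefficients`` maps retained design-column names to their least-squares
    estimates (phenotype units per covariate unit); ``dropped`` lists columns
    removed for collinearity; ``grand_mean`` is the mean the residuals were
    re-centered on; ``n`` is the number of rows the model was fitted on.
    """

    coefficients: dict[str, float]
    dropped: list[str]
    grand_mean: float
    n: int


def _design_matrix(cohort: Cohort) -> np.ndarray:
    female = (cohort.data["sex"].to_numpy() == "F").astype(float)
    age = cohort.data["age"].to_numpy(dtype=float)
    return np.column_stack([
        np.ones(len(age)), female, age, age ** 2, female * age, female * age ** 2,
    ])


def _drop_collinear(X: np.ndarray) -> tuple[np.ndarray, list[int], list[int]]:
    """Keep design columns left to right, dropping any in the span of earlier ones."""
    kept: list[int] = []
    dropped: list[int] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if kept:
            coef, *_ = np.linalg.lstsq(X[:, kept], col, rcond=None)
            resid = col - X[:, kept] @ coef
            scale = np.linalg.norm(col)
            if np.linalg.norm(resid) <= _COLLINEAR_TOL * max(scale, 1.0):
                dropped.append(j)
                continue
        kept.append(j)
    return X[:, kept], kept, dropped


def adjust_phenotype(cohort: Cohort, phenotype: PhenotypeVector) -> PhenotypeVector:
    """Return the age/sex-adjusted phenotype (residual + grand mean).

    The model is fitted on all rows with a non-missing phenotype value;
    missing values stay missing.  The adjusted vector's mean equals the raw
    mean to numerical tolerance, and the fitted :class:`AdjustmentModel` is
    attached as ``.model``.
    """
    if len(phenotype) != cohort.n:
        raise ValueError("phenotype vector is not aligned to the cohort")
    y = phenotype.values
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError(f"all values of {phenotype.name!r} are missing")
    X_full = _design_matrix(cohort)
    X, kept, dropped_idx = _drop_collinear(X_full[obs])
    coef, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
    grand_mean = float(np.mean(y[obs]))
    adjusted = np.full_like(y, np.nan)
    adjusted[obs] = y[obs] - X @ coef + grand_mean
    model = AdjustmentModel(
        coefficients={DESIGN_COLUMNS[k]: float(c) for k, c in zip(kept, coef)},
        dropped=[DESIGN_COLUMNS[j] for j in dropped_idx],
        grand_mean=grand_mean,
        n=int(obs.sum()),
    )
    return replace(phenotype, values=adjusted, name=f"{phenotype.name}_adj", model=model)


def adjust_or_passthrough(
    cohort: Cohort, phenotype: PhenotypeVector, mode: str = "adjusted"
) -> tuple[PhenotypeVector, PhenotypeVector]:
    """Return (dependent-role, independent-role) phenotype vectors.

    ``mode="adjusted"`` adjusts both roles.  ``mode="unadjusted"`` keeps the
    raw values for the dependent role only, while the independent role still
    uses adjusted values — i.e. an unadjusted sib value is regressed on the
    adjusted co-sib values.
    """
    if mode not in ("adjusted", "unadjusted"):
        raise ValueError(f"mode must be 'adjusted' or 'unadjusted', got {mode!r}")
    adjusted = adjust_phenotype(cohort, phenotype)
    if mode == "adjusted":
        return adjusted, adjusted
    return phenotype, adjusted
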