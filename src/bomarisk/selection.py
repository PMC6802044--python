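"""A-priori candidate models, AICc ranking with Akaike weights, and the
multicollinearity screen.

The candidate set holds the five hypotheses about what drives hyena raids on
livestock enclosures: management (boma fortification), seasonality, landscape
(distances to river/road/protected area, agriculture, NDVI), and their
combinations. Each candidate keeps the crossed village x year random
intercepts; the parameter count ``k`` is the number of fixed effects
(including the intercept) plus the two variance components.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .glmm import GlmmFit, ModelSpec

SPATIAL_TERMS = ("dist_river", "dist_road", "dist_pa", "prop_agric", "ndvi")

_SPATIAL_LABEL = ("Distance to river + Distance to road + Distance to PA "
                  "+ Proportion agriculture + NDVI")


def model_label(spec: ModelSpec) -> str:
    """Human-readable formula text for a candidate spec."""
    named = [t for t in spec.fixed_terms if t != "intercept"]
    parts: list[str] = []
    if all(t in named for t in SPATIAL_TERMS):
        parts.append(_SPATIAL_LABEL)
        named = [t for t in named if t not in SPATIAL_TERMS]
        order = ("season", "boma_type")  # "... + Season + Boma type"
    else:
        order = ("boma_type", "season")  # "Boma type + Season"
    mapping = {"season": "Season", "boma_type": "Boma type"}
    parts += [mapping[t] for t in order if t in named]
    parts += [t for t in named if t not in mapping]
    return " + ".join(parts) if parts else "Intercept only"


def candidate_set(response: str) -> list[ModelSpec]:
    """The five a-priori candidate structures for a response, each with both
    random intercepts: management+season, landscape+season,
    landscape+season+management, landscape only, management only."""
    base = ("intercept",)
    return [
        ModelSpec(response, base + ("boma_type", "season")),
        ModelSpec(response, base + SPATIAL_TERMS + ("season",)),
        ModelSpec(response, base + SPATIAL_TERMS + ("season", "boma_type")),
        ModelSpec(response, base + SPATIAL_TERMS),
        ModelSpec(response, base + ("boma_type",)),
    ]


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: ``-2 l + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Normalized relative likelihoods ``exp(-delta/2)`` of a candidate set."""
    a = np.asarray(aicc_values, float)
    delta = a - a.min()
    rel = np.exp(-0.5 * delta)
    return rel / rel.sum()


@dataclasses.dataclass(frozen=True)
class SelectionRow:
    label: str
    k: int
    aicc: float
    delta: float
    weight: float


def selection_from_aicc(labels: Sequence[str], ks: Sequence[int],
                        aicc_values: Sequence[float]) -> list[SelectionRow]:
    """Rank precomputed AICc values: sort ascending, ties broken by smaller
    ``k`` then label order."""
    w = akaike_weights(aicc_values)
    best = min(aicc_values)
    rows = [SelectionRow(l, int(k), float(a), float(a - best), float(wi))
            for l, k, a, wi in zip(labels, ks, aicc_values, w)]
    return sorted(rows, key=lambda r: (r.aicc, r.k, r.label))


def selection_table(fits: Sequence[GlmmFit]) -> list[SelectionRow]:
    """AICc ranking of fitted candidates (all on the same observation set)."""
    if not fits:
        raise ValueError("need at least one fit")
    ns = {f.n_obs for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits are not comparable: differing n_obs {sorted(ns)}")
    n = ns.pop()
    labels = [model_label(f.spec) for f in fits]
    ks = [f.k for f in fits]
    values = [aicc(f.loglik, f.k, n) for f in fits]
    return selection_from_aicc(labels, ks, values)


def selection_frame(rows: Sequence[SelectionRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "Variables": r.label, "df": r.k, "AICc": r.aicc,
        "dAICc": r.delta, "wi": r.weight,
    } for r in rows])


# ---------------------------------------------------------------------------
# Collinearity screen
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    vif: pd.Series
    passed: bool
    flagged_pairs: list[tuple[str, str, float]]


def collinearity_screen(covariates: pd.DataFrame,
                        vif_threshold: float = 2.5,
                        corr_warn: float = 0.7) -> CollinearityReport:
    """Pearson correlations and variance inflation factors of a covariate table.

    ``VIF_j = 1 / (1 - R_j^2)`` from regressing covariate ``j`` on the others
    (with intercept). The screen passes when every VIF is below the threshold;
    correlations above ``corr_warn`` in magnitude are flagged as warnings only.
    A constant covariate has undefined (infinite) VIF and fails the screen.
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least two covariates")
    if len(covariates) <= covariates.shape[1]:
        raise ValueError("need more rows than covariates")
    corr = covariates.corr()
    cols = list(covariates.columns)
    vifs = {}
    for j, col in enumerate(cols):
        yv = covariates[col].to_numpy(float)
        sst = float(((yv - yv.mean()) ** 2).sum())
        if sst == 0.0:
            vifs[col] = np.inf
            continue
        others = covariates.drop(columns=[col]).to_numpy(float)
        A = np.column_stack([np.ones(len(yv)), others])
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        ssr = float(((yv - A @ coef) ** 2).sum())
        r2 = 1.0 - ssr / sst
        vifs[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    vif = pd.Series(vifs, name="vif")
    flagged = [(a, b, float(corr.loc[a, b]))
               for i, a in enumerate(cols) for b in cols[i + 1:]
               if abs(corr.loc[a, b]) > corr_warn]
    passed = bool(np.all(np.array(list(vifs.values())) < vif_threshold))
    return CollinearityReport(corr, vif, passed, flagged)
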