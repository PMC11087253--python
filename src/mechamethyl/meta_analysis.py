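"""DerSimonian-Laird random-effects meta-analysis of the two per-model scans.

The combiner is the standard method-of-moments estimator: fixed-effect
weights give Cochran's Q, the between-study variance is
``tau_sq = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))``, and the
random-effects estimate re-weights by ``1 / (se_i^2 + tau_sq)``.  The
combined z is referred to the standard normal.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, EmptyInputError
from .differential_methylation import adjust_bh

logger = logging.getLogger(__name__)


class MetaResult(NamedTuple):
    b_meta: float
    se_meta: float
    tau_sq: float
    Q: float
    z: float
    p: float


def _combine_arrays(b: np.ndarray, se: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized DL combination; ``b`` and ``se`` are (k, n_probes)."""
    k = b.shape[0]
    w = 1.0 / se**2
    sw = w.sum(axis=0)
    b_fe = (w * b).sum(axis=0) / sw
    q = (w * (b - b_fe) ** 2).sum(axis=0)
    denom = sw - (w**2).sum(axis=0) / sw
    tau_sq = np.maximum(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (se**2 + tau_sq)
    sws = w_star.sum(axis=0)
    b_meta = (w_star * b).sum(axis=0) / sws
    se_meta = 1.0 / np.sqrt(sws)
    z = b_meta / se_meta
    p = 2 * stats.norm.sf(np.abs(z))
    return {
        "b_meta": b_meta, "se_meta": se_meta, "tau_sq": tau_sq,
        "Q": q, "z": z, "p": p,
    }


def random_effects_combine(effects: Sequence[tuple[float, float]]) -> MetaResult:
    """Combine k >= 2 (estimate, standard error) pairs into one random-effects
    estimate with DerSimonian-Laird between-study variance."""
    if len(effects) < 2:
        raise DomainError("random_effects_combine needs k >= 2 studies")
    b = np.array([[e[0]] for e in effects], dtype=float)
    se = np.array([[e[1]] for e in effects], dtype=float)
    if np.any(se <= 0):
        raise DomainError("all standard errors must be positive")
    out = _combine_arrays(b, se)
    return MetaResult(*(float(out[k][0]) for k in ("b_meta", "se_meta", "tau_sq", "Q", "z", "p")))


def meta_ewas(
    dm_spherical: pd.DataFrame,
    dm_cylindrical: pd.DataFrame,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Probe-wise random-effects combination of two per-model DM tables.

    Inputs are tables indexed by probe id with columns ``b_g`` and ``se``
    (as produced by :func:`mechamethyl.differential_methylation.dm_analysis`).
    Probes present in only one table are excluded (a random-effects estimate
    needs both models) and logged.  BH is applied across all combined probes
    and ``dm_flag`` marks ``q < fdr_threshold``.
    """
    shared = dm_spherical.index.intersection(dm_cylindrical.index)
    if len(shared) == 0:
        raise EmptyInputError("no probes shared between the two models")
    only = (len(dm_spherical) - len(shared)) + (len(dm_cylindrical) - len(shared))
    if only:
        logger.info("meta_ewas: %d probes present in a single model were excluded", only)
    b = np.stack(
        [dm_spherical.loc[shared, "b_g"].to_numpy(), dm_cylindrical.loc[shared, "b_g"].to_numpy()]
    )
    se = np.stack(
        [dm_spherical.loc[shared, "se"].to_numpy(), dm_cylindrical.loc[shared, "se"].to_numpy()]
    )
    if np.any(se <= 0):
        raise DomainError("per-model standard errors must be positive")
    out = _combine_arrays(b, se)
    meta = pd.DataFrame(out, index=shared)
    meta["q"] = adjust_bh(meta["p"].to_numpy())
    meta["dm_flag"] = meta["q"] < fdr_threshold
    meta.index.name = "probe_id"
    return meta
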