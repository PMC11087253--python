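"""Clinical severity association for selected CpGs and targeted RT-qPCR analysis.

The clinical model regresses methylation at a CpG on the radiographic
Kellgren-Lawrence grade adjusted for BMI and age; the qPCR side implements
the standard delta-Ct normalization against housekeeping genes, 2^-ddCt fold
changes, and a Gaussian linear model for the loading effect on -dCt.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, InvalidDesignError


def correlate_with_severity(
    clinical: pd.DataFrame,
    cpg: str,
    scale: str = "beta",
    direction: str = "meth_on_kl",
) -> tuple[float, float, float]:
    """KL coefficient for one CpG, adjusted for BMI and age.

    Default fits OLS of methylation on (KL, BMI, age) with intercept and
    returns (slope, se, p) for the KL term.  ``scale='logit'`` regresses the
    natural-logit of beta instead (the scale on which simulated slopes are
    planted); ``direction='kl_on_meth'`` swaps response and predictor.
    """
    if len(clinical) < 10:
        raise InvalidDesignError("need >= 10 patients")
    y = clinical[cpg].to_numpy(dtype=float)
    if scale == "logit":
        y = np.log(np.clip(y, 1e-9, 1 - 1e-9) / (1 - np.clip(y, 1e-9, 1 - 1e-9)))
    elif scale != "beta":
        raise DomainError("scale must be 'beta' or 'logit'")
    kl = clinical["kl_score"].to_numpy(dtype=float)
    covs = clinical[["bmi", "age"]].to_numpy(dtype=float)
    if direction == "meth_on_kl":
        x = sm.add_constant(np.column_stack([kl, covs]))
        response = y
    elif direction == "kl_on_meth":
        x = sm.add_constant(np.column_stack([y, covs]))
        response = kl
    else:
        raise DomainError("direction must be 'meth_on_kl' or 'kl_on_meth'")
    if np.linalg.cond(x) > 1e10:
        raise InvalidDesignError("design matrix is (near-)singular")
    fit = sm.OLS(response, x).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def delta_ct(ct_goi: float, ct_housekeeping) -> float:
    """dCt = Ct(gene of interest) - mean(housekeeping Cts)."""
    hk = np.asarray(ct_housekeeping, dtype=float)
    if hk.size == 0:
        raise DomainError("need at least one housekeeping Ct")
    if np.any(hk <= 0) or ct_goi <= 0:
        raise DomainError("Ct values must be positive")
    return float(ct_goi - hk.mean())


def fold_change(dct_treated: float, dct_control: float) -> float:
    """Expression fold change, ``2 ** -(dCt_treated - dCt_control)``."""
    if not (np.isfinite(dct_treated) and np.isfinite(dct_control)):
        raise DomainError("delta-Ct values must be finite")
    return float(2.0 ** -(dct_treated - dct_control))


def qpcr_table(raw: pd.DataFrame, housekeeping_cols=("ct_gapdh", "ct_sdha")) -> pd.DataFrame:
    """Attach delta_ct / minus_delta_ct to a raw qPCR table.

    ``raw`` needs columns sample_id, condition, gene, ct_goi and the
    housekeeping Ct columns.
    """
    out = raw.copy()
    hk = out[list(housekeeping_cols)].to_numpy(dtype=float)
    out["delta_ct"] = out["ct_goi"].to_numpy(dtype=float) - hk.mean(axis=1)
    out["minus_delta_ct"] = -out["delta_ct"]
    return out


def loading_effect_glm(records: pd.DataFrame, gene: str) -> tuple[float, float]:
    """Loading effect on -dCt for one gene: Gaussian linear model
    ``minus_delta_ct ~ loaded``; returns (coefficient, two-sided p)."""
    sub = records[records["gene"] == gene]
    loaded = (sub["condition"] == "loaded").to_numpy(dtype=float)
    if loaded.sum() < 2 or (1 - loaded).sum() < 2:
        raise InvalidDesignError("need >= 2 samples in each condition")
    x = sm.add_constant(loaded)
    fit = sm.OLS(sub["minus_delta_ct"].to_numpy(dtype=float), x).fit()
    return float(fit.params[1]), float(fit.pvalues[1])
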