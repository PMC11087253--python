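"""Probe-level QC and normalization for methylation beta matrices.

The stages mirror a standard Infinium-array preprocessing chain: drop probes
that fail detection in any sample, quantile-normalize across samples, remove
technical variation captured by control probes, flag probes whose beta values
cluster like genotypes rather than methylation, and remove blacklisted
(cross-reactive / SNP-overlapping) probes.  All matrices are pandas DataFrames
with probes as rows and samples as columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError

logger = logging.getLogger(__name__)

#: clipping bound used when mapping beta values onto the M (logit) scale
BETA_EPS = 1e-6


@dataclass
class MethylationDataset:
    """A probe-by-sample beta matrix with detection p-values and sample sheet.

    ``beta`` and ``detp`` share index (probe ids) and columns (sample ids);
    ``samples`` is indexed by sample id and carries at least ``model`` and
    ``condition`` ({loaded, control}) columns.
    """

    beta: pd.DataFrame
    detp: pd.DataFrame
    samples: pd.DataFrame
    model_label: str = ""

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.detp.index) or not self.beta.columns.equals(
            self.detp.columns
        ):
            raise ValueError("beta and detp must share probes and samples")
        if self.beta.columns.has_duplicates:
            raise ValueError("sample ids must be unique")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def condition(self) -> pd.Series:
        """Per-sample condition aligned to the beta columns."""
        return self.samples.loc[self.beta.columns, "condition"]

    def subset_probes(self, probes: pd.Index) -> "MethylationDataset":
        return replace(self, beta=self.beta.loc[probes], detp=self.detp.loc[probes])


@dataclass
class QCReport:
    """Bookkeeping of how many probes each QC stage removed."""

    n_input_probes: int = 0
    n_failed_detection: int = 0
    n_snp_like: int = 0
    n_blacklisted: int = 0
    n_retained: int = 0
    removed: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input_probes": self.n_input_probes,
            "n_failed_detection": self.n_failed_detection,
            "n_snp_like": self.n_snp_like,
            "n_blacklisted": self.n_blacklisted,
            "n_retained": self.n_retained,
        }


def detection_filter(
    ds: MethylationDataset, p_thresh: float = 0.01
) -> tuple[MethylationDataset, pd.Index]:
    """Remove every probe whose detection p-value exceeds ``p_thresh`` in >= 1 sample."""
    if ds.n_probes == 0 or ds.n_samples == 0:
        raise EmptyInputError("detection_filter: empty dataset")
    failed = (ds.detp.to_numpy() > p_thresh).any(axis=1)
    removed = ds.beta.index[failed]
    kept = ds.beta.index[~failed]
    logger.info("detection filter: removed %d of %d probes", len(removed), ds.n_probes)
    return ds.subset_probes(kept), removed


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean order-statistic distribution.

    Ties within a column receive the average of the reference values they
    span, which makes the transform idempotent.
    """
    if matrix.isna().to_numpy().any():
        raise DomainError("quantile_normalize: missing values not allowed")
    if matrix.shape[1] < 2:
        logger.warning("quantile_normalize: single column, returning input unchanged")
        return matrix.copy()
    x = matrix.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(x.shape[0])[:, None], axis=0)
    out = reference[ranks]
    # average reference values across tied input values, column by column
    for j in range(x.shape[1]):
        col = x[:, j]
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=out[:, j])
            out[:, j] = (sums / counts)[inv]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def control_probe_normalize(
    values: pd.DataFrame, controls: pd.DataFrame, k: int = 2
) -> pd.DataFrame:
    """Regress the top-``k`` control-probe principal components out of each probe row.

    A light-weight analogue of functional normalization: technical variation
    shared between control probes and target probes is captured by a PCA on
    the standardized control matrix (controls x samples) and removed from the
    target rows.  Probe-wise means are preserved.
    """
    if not controls.columns.equals(values.columns):
        raise DomainError("controls must share sample columns with values")
    if k >= values.shape[1]:
        raise DomainError(f"k={k} must be < n_samples={values.shape[1]}")
    if k == 0:
        return values.copy()
    c = controls.to_numpy(dtype=float)
    c = c - c.mean(axis=1, keepdims=True)
    sd = c.std(axis=1, ddof=1, keepdims=True)
    nonzero = sd[:, 0] > 0
    if not nonzero.any():
        return values.copy()
    c = c[nonzero] / sd[nonzero]
    # right singular vectors live in sample space
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    comps = vt[: min(k, vt.shape[0])]  # (k, n_samples), orthonormal
    x = values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    resid = x - mean
    resid = resid - (resid @ comps.T) @ comps
    return pd.DataFrame(resid + mean, index=values.index, columns=values.columns)


def flag_snp_like_probes(
    ds: MethylationDataset,
    gap_low: float = 0.25,
    gap_high: float = 0.75,
    min_cluster_frac: float = 0.05,
    max_band_sd: float = 0.1,
    min_band_separation: float = 0.2,
) -> tuple[pd.Index, pd.Series]:
    """Flag probes whose betas fall into 2-3 tight genotype-like bands.

    A probe is flagged when its samples occupy at least two of the bands
    (< gap_low, [gap_low, gap_high], > gap_high), every occupied band holds at
    least ``min_cluster_frac`` of samples, each occupied band is tight
    (within-band SD < ``max_band_sd``), and the means of adjacent occupied
    bands are more than ``min_band_separation`` apart.  The separation rule
    keeps a unimodal probe that merely straddles a band boundary — or a truly
    differentially methylated probe whose two condition groups fall either
    side of one — from being mistaken for a genotype pattern.  Bands holding
    a single sample are treated as outliers and ignored (rare genotypes at
    modest sample sizes otherwise veto a clear two-band pattern).  The
    confidence score is ``1 - mean within-band SD / max_band_sd`` clipped to
    [0, 1].
    """
    if ds.n_samples < 10:
        logger.warning("flag_snp_like_probes: fewer than 10 samples, flags unreliable")
    x = ds.beta.to_numpy(dtype=float)
    n = x.shape[1]
    in_band = np.stack(
        [x < gap_low, (x >= gap_low) & (x <= gap_high), x > gap_high]
    )  # (3, probes, samples)
    counts = in_band.sum(axis=2)                      # (3, probes)
    occupied = counts >= 2                            # singleton bands = outliers
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(in_band, x, 0.0).sum(axis=2) / counts
        sq = np.where(in_band, x**2, 0.0).sum(axis=2) / counts
        sds = np.sqrt(np.maximum(sq - means**2, 0.0))
    frac_ok = (~occupied | (counts / n >= min_cluster_frac)).all(axis=0)
    sd_ok = (~occupied | (sds < max_band_sd)).all(axis=0)
    # adjacent occupied bands must be separated by more than min_band_separation
    big = 10.0  # sentinel gap for unoccupied bands
    gap01 = np.where(occupied[0] & occupied[1], np.abs(means[1] - means[0]), big)
    gap12 = np.where(occupied[1] & occupied[2], np.abs(means[2] - means[1]), big)
    gap02 = np.where(
        occupied[0] & occupied[2] & ~occupied[1], np.abs(means[2] - means[0]), big
    )
    sep_ok = (
        (gap01 > min_band_separation)
        & (gap12 > min_band_separation)
        & (gap02 > min_band_separation)
    )
    flags = (occupied.sum(axis=0) >= 2) & frac_ok & sd_ok & sep_ok
    mean_sd = np.where(occupied, sds, 0.0).sum(axis=0) / np.maximum(occupied.sum(axis=0), 1)
    confidence = np.where(flags, np.clip(1.0 - mean_sd / max_band_sd, 0.0, 1.0), 0.0)
    idx = ds.beta.index[flags]
    return idx, pd.Series(confidence, index=ds.beta.index, name="snp_confidence")


def remove_blacklisted(
    ds: MethylationDataset, blacklist: "str | list[str] | pd.Index"
) -> MethylationDataset:
    """Drop blacklisted probe ids (path to a one-id-per-line file, or an id list)."""
    if isinstance(blacklist, str):
        with open(blacklist) as fh:
            ids = [line.strip() for line in fh if line.strip()]
    else:
        ids = list(blacklist)
    present = ds.beta.index.intersection(ids)
    absent = len(set(ids)) - len(present)
    if absent:
        logger.info("remove_blacklisted: %d blacklist ids absent from dataset", absent)
    kept = ds.beta.index.difference(present, sort=False)
    if len(kept) == 0:
        logger.warning("remove_blacklisted: all probes removed")
    return ds.subset_probes(kept)


def beta_to_m(beta):
    """M-value transform, ``log2(beta / (1 - beta))`` with clipping at 1e-6."""
    b = np.clip(np.asarray(beta, dtype=float), BETA_EPS, 1 - BETA_EPS)
    return np.log2(b / (1 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def run_qc(
    ds: MethylationDataset,
    detection_p: float = 0.01,
    blacklist=None,
    controls: pd.DataFrame | None = None,
    control_k: int = 2,
    snp_kwargs: dict | None = None,
) -> tuple[MethylationDataset, QCReport]:
    """Full QC chain: detection filter -> quantile normalize -> control-probe
    normalization (when control probes are given) -> SNP-like and blacklist
    removal.  Returns the analysis-ready dataset and a reconciled report."""
    report = QCReport(n_input_probes=ds.n_probes)
    ds, removed_det = detection_filter(ds, detection_p)
    report.n_failed_detection = len(removed_det)
    report.removed["detection"] = list(removed_det)

    beta_qn = quantile_normalize(ds.beta)
    if controls is not None:
        beta_qn = control_probe_normalize(beta_qn, controls, k=control_k)
        beta_qn = beta_qn.clip(lower=BETA_EPS, upper=1 - BETA_EPS)
    ds = replace(ds, beta=beta_qn)

    snp_flags, _ = flag_snp_like_probes(ds, **(snp_kwargs or {}))
    report.n_snp_like = len(snp_flags)
    report.removed["snp_like"] = list(snp_flags)
    ds = ds.subset_probes(ds.beta.index.difference(snp_flags, sort=False))

    if blacklist is not None:
        before = ds.n_probes
        ds = remove_blacklisted(ds, blacklist)
        report.n_blacklisted = before - ds.n_probes

    if ds.beta.isna().to_numpy().any():
        bad = ds.beta.index[ds.beta.isna().any(axis=1)]
        logger.warning("run_qc: dropping %d probes with missing betas", len(bad))
        ds = ds.subset_probes(ds.beta.index.difference(bad, sort=False))

    report.n_retained = ds.n_probes
    return ds, report
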