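"""Differentially methylated region (DMR) calling from positional DM flags.

A DMR is a run of CpGs that starts and ends at a DM CpG, contains at least
``min_dm`` DM CpGs and at most ``max_nondm`` interspersed non-DM CpGs, with
every pair of consecutive member CpGs closer than ``max_gap_bp``.  Regions
are assembled greedily left to right and are maximal: no returned region can
be extended without violating a constraint.  Region-level significance is a
Stouffer combination of the member DM CpGs' signed z-scores (Fisher's method
is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnnotationMismatchError
from .differential_methylation import adjust_bh


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    n_dm: int
    n_nondm: int
    probe_ids: list = field(default_factory=list)
    p_combined: float = np.nan
    q: float = np.nan

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and self.end >= start


def scan_dmrs(
    meta: pd.DataFrame,
    annotation: pd.DataFrame,
    min_dm: int = 3,
    max_gap_bp: int = 1000,
    max_nondm: int = 3,
) -> list[DMR]:
    """Greedy left-to-right maximal assembly of DMRs.

    ``meta`` must carry a boolean ``dm_flag`` column indexed by probe id;
    ``annotation`` supplies ``chrom`` and ``pos`` for every probe in ``meta``.
    """
    missing = meta.index.difference(annotation.index)
    if len(missing) > 0:
        raise AnnotationMismatchError(
            f"probes missing from annotation: {list(missing[:10])}"
        )
    tab = annotation.loc[meta.index, ["chrom", "pos"]].copy()
    tab["dm"] = meta["dm_flag"].to_numpy(dtype=bool)
    tab = tab.sort_values(["chrom", "pos"], kind="stable")

    regions: list[DMR] = []
    for chrom, sub in tab.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        dm = sub["dm"].to_numpy()
        ids = sub.index.to_numpy()
        n = len(pos)
        i = 0
        while i < n:
            if not dm[i]:
                i += 1
                continue
            # extend from the DM anchor at i as far as the rules allow
            n_dm_run, nondm, pending = 1, 0, 0
            best = i
            j = i + 1
            while j < n:
                if pos[j] - pos[j - 1] >= max_gap_bp:
                    break
                if dm[j]:
                    if nondm + pending > max_nondm:
                        break
                    nondm += pending
                    pending = 0
                    n_dm_run += 1
                    best = j
                else:
                    pending += 1
                j += 1
            if n_dm_run >= min_dm:
                members = list(ids[i : best + 1])
                regions.append(
                    DMR(
                        chrom=str(chrom),
                        start=int(pos[i]),
                        end=int(pos[best]),
                        n_dm=n_dm_run,
                        n_nondm=nondm,
                        probe_ids=members,
                    )
                )
                i = best + 1
            else:
                i += 1
    return regions


def dmr_significance(
    dmrs: list[DMR], meta: pd.DataFrame, method: str = "stouffer"
) -> list[DMR]:
    """Attach a combined p-value (over member DM CpGs) and BH q to each DMR."""
    if not dmrs:
        return []
    p_comb = []
    for dmr in dmrs:
        members = [p for p in dmr.probe_ids if bool(meta.loc[p, "dm_flag"])]
        if method == "stouffer":
            z = meta.loc[members, "z"].to_numpy(dtype=float)
            z_comb = z.sum() / np.sqrt(len(z))
            p = 2 * stats.norm.sf(abs(z_comb))
        elif method == "fisher":
            pv = meta.loc[members, "p"].to_numpy(dtype=float)
            chi2 = -2 * np.log(np.clip(pv, 1e-300, 1.0)).sum()
            p = stats.chi2.sf(chi2, 2 * len(pv))
        else:
            raise ValueError("method must be 'stouffer' or 'fisher'")
        p_comb.append(float(p))
    q = adjust_bh(np.array(p_comb))
    out = []
    for dmr, p, qq in zip(dmrs, p_comb, q):
        out.append(
            DMR(dmr.chrom, dmr.start, dmr.end, dmr.n_dm, dmr.n_nondm,
                list(dmr.probe_ids), p_combined=p, q=float(qq))
        )
    return out


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """BED-like table (0-based start) of called regions."""
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start - 1 for d in dmrs],
            "end": [d.end for d in dmrs],
            "n_dm": [d.n_dm for d in dmrs],
            "n_nondm": [d.n_nondm for d in dmrs],
            "p_combined": [d.p_combined for d in dmrs],
            "q": [d.q for d in dmrs],
        }
    )
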