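"""Enrichment of DM CpGs across the 15 ChromHMM chromatin states.

For each state a 2x2 table (DM / non-DM x in-state / not-in-state) over the
tested probe universe is scored with a two-sided Fisher exact test; BH runs
across the 15 states only.  Both enrichment (OR > 1) and depletion (OR < 1)
are reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CHROMATIN_STATES
from .differential_methylation import adjust_bh

logger = logging.getLogger(__name__)


def enrichment_by_state(
    meta: pd.DataFrame,
    annotation: pd.DataFrame,
    states: tuple[str, ...] = CHROMATIN_STATES,
) -> pd.DataFrame:
    """One row per chromatin state: counts, odds ratio, Fisher p, BH q.

    The background universe is every probe in ``meta`` (the tested set, i.e.
    all probes surviving QC and meta-analysis).  States with zero tested
    probes get null statistics and are excluded from the BH family.
    """
    probes = meta.index
    state = annotation.loc[probes, "chrom_state"]
    dm = meta["dm_flag"].to_numpy(dtype=bool)
    n_dm = int(dm.sum())
    n_all = len(probes)

    rows = []
    for st in states:
        in_state = (state == st).to_numpy()
        a = int((dm & in_state).sum())          # DM, in state
        b = n_dm - a                            # DM, not in state
        c = int((~dm & in_state).sum())         # non-DM, in state
        d = (n_all - n_dm) - c                  # non-DM, not in state
        if a + c == 0:
            logger.info("enrichment_by_state: no tested probes in state %s", st)
            rows.append((st, a, b, c, d, np.nan, np.nan))
            continue
        if b * c > 0:
            odds = (a * d) / (b * c)
        elif a * d == 0:
            odds = 0.0 if a == 0 or d == 0 else np.nan
        else:
            odds = np.inf
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((st, a, b, c, d, float(odds), float(p)))
    out = pd.DataFrame(
        rows, columns=["state", "a", "b", "c", "d", "odds_ratio", "p"]
    ).set_index("state")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = adjust_bh(out.loc[tested, "p"].to_numpy())
    return out
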