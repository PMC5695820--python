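"""One-sided replication testing with Bonferroni correction.

Replication of discovery associations in an independent cohort uses a
one-sided test whose direction is fixed by the discovery effect sign:
this is more powerful than two-sided testing while still controlling
type-I error in the replication stage. Significance is declared at the
family-wise Bonferroni threshold alpha / m over the m tested
(variant, trait) pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def one_sided_p(rep_effect: float, rep_se: float, discovery_sign: float, t_df: int | None = None) -> float:
    """One-sided replication p-value in the discovery direction.

    z = effect / SE; upper normal tail if the discovery effect was
    positive, lower tail otherwise. ``t_df`` switches to a Student-t
    reference for small replication cohorts.
    """
    if rep_se <= 0:
        raise ValueError("replication SE must be positive")
    if discovery_sign == 0:
        raise ValueError("discovery effect sign must be nonzero")
    z = rep_effect / rep_se
    dist = stats.t(df=t_df) if t_df is not None else stats.norm
    return float(dist.sf(z) if discovery_sign > 0 else dist.cdf(z))


def bonferroni_threshold(m_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha / m."""
    if m_tests < 1:
        raise ValueError("number of tests must be at least 1")
    return family_alpha / m_tests


def replication_table(
    records: pd.DataFrame,
    family_alpha: float = 0.05,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Summary-level replication report.

    ``records`` needs columns ``variant``, ``trait``, ``discovery_effect``,
    ``rep_effect``, ``rep_se`` (extra columns pass through). Adds the
    one-sided p, the Bonferroni threshold over the tested pairs, and the
    significance flag.
    """
    out = records.copy()
    out["p_one_sided"] = [
        one_sided_p(e, s, np.sign(d))
        for e, s, d in zip(out["rep_effect"], out["rep_se"], out["discovery_effect"])
    ]
    thr = bonferroni_threshold(m_tests if m_tests is not None else len(out), family_alpha)
    out["bonferroni_threshold"] = thr
    out["replicated"] = out["p_one_sided"] < thr
    return out
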