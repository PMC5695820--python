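"""Blood-pressure trait derivation, medication adjustment, and exclusions.

The preparation pipeline mirrors the standard epidemiological BP workflow:
for treated individuals the measured pressures are shifted up by fixed
constants (+10 mmHg SBP, +5 mmHg DBP) to approximate the untreated value;
pulse pressure PP = SBP - DBP and mean arterial pressure MAP = DBP + PP/3
are derived; and records failing measurement-consistency, range, or
completeness rules are excluded with an audited reason code. Extreme PP
values are winsorized at mean + 6 SD of the analysed sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SBP_MED_ADJUSTMENT = 10.0  # mmHg added to treated SBP
DBP_MED_ADJUSTMENT = 5.0   # mmHg added to treated DBP
INCONSISTENCY_MMHG = 5.0   # device-vs-raw mean disagreement that drops a record
SBP_FLOOR = 80.0           # strict <: SBP below this is excluded
DBP_FLOOR = 50.0           # strict <: DBP below this is excluded
WINSOR_SD = 6.0            # PP winsorization at mean + 6 SD

# Exclusion reason codes, applied in this order; each dropped record gets
# the first rule it fails.
REASON_INCONSISTENT = "measurement_inconsistency"
REASON_MISSING = "missing_covariate_or_outcome"
REASON_RANGE = "bp_out_of_range"
REASON_NEGATIVE_PP = "negative_pp"


@dataclass
class ExclusionConfig:
    """Thresholds of the exclusion rules; defaults are the standard values."""

    inconsistency_mmhg: float = INCONSISTENCY_MMHG
    sbp_floor: float = SBP_FLOOR
    dbp_floor: float = DBP_FLOOR
    winsor_sd: float = WINSOR_SD
    map_standard: bool = True  # MAP = DBP + PP/3; False gives DBP - PP/3
    required_covariates: tuple[str, ...] = ("age", "sex", "on_meds")
    sbp_adjustment: float = SBP_MED_ADJUSTMENT
    dbp_adjustment: float = DBP_MED_ADJUSTMENT


@dataclass
class TraitTable:
    """Prepared traits plus the exclusion audit log.

    ``traits`` has one row per retained individual with SBP, DBP, PP, MAP
    (medication-adjusted, winsorized); ``exclusion_log`` one row per
    dropped record with its primary reason code; ``winsorized`` records
    every value replaced by the mean+6SD cap.
    """

    traits: pd.DataFrame
    exclusion_log: pd.DataFrame
    winsorized: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_retained(self) -> int:
        return len(self.traits)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusion_log)


def adjust_for_medication(
    df: pd.DataFrame,
    sbp_col: str = "sbp_mean",
    dbp_col: str = "dbp_mean",
    meds_col: str = "on_meds",
    sbp_add: float = SBP_MED_ADJUSTMENT,
    dbp_add: float = DBP_MED_ADJUSTMENT,
) -> pd.DataFrame:
    """Add +10/+5 mmHg to SBP/DBP of individuals on anti-hypertensives.

    Records with a missing medication flag are left unchanged here; they
    are routed to the missing-covariate exclusion by `apply_exclusions`.
    """
    out = df.copy()
    meds = out[meds_col]
    treated = pd.Series(
        [bool(v) if pd.notna(v) else False for v in meds], index=out.index
    )
    out.loc[treated, sbp_col] = out.loc[treated, sbp_col] + sbp_add
    out.loc[treated, dbp_col] = out.loc[treated, dbp_col] + dbp_add
    return out


def derive_traits(sbp, dbp, map_standard: bool = True):
    """Pulse pressure and mean arterial pressure from SBP and DBP.

    PP = SBP - DBP. MAP is DBP + PP/3 under the physiological convention
    (``map_standard=True``); the alternative DBP - PP/3 is available for
    comparison with sources that print it that way.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    pp = sbp - dbp
    map_ = dbp + pp / 3.0 if map_standard else dbp - pp / 3.0
    if np.isscalar(sbp) or sbp.ndim == 0:
        return float(pp), float(map_)
    return pp, map_


def apply_exclusions(records: pd.DataFrame, config: ExclusionConfig | None = None) -> TraitTable:
    """Run the full preparation: adjust, derive, exclude, winsorize.

    Rules in order (a dropped record carries the first failing rule):

    1. measurement inconsistency: |device mean - raw mean| >= 5 mmHg for
       SBP or DBP;
    2. missing covariates or outcomes;
    3. range: SBP < 80 or DBP < 50 (strict, on the medication-adjusted
       scale);
    4. negative pulse pressure.

    PP values above mean + 6 SD — both computed on the sample retained
    after all exclusions — are winsorized to exactly that cap, so the
    sample size is unchanged. Idempotent: rerunning on the output's
    retained rows changes nothing.
    """
    if len(records) == 0:
        raise ValueError("empty phenotype table")
    cfg = config or ExclusionConfig()
    df = records.reset_index(drop=True).copy()
    reason = pd.Series(pd.NA, index=df.index, dtype="object")

    # 1. device-vs-raw inconsistency on either trait, tested on the raw scale.
    if {"sbp_raw_mean", "dbp_raw_mean"}.issubset(df.columns):
        d_sbp = (df["sbp_mean"] - df["sbp_raw_mean"]).abs()
        d_dbp = (df["dbp_mean"] - df["dbp_raw_mean"]).abs()
        inconsistent = (d_sbp >= cfg.inconsistency_mmhg) | (d_dbp >= cfg.inconsistency_mmhg)
        reason[inconsistent.fillna(False) & reason.isna()] = REASON_INCONSISTENT

    # 2. missing outcomes or covariates (including the medication flag).
    required = ["sbp_mean", "dbp_mean"] + [c for c in cfg.required_covariates if c in df.columns]
    missing = df[required].isna().any(axis=1)
    reason[missing & reason.isna()] = REASON_MISSING

    # Medication adjustment on records that still have a flag.
    adj = adjust_for_medication(df, sbp_add=cfg.sbp_adjustment, dbp_add=cfg.dbp_adjustment)
    sbp, dbp = adj["sbp_mean"], adj["dbp_mean"]

    # 3. physiological range, strict inequalities.
    out_of_range = (sbp < cfg.sbp_floor) | (dbp < cfg.dbp_floor)
    reason[out_of_range.fillna(False) & reason.isna()] = REASON_RANGE

    # 4. negative pulse pressure.
    pp, map_ = derive_traits(sbp, dbp, map_standard=cfg.map_standard)
    reason[pd.Series(pp < 0, index=df.index) & reason.isna()] = REASON_NEGATIVE_PP

    keep = reason.isna()
    traits = df.loc[keep].copy()
    traits["SBP"] = sbp[keep]
    traits["DBP"] = dbp[keep]
    traits["PP"] = pp[keep.to_numpy()]
    traits["MAP"] = map_[keep.to_numpy()]

    # Winsorize PP on the analysed sample.
    winsorized = pd.DataFrame(columns=["sample", "original_pp", "cap"])
    if len(traits) > 1:
        cap = traits["PP"].mean() + cfg.winsor_sd * traits["PP"].std(ddof=1)
        over = traits["PP"] > cap
        if over.any():
            winsorized = pd.DataFrame(
                {
                    "sample": traits.loc[over, "sample"] if "sample" in traits else traits.index[over],
                    "original_pp": traits.loc[over, "PP"],
                    "cap": cap,
                }
            )
            traits.loc[over, "PP"] = cap
            traits.loc[over, "MAP"] = traits.loc[over, "DBP"] + traits.loc[over, "PP"] / 3.0

    log = pd.DataFrame(
        {
            "sample": df.loc[~keep, "sample"] if "sample" in df else df.index[~keep],
            "reason": reason[~keep],
        }
    ).reset_index(drop=True)
    return TraitTable(traits=traits.reset_index(drop=True), exclusion_log=log, winsorized=winsorized)
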