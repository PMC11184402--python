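"""Two-sample Mendelian randomization by inverse-variance weighting.

Exposure instruments (eQTL effects on a marker gene's expression, in
SD units) are harmonized with outcome associations (e.g. blood
pressure in mm Hg), per-instrument Wald ratios are combined by
fixed-effect IVW, and the estimate is reported in outcome units per
SD of exposure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

INSTRUMENT_COLUMNS = [
    "snp_id", "beta_exp", "se_exp", "beta_out", "se_out", "a1", "a2",
]


class HarmonizationError(ValueError):
    pass


@dataclass
class MRResult:
    estimate: float
    se: float
    p_two_sided: float
    n_instruments: int
    method: str = "ivw_fixed"


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    Both tables need snp_id, a1 (effect allele), a2, beta, se.  Outcome
    betas are sign-flipped where its effect allele equals the
    exposure's other allele; palindromic (A/T, C/G) SNPs and SNPs whose
    alleles cannot be reconciled are dropped.
    """
    exp = exposure.rename(columns={"beta": "beta_exp", "se": "se_exp"})
    out = outcome.rename(
        columns={"beta": "beta_out", "se": "se_out", "a1": "a1_out", "a2": "a2_out"}
    )
    merged = exp.merge(out[["snp_id", "a1_out", "a2_out", "beta_out", "se_out"]], on="snp_id")
    n_dropped_overlap = len(exposure) - len(merged)
    if merged.empty:
        raise HarmonizationError("no overlapping SNPs between exposure and outcome")

    rows = []
    n_palindromic = n_mismatch = 0
    for r in merged.itertuples():
        a1, a2 = str(r.a1).upper(), str(r.a2).upper()
        b1, b2 = str(r.a1_out).upper(), str(r.a2_out).upper()
        if (a1, a2) in _PALINDROMIC:
            n_palindromic += 1
            continue
        if (b1, b2) == (a1, a2):
            beta_out = r.beta_out
        elif (b1, b2) == (a2, a1):
            beta_out = -r.beta_out
        else:
            n_mismatch += 1
            continue
        rows.append(
            {"snp_id": r.snp_id, "beta_exp": r.beta_exp, "se_exp": r.se_exp,
             "beta_out": beta_out, "se_out": r.se_out, "a1": a1, "a2": a2}
        )
    if n_palindromic or n_mismatch or n_dropped_overlap:
        logger.info(
            "harmonize: dropped %d non-overlapping, %d palindromic, %d allele-mismatch SNPs",
            n_dropped_overlap, n_palindromic, n_mismatch,
        )
    if not rows:
        raise HarmonizationError("harmonization left no usable instruments")
    inst = pd.DataFrame(rows)
    if (inst["se_exp"] <= 0).any() or (inst["se_out"] <= 0).any():
        raise HarmonizationError("standard errors must be positive")
    return inst


def ivw(instruments: pd.DataFrame, random_effects: bool = False) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate over Wald ratios.

    Per instrument i: ratio r_i = beta_out/beta_exp with first-order
    SE sigma_i = se_out/|beta_exp|.  Estimate = sum(r_i/sigma_i^2) /
    sum(1/sigma_i^2); SE = sqrt(1/sum(1/sigma_i^2)).  With
    ``random_effects`` the SE is inflated by max(1, sqrt(Q/(k-1)))
    (multiplicative random-effects scaling).
    """
    inst = instruments.copy()
    usable = inst["beta_exp"] != 0
    if (~usable).any():
        warnings.warn(
            f"{int((~usable).sum())} instruments with zero exposure effect excluded",
            stacklevel=2,
        )
    inst = inst.loc[usable]
    if inst.empty:
        raise ValueError("no instruments with nonzero exposure effect")

    ratio = inst["beta_out"].to_numpy() / inst["beta_exp"].to_numpy()
    sigma = inst["se_out"].to_numpy() / np.abs(inst["beta_exp"].to_numpy())
    w = 1.0 / sigma**2
    est = float(np.sum(w * ratio) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    k = len(inst)
    if random_effects and k > 1:
        q = float(np.sum(w * (ratio - est) ** 2))
        se *= max(1.0, np.sqrt(q / (k - 1)))
    p = float(2.0 * norm.sf(abs(est) / se)) if se > 0 else float(est == 0)
    return MRResult(
        estimate=est, se=se, p_two_sided=min(p, 1.0), n_instruments=k,
        method="ivw_random" if random_effects else "ivw_fixed",
    )


def mr_analysis(
    exposure: pd.DataFrame, outcome: pd.DataFrame, random_effects: bool = False
) -> tuple[MRResult, pd.DataFrame]:
    """Harmonize then IVW; returns the result and the instrument table."""
    inst = harmonize(exposure, outcome)
    return ivw(inst, random_effects=random_effects), inst


def result_table(res: MRResult) -> pd.DataFrame:
    return pd.DataFrame(
        [{"estimate": res.estimate, "se": res.se, "p": res.p_two_sided,
          "n_instruments": res.n_instruments, "method": res.method}]
    )
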