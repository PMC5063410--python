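"""ΔΔCt qPCR statistics for the isoform assays.

Ct is the PCR cycle at which a well's fluorescence crosses threshold; one
cycle is one doubling, so abundance ratios are powers of two of Ct
differences (amplification efficiency fixed at 2.0, as in standard ΔΔCt).
Implemented here: ΔΔCt fold changes against a reference assay (beta
actin), per-assay ΔCt under RNase R treatment (linear RNAs gain Ct, circles
do not), linear:circular ratio fold changes across deletion constructs
normalised to the full-length construct, and the box-plot summary used for
reporting (median, quartiles, 1.5×IQR whiskers). Quartiles use linear
interpolation (type 7); recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CT_COLUMNS = ["assay", "condition", "replicate", "ct"]
QUARTILE_METHOD = "linear (type 7)"


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of Ct measurements: assay, condition, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError(f"{path}: Ct values must be positive")
    return df


def _cell(df: pd.DataFrame, assay: str, condition: str) -> pd.Series:
    sub = df[(df["assay"] == assay) & (df["condition"] == condition)]
    if sub.empty:
        raise ValueError(f"no Ct measurements for assay={assay!r}, "
                         f"condition={condition!r}")
    return sub.sort_values("replicate").set_index("replicate")["ct"]


@dataclass
class FoldChangeResult:
    """ΔΔCt fold change, reported both ways the replicates can be summarised."""

    ddct_per_replicate: np.ndarray
    fold_per_replicate: np.ndarray

    @property
    def fold_of_mean_ddct(self) -> float:
        """2^-mean(ΔΔCt): fold change of the replicate-mean ΔΔCt."""
        return float(2.0 ** -np.mean(self.ddct_per_replicate))

    @property
    def mean_fold(self) -> float:
        """Arithmetic mean of per-replicate fold changes."""
        return float(np.mean(self.fold_per_replicate))


def delta_delta_ct(
    measurements: pd.DataFrame,
    target_assay: str,
    reference_assay: str,
    treated: str,
    control: str,
) -> FoldChangeResult:
    """Fold change 2^-ΔΔCt of the target against the reference assay.

    ΔΔCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control,
    computed replicate-wise (replicates paired by index; the control ΔCt is
    averaged when replicate indices do not align).
    """
    dct = {}
    for cond in (treated, control):
        t = _cell(measurements, target_assay, cond)
        r = _cell(measurements, reference_assay, cond)
        common = t.index.intersection(r.index)
        if common.empty:
            raise ValueError(f"no paired replicates for condition {cond!r}")
        dct[cond] = (t.loc[common] - r.loc[common]).to_numpy()
    treated_dct = dct[treated]
    control_dct = dct[control]
    if len(control_dct) == len(treated_dct):
        ddct = treated_dct - control_dct
    else:
        ddct = treated_dct - control_dct.mean()
    return FoldChangeResult(ddct_per_replicate=ddct,
                            fold_per_replicate=2.0 ** -ddct)


def rnase_r_resistance(
    measurements: pd.DataFrame,
    treated: str = "rnase_r",
    untreated: str = "mock",
) -> pd.DataFrame:
    """Per-assay ΔCt = Ct_treated - Ct_untreated and its classification.

    RNase R degrades linear RNA, raising its Ct (ΔCt > 0: sensitive);
    circular RNA survives or is enriched (ΔCt <= 0: resistant).
    Replicates are paired by index; unpaired replicates are an error.
    """
    rows = []
    for assay in sorted(measurements["assay"].unique()):
        t = _cell(measurements, assay, treated)
        u = _cell(measurements, assay, untreated)
        if not t.index.equals(u.index):
            raise ValueError(f"assay {assay!r}: treated/untreated replicates unpaired")
        for rep in t.index:
            d = float(t.loc[rep] - u.loc[rep])
            rows.append({"assay": assay, "replicate": rep, "delta_ct": d,
                         "classification": "sensitive" if d > 0 else "resistant"})
    return pd.DataFrame(rows)


@dataclass
class RatioResult:
    """Linear:circular ratio of one construct, normalised to full length."""

    condition: str
    fold_ratio: float                 # summary ratio / reference summary ratio
    per_replicate: np.ndarray         # normalised per-replicate ratios
    summary: dict                     # box-plot summary of per-replicate values


def linear_circular_ratio(
    measurements: pd.DataFrame,
    condition: str,
    reference_condition: str = "full-length",
    linear_assay: str = "short",
    circle_assay: str = "circle",
) -> RatioResult:
    """Fold change of the linear:circular ratio relative to the reference.

    Per replicate the ratio is 2^-(Ct_linear - Ct_circle); condition
    summaries are geometric means (equivalently 2^-mean ΔCt), so the
    reference condition's normalised ratio is exactly 1.
    """
    def per_rep(cond: str) -> np.ndarray:
        lin = _cell(measurements, linear_assay, cond)
        cir = _cell(measurements, circle_assay, cond)
        common = lin.index.intersection(cir.index)
        if common.empty:
            raise ValueError(f"no paired short/circle replicates for {cond!r}")
        return 2.0 ** -(lin.loc[common] - cir.loc[common]).to_numpy()

    try:
        ref = per_rep(reference_condition)
    except ValueError as exc:
        raise ValueError(
            f"missing reference condition {reference_condition!r}: {exc}"
        ) from exc
    cond_ratios = per_rep(condition)
    geo = lambda x: float(np.exp(np.mean(np.log(x))))
    normalised = cond_ratios / geo(ref)
    return RatioResult(
        condition=condition,
        fold_ratio=geo(cond_ratios) / geo(ref),
        per_replicate=normalised,
        summary=boxplot_summary(normalised),
    )


def boxplot_summary(values) -> dict:
    """Median, quartiles and 1.5×IQR whiskers.

    Whiskers are the most extreme observations still inside
    [q1 - 1.5*IQR, q3 + 1.5*IQR]; quartiles use linear interpolation.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty value set")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_bound) & (arr <= hi_bound)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "lower_whisker": float(inside.min()),
        "upper_whisker": float(inside.max()),
        "quartile_method": QUARTILE_METHOD,
    }
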