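"""ChIP-qPCR relative occupancy: standard curves, quantification, and the
IP/input → control-region → 5S normalization chain.

Standard curves are ordinary least-squares lines of mean Ct versus log10
relative quantity over a serial dilution; amplification efficiency is
10^(-1/slope) - 1. Occupancy of a factor at a target locus is the IP/input
quantity ratio, divided by the same ratio at a non-transcribed control region
(chromosome VII), divided by the same control-normalized ratio at the 5S
gene, and finally expressed as fold versus a reference condition. With 100%
efficiency the whole chain reduces to 2-based ΔΔCt arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StdCurve",
    "OccupancyResult",
    "fit_standard_curve",
    "fit_standard_curves",
    "quantify",
    "relative_occupancy",
]


@dataclass
class StdCurve:
    amplicon: str
    slope: float  # Ct per log10 quantity, < 0
    intercept: float  # Ct at log10 quantity 0
    efficiency: float  # 10^(-1/slope) - 1
    r_squared: float


def fit_standard_curve(dilution_cts: dict[float, list[float]] | pd.DataFrame,
                       amplicon: str = "") -> StdCurve:
    """OLS line of mean Ct vs log10 relative quantity over >= 3 dilutions.

    Accepts a mapping {log10_quantity: [Ct replicates]} or a DataFrame with
    ``log10_quantity`` and ``ct`` columns.
    """
    if isinstance(dilution_cts, pd.DataFrame):
        grouped = dilution_cts.groupby("log10_quantity")["ct"].apply(list)
        dilution_cts = dict(grouped)
    if len(dilution_cts) < 3:
        raise ValueError("need >= 3 distinct dilutions to fit a standard curve")
    x = np.array(sorted(dilution_cts), dtype=float)
    y = np.array([float(np.mean(dilution_cts[k])) for k in sorted(dilution_cts)])
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope >= 0:
        raise ValueError(
            f"invalid standard curve for {amplicon or 'amplicon'}: "
            f"slope {slope:.3f} >= 0 (Ct must fall as quantity rises)")
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StdCurve(amplicon, float(slope), float(intercept), float(efficiency),
                    float(r2))


def fit_standard_curves(dilutions: pd.DataFrame) -> dict[str, StdCurve]:
    """Per-amplicon standard curves from a long table (amplicon,
    log10_quantity, ct)."""
    return {amp: fit_standard_curve(sub, amp)
            for amp, sub in dilutions.groupby("amplicon")}


def quantify(ct: float, curve: StdCurve) -> float:
    """Relative quantity 10^((ct - intercept) / slope); higher Ct → less."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


@dataclass
class OccupancyResult:
    target_locus: str
    control_locus: str
    reference_locus: str
    reference_condition: str
    per_replicate: pd.DataFrame  # condition, replicate, ip_input, control_norm, occupancy, fold
    summary: pd.DataFrame  # condition, mean, sd, n, fold_vs_reference


_REQUIRED = ("condition", "replicate", "fraction", "amplicon", "ct")


def relative_occupancy(cts: pd.DataFrame, curves: dict[str, StdCurve],
                       target_locus: str, control_locus: str = "chrVII_control",
                       reference_locus: str = "5S",
                       reference_condition: str | None = None) -> OccupancyResult:
    """Full normalization chain per condition and biological replicate.

    Technical replicates are averaged on the Ct scale (geometric mean of
    quantities). Per replicate: r(locus) = Q_IP / Q_input; c(locus) =
    r(locus) / r(control); occupancy = c(target) / c(reference locus); fold =
    occupancy / mean occupancy of the reference condition.
    """
    missing_cols = [c for c in _REQUIRED if c not in cts.columns]
    if missing_cols:
        raise ValueError(f"Ct table lacks columns: {missing_cols}")
    if not np.isfinite(cts["ct"]).all() or (cts["ct"] <= 0).any():
        raise ValueError("all Ct values must be finite and > 0")
    needed = {target_locus, control_locus, reference_locus}
    have = set(cts["amplicon"].unique())
    if not needed <= have:
        raise ValueError(f"Ct table lacks loci: {sorted(needed - have)}")
    for locus in needed:
        if locus not in curves:
            raise ValueError(f"no standard curve for locus {locus!r}")

    mean_ct = (cts.groupby(["condition", "replicate", "fraction", "amplicon"],
                           sort=True)["ct"].mean().reset_index())

    rows = []
    for (cond, rep), sub in mean_ct.groupby(["condition", "replicate"], sort=True):
        table = sub.set_index(["fraction", "amplicon"])["ct"]

        def ratio(locus: str) -> float:
            for frac in ("IP", "input"):
                if (frac, locus) not in table.index:
                    raise ValueError(
                        f"missing {frac} Ct for locus {locus!r} in condition "
                        f"{cond!r} replicate {rep!r}")
            q_ip = quantify(table[("IP", locus)], curves[locus])
            q_in = quantify(table[("input", locus)], curves[locus])
            if q_ip <= 0 or q_in <= 0:
                raise ValueError(f"non-positive quantity at locus {locus!r}")
            return q_ip / q_in

        r_ctrl = ratio(control_locus)
        c_target = ratio(target_locus) / r_ctrl
        c_ref = ratio(reference_locus) / r_ctrl
        rows.append({"condition": cond, "replicate": rep,
                     "ip_input": ratio(target_locus),
                     "control_norm": c_target,
                     "occupancy": c_target / c_ref})
    per_rep = pd.DataFrame(rows)

    if reference_condition is None:
        reference_condition = str(per_rep["condition"].iloc[0])
    if reference_condition not in set(per_rep["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ref_mean = per_rep.loc[per_rep["condition"] == reference_condition,
                           "occupancy"].mean()
    per_rep["fold"] = per_rep["occupancy"] / ref_mean

    summary = (per_rep.groupby("condition")["occupancy"]
               .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
               .reset_index())
    summary["sd"] = summary["sd"].fillna(0.0)
    summary["fold_vs_reference"] = summary["mean"] / ref_mean
    return OccupancyResult(target_locus, control_locus, reference_locus,
                           reference_condition, per_rep, summary)
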