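"""qPCR copy-number arithmetic: standard-curve quantification,
dual-reference normalization, tumor/normal ratios and the 2^-ddCt
comparator."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import linear_fit

#: default deviation-from-unity cutoff; loss when mean ratio < 1 - cutoff,
#: gain when mean ratio > 1 + cutoff
DEFAULT_RATIO_CUTOFF = 0.2

REFERENCE_ASSAYS = ("ALPHA_SAT", "ALB")


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of Ct on log10(input quantity)."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float

    def predict(self, quantity: float) -> float:
        if quantity <= 0:
            raise ValueError("quantity must be positive")
        return self.intercept + self.slope * math.log10(quantity)


@dataclass(frozen=True)
class CopyNumberRatio:
    target: str
    sample: str
    per_reference: Dict[str, float]  # reference name -> mean ratio
    mean_ratio: float
    classification: str  # loss | normal | gain
    references_concur: bool


def fit_standard_curve(quantities: Sequence[float], cts: Sequence[Sequence[float]] | Sequence[float]) -> StandardCurve:
    """Fit a dilution-series standard curve.

    ``quantities`` are the input amounts (>= 4 distinct, all positive);
    ``cts`` is either one Ct per point or a list of replicate lists.
    Efficiency = 10^(-1/slope) - 1.
    """
    q = [float(v) for v in quantities]
    if any(v <= 0 for v in q):
        raise ValueError("quantities must be strictly positive")
    if len(set(q)) < 4:
        raise ValueError("need >= 4 distinct quantities for a standard curve")
    xs, ys = [], []
    for quantity, ct in zip(q, cts, strict=True):
        reps = np.atleast_1d(np.asarray(ct, dtype=float))
        xs.extend([math.log10(quantity)] * reps.size)
        ys.extend(reps.tolist())
    fit = linear_fit(xs, ys)
    if fit.slope == 0:
        raise ValueError("flat standard curve: slope is zero")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(fit.slope, fit.intercept, fit.r_squared, efficiency)


def quantify(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: quantity = 10^((Ct - intercept)/slope)."""
    if curve.slope == 0:
        raise ValueError("cannot quantify on a zero-slope curve")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def copy_ratio(
    target_tumor: Sequence[float],
    target_normal: Sequence[float],
    references_tumor: Mapping[str, Sequence[float]],
    references_normal: Mapping[str, Sequence[float]],
    cutoff: float = DEFAULT_RATIO_CUTOFF,
    target: str = "",
    sample: str = "",
) -> CopyNumberRatio:
    """Dual-reference normalized tumor/normal quantity ratio.

    Quantities are given per measurement level (e.g. the two gDNA inputs);
    for each reference r and level i the ratio is
    (target_T[i]/ref_rT[i]) / (target_N[i]/ref_rN[i]); ratios are averaged
    over levels then over references.  Classified loss when the mean ratio
    falls below 1 - cutoff and gain above 1 + cutoff (deviation-from-unity
    reading of the 0.2 cutoff).
    """
    if set(references_tumor) != set(references_normal) or not references_tumor:
        raise ValueError("tumor and normal must carry the same reference assays")
    tt = np.asarray(target_tumor, dtype=float)
    tn = np.asarray(target_normal, dtype=float)
    per_reference: Dict[str, float] = {}
    for ref in references_tumor:
        rt = np.asarray(references_tumor[ref], dtype=float)
        rn = np.asarray(references_normal[ref], dtype=float)
        if np.any(tt <= 0) or np.any(tn <= 0) or np.any(rt <= 0) or np.any(rn <= 0):
            raise ValueError("quantities must be strictly positive")
        per_reference[ref] = float(np.mean((tt / rt) / (tn / rn)))
    mean_ratio = float(np.mean(list(per_reference.values())))

    def classify(ratio: float) -> str:
        if ratio < 1.0 - cutoff:
            return "loss"
        if ratio > 1.0 + cutoff:
            return "gain"
        return "normal"

    classification = classify(mean_ratio)
    concur = len({classify(r) for r in per_reference.values()}) == 1
    return CopyNumberRatio(target, sample, per_reference, mean_ratio, classification, concur)


def ddct_ratio(ct_target_tumor: float, ct_ref_tumor: float,
               ct_target_normal: float, ct_ref_normal: float) -> float:
    """Relative quantity 2^-((CtT,tgt - CtT,ref) - (CtN,tgt - CtN,ref))."""
    for v in (ct_target_tumor, ct_ref_tumor, ct_target_normal, ct_ref_normal):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_tumor - ct_ref_tumor) - (ct_target_normal - ct_ref_normal)
    return 2.0 ** (-ddct)


def fit_standard_curves(ct_table: pd.DataFrame) -> Dict[str, StandardCurve]:
    """Fit one standard curve per assay from rows with role == 'standard'."""
    std = ct_table[ct_table["role"] == "standard"]
    curves: Dict[str, StandardCurve] = {}
    for assay, grp in std.groupby("assay"):
        by_q = grp.groupby("input_ng")["ct"].apply(list)
        curves[assay] = fit_standard_curve(by_q.index.to_list(), by_q.to_list())
    return curves


def call_copy_numbers(
    ct_table: pd.DataFrame,
    cutoff: float = DEFAULT_RATIO_CUTOFF,
    references: Sequence[str] = REFERENCE_ASSAYS,
) -> pd.DataFrame:
    """Full qPCR workflow on a tidy Ct table.

    Expects columns sample/assay/role/input_ng/replicate/ct, where role is
    'standard', 'target' or 'reference' and tumor/normal status is encoded
    in the sample name suffix '_T' / '_N'.  Replicate Cts are averaged per
    (sample, assay, input level) before quantification; quantities are
    normalized per reference and level, then averaged.  Also reports the
    2^-ddCt comparator computed from mean Cts averaged over references.
    """
    curves = fit_standard_curves(ct_table)
    unknowns = ct_table[ct_table["role"] != "standard"]
    mean_ct = (
        unknowns.groupby(["sample", "assay", "input_ng"])["ct"].mean().reset_index()
    )
    mean_ct["quantity"] = [
        quantify(row.ct, curves[row.assay]) for row in mean_ct.itertuples()
    ]

    targets = sorted(unknowns.loc[unknowns["role"] == "target", "assay"].unique())
    pairs = sorted(
        {s[:-2] for s in unknowns["sample"].unique() if s.endswith(("_T", "_N"))}
    )
    rows = []
    for target in targets:
        for pair in pairs:
            sub = mean_ct[mean_ct["sample"].isin([f"{pair}_T", f"{pair}_N"])]
            if sub[sub["assay"] == target].empty:
                continue
            levels = sorted(sub.loc[sub["assay"] == target, "input_ng"].unique())

            def q(sample: str, assay: str) -> np.ndarray:
                sel = sub[(sub["sample"] == sample) & (sub["assay"] == assay)]
                sel = sel.set_index("input_ng").loc[levels]
                return sel["quantity"].to_numpy()

            def c(sample: str, assay: str) -> np.ndarray:
                sel = sub[(sub["sample"] == sample) & (sub["assay"] == assay)]
                sel = sel.set_index("input_ng").loc[levels]
                return sel["ct"].to_numpy()

            result = copy_ratio(
                q(f"{pair}_T", target),
                q(f"{pair}_N", target),
                {r: q(f"{pair}_T", r) for r in references},
                {r: q(f"{pair}_N", r) for r in references},
                cutoff=cutoff,
                target=target,
                sample=pair,
            )
            ddct = float(
                np.mean(
                    [
                        ddct_ratio(ctt, crt, ctn, crn)
                        for r in references
                        for ctt, crt, ctn, crn in zip(
                            c(f"{pair}_T", target), c(f"{pair}_T", r),
                            c(f"{pair}_N", target), c(f"{pair}_N", r),
                        )
                    ]
                )
            )
            row = {
                "target": target,
                "sample": pair,
                "mean_ratio": result.mean_ratio,
                "ddct_ratio": ddct,
                "classification": result.classification,
                "references_concur": result.references_concur,
            }
            for ref, ratio in result.per_reference.items():
                row[f"ratio_{ref}"] = ratio
            rows.append(row)
    return pd.DataFrame(rows)
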