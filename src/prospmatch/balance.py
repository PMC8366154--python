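"""Standardized mean difference (SMD) balance diagnostics.

The SMD for a continuous covariate is the between-group mean difference
divided by the unweighted pooled standard deviation,

    SMD = (mean2 - mean1) / sqrt((sd1^2 + sd2^2) / 2),

with group 1 the treated arm; for a binary covariate the variances are
p(1-p).  |SMD| < 0.2 is the conventional balance threshold, insensitive to
sample size.  A dyad-adjusted (paired) variant is available for aligned
matched samples.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, UndefinedSMDError

#: |SMD| at or above this is flagged as imbalanced
BALANCE_THRESHOLD = 0.2


def smd_continuous(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """SMD for a continuous covariate from per-group means and SDs."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    denom = math.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    if denom == 0.0:
        if mean1 == mean2:
            return 0.0
        raise UndefinedSMDError("both SDs are zero with unequal means")
    return (mean2 - mean1) / denom


def smd_binary(p1: float, p2: float) -> float:
    """SMD for a binary covariate from per-group proportions."""
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    if p1 == p2:
        return 0.0
    denom = math.sqrt((p1 * (1.0 - p1) + p2 * (1.0 - p2)) / 2.0)
    if denom == 0.0:
        raise UndefinedSMDError("degenerate proportions with unequal values")
    return (p2 - p1) / denom


def smd_paired_continuous(x1: np.ndarray, x2: np.ndarray) -> float:
    """Dyad-adjusted SMD: mean within-pair difference over the SD of
    differences. Requires aligned samples of equal length."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("paired SMD requires aligned samples of equal length")
    d = x2 - x1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0
        raise UndefinedSMDError("zero variance of paired differences with "
                                "nonzero mean difference")
    return float(d.mean() / sd)


def _to_frame(group) -> pd.DataFrame:
    if isinstance(group, pd.DataFrame):
        df = group.copy()
    else:
        from .cohort import patients_to_frame
        df = patients_to_frame(group)
    if "race" in df.columns:
        # per-category indicator rows, Table-1 style
        for cat in df["race"].dropna().unique():
            col = f"race_{cat}"
            if col not in df.columns:
                df[col] = (df["race"] == cat).astype(float)
    return df


def balance_table(group1, group2,
                  covariates: Sequence[tuple[str, str]],
                  paired: bool = False) -> pd.DataFrame:
    """Table-1-style balance report.

    Parameters
    ----------
    group1, group2
        Treated and control samples: DataFrames or sequences of
        ``PatientRecord``. For ``paired=True`` the rows must be aligned
        dyad-wise.
    covariates
        ``(name, kind)`` pairs with kind ``"continuous"`` or ``"binary"``.
    paired
        Use the dyad-adjusted SMD for continuous covariates.

    Summaries use non-missing values per group (pairwise-complete); rows
    whose SMD is undefined carry NaN and a warning flag.
    """
    g1, g2 = _to_frame(group1), _to_frame(group2)
    if len(g1) == 0 or len(g2) == 0:
        raise DegenerateInputError("both groups must be nonempty")
    rows = []
    for name, kind in covariates:
        if name not in g1.columns or name not in g2.columns:
            if name.startswith("race_"):  # category absent from both groups
                g1[name] = g1.get(name, 0.0)
                g2[name] = g2.get(name, 0.0)
            else:
                raise KeyError(f"covariate {name!r} not present in both groups")
        x1 = pd.to_numeric(g1[name], errors="coerce")
        x2 = pd.to_numeric(g2[name], errors="coerce")
        n_miss1, n_miss2 = int(x1.isna().sum()), int(x2.isna().sum())
        v1, v2 = x1.dropna(), x2.dropna()
        warning = False
        if len(v1) == 0 or len(v2) == 0:
            smd = float("nan")
            warning = True
            s1 = s2 = (float("nan"), float("nan"))
        elif kind == "binary":
            p1, p2 = float(v1.mean()), float(v2.mean())
            s1, s2 = (int(v1.sum()), p1), (int(v2.sum()), p2)
            try:
                smd = smd_binary(p1, p2)
            except UndefinedSMDError:
                smd, warning = float("nan"), True
        elif kind == "continuous":
            m1, sd1 = float(v1.mean()), float(v1.std(ddof=1)) if len(v1) > 1 else 0.0
            m2, sd2 = float(v2.mean()), float(v2.std(ddof=1)) if len(v2) > 1 else 0.0
            s1, s2 = (m1, sd1), (m2, sd2)
            try:
                if paired and not x1.isna().any() and not x2.isna().any() \
                        and len(x1) == len(x2):
                    smd = smd_paired_continuous(x1.to_numpy(), x2.to_numpy())
                else:
                    smd = smd_continuous(m1, sd1, m2, sd2)
            except UndefinedSMDError:
                smd, warning = float("nan"), True
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")
        rows.append({
            "covariate": name, "kind": kind,
            "group1_stat": s1[0], "group1_spread": s1[1],
            "group2_stat": s2[0], "group2_spread": s2[1],
            "smd": smd,
            "n_missing_group1": n_miss1, "n_missing_group2": n_miss2,
            "imbalanced": bool(abs(smd) >= BALANCE_THRESHOLD) if math.isfinite(smd)
                          else True,
            "warning": warning,
        })
    return pd.DataFrame(rows)


def render_balance_table(table: pd.DataFrame,
                         group1_name: str = "treated",
                         group2_name: str = "control") -> str:
    """Plain-text rendering with SMDs to 2 decimals."""
    lines = [f"{'Covariate':<22}{group1_name:>18}{group2_name:>18}{'SMD':>8}  flag",
             "-" * 72]
    for r in table.itertuples(index=False):
        if r.kind == "binary":
            c1 = f"{r.group1_stat} ({100 * r.group1_spread:.1f}%)"
            c2 = f"{r.group2_stat} ({100 * r.group2_spread:.1f}%)"
        else:
            c1 = f"{r.group1_stat:.1f} ({r.group1_spread:.1f})"
            c2 = f"{r.group2_stat:.1f} ({r.group2_spread:.1f})"
        smd = f"{r.smd:.2f}" if math.isfinite(r.smd) else "NA"
        flag = "*" if r.imbalanced else ""
        lines.append(f"{r.covariate:<22}{c1:>18}{c2:>18}{smd:>8}  {flag}")
    return "\n".join(lines)
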