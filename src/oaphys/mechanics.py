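"""Vickers microindentation hardness, indentation fracture toughness, and the
group-comparison statistics used for shell micromechanics.

Hardness follows the Vickers definition

    VHN = 1.8544 · F / d²        (F in kgf, d = mean indent diagonal in mm)

and fracture toughness the Anstis-type indentation relation

    K_c = 0.0154 · (E/H)^0.5 · P / C^1.5

with E and H in consistent units (GPa here), P the applied load in N and C
the crack radius converted from μm to m, giving K_c in MPa·m^0.5 after
scaling.  The elastic modulus default of 73 GPa is the empirical value for
*Crassostrea gigas* foliated shell.

Group statistics: Tukey-fence outlier removal (1.5·IQR beyond the quartiles),
one-way fixed-effects ANOVA with Tukey HSD post hoc for homoscedastic data,
and Welch's heteroscedastic ANOVA with Games-Howell post hoc otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GRAVITY",
    "KGF_MM2_TO_GPA",
    "vickers_hardness",
    "vhn_to_gpa",
    "fracture_toughness",
    "iqr_outlier_filter",
    "one_way_anova",
    "welch_anova",
    "tukey_hsd",
    "games_howell",
    "analyze_indents",
    "AnovaResult",
]

GRAVITY = 9.80665            # m/s², N per kgf
KGF_MM2_TO_GPA = GRAVITY * 1e-3  # 1 kgf/mm² = 9.80665 MPa


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    df_between: float
    df_within: float
    p_value: float


def vickers_hardness(load_n: float, diag1_um: float, diag2_um: float) -> float:
    """Vickers hardness number (kgf/mm²) from load (N) and diagonals (μm)."""
    if load_n <= 0:
        raise ValueError("load must be positive")
    if diag1_um <= 0 or diag2_um <= 0:
        raise ValueError("diagonals must be positive")
    f_kgf = load_n / GRAVITY
    d_mm = 0.5 * (diag1_um + diag2_um) * 1e-3
    return 1.8544 * f_kgf / d_mm**2


def vhn_to_gpa(vhn: float) -> float:
    """Convert Vickers hardness (kgf/mm²) to H in GPa."""
    return vhn * KGF_MM2_TO_GPA


def fracture_toughness(
    e_gpa: float, hardness_gpa: float, load_n: float, crack_um: float
) -> float:
    """Indentation fracture toughness K_c in MPa·m^0.5."""
    if min(e_gpa, hardness_gpa, load_n) <= 0:
        raise ValueError("modulus, hardness and load must be positive")
    if crack_um <= 0:
        raise ValueError("crack radius must be positive")
    c_m = crack_um * 1e-6
    kc_pa = 0.0154 * np.sqrt(e_gpa / hardness_gpa) * load_n / c_m**1.5
    return kc_pa / 1e6


def iqr_outlier_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Remove values beyond the Tukey fences Q1 − 1.5·IQR and Q3 + 1.5·IQR.

    Quartiles use linear interpolation between order statistics.  With fewer
    than 4 values the filter is skipped with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn("fewer than 4 values; outlier filter skipped", stacklevel=2)
        return v, np.array([])
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


def _check_groups(groups, min_size: int = 2) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(gs):
        if g.size < min_size:
            raise ValueError(f"group {i} has fewer than {min_size} values")
    return gs


def one_way_anova(groups) -> AnovaResult:
    """Classic fixed-effects one-way ANOVA."""
    gs = _check_groups(groups)
    k = len(gs)
    n = sum(g.size for g in gs)
    if np.concatenate(gs).std() == 0:
        return AnovaResult(0.0, k - 1, n - k, 1.0)
    res = stats.f_oneway(*gs)
    return AnovaResult(float(res.statistic), k - 1, n - k, float(res.pvalue))


def welch_anova(groups) -> AnovaResult:
    """Welch's heteroscedastic one-way ANOVA (Satterthwaite-type df)."""
    gs = _check_groups(groups)
    k = len(gs)
    if np.concatenate(gs).std() == 0:
        return AnovaResult(0.0, k - 1, np.inf, 1.0)
    n = np.array([g.size for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    var = np.array([g.var(ddof=1) for g in gs])
    if (var == 0).any():
        raise ValueError("Welch ANOVA undefined for zero-variance groups")
    w = n / var
    mw = (w * m).sum() / w.sum()
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = ((1.0 - w / w.sum()) ** 2 / (n - 1)).sum()
    f = a / (1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam)
    df1 = k - 1
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return AnovaResult(float(f), df1, float(df2), p)


def tukey_hsd(groups, labels=None) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons on a pooled variance estimate.

    Returns a DataFrame with one row per pair: group labels, mean difference,
    and the studentized-range adjusted p-value.
    """
    gs = _check_groups(groups)
    if labels is None:
        labels = list(range(len(gs)))
    res = stats.tukey_hsd(*gs)
    rows = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": gs[j].mean() - gs[i].mean(),
                    "p_value": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def games_howell(groups, labels=None) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (per-pair Welch variance and df).

    For each pair the statistic q = |m_i − m_j| / sqrt((v_i/n_i + v_j/n_j)/2)
    is referred to the studentized-range distribution with k groups and
    Welch-Satterthwaite degrees of freedom.  Groups with fewer than 2 values
    are excluded with a warning.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = list(range(len(gs)))
    usable = [(lab, g) for lab, g in zip(labels, gs) if g.size >= 2]
    if len(usable) < len(gs):
        dropped = [lab for lab, g in zip(labels, gs) if g.size < 2]
        warnings.warn(f"groups excluded from Games-Howell (n < 2): {dropped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least two groups with n ≥ 2")
    k = len(usable)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            la, a = usable[i]
            lb, b = usable[j]
            va, vb = a.var(ddof=1), b.var(ddof=1)
            na, nb = a.size, b.size
            se2 = va / na + vb / nb
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            diff = b.mean() - a.mean()
            if se2 == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / np.sqrt(se2 / 2.0)
                p = float(stats.studentized_range.sf(q, k, df))
            rows.append(
                {"group_a": la, "group_b": lb, "mean_diff": diff, "df": df, "p_value": min(p, 1.0)}
            )
    return pd.DataFrame(rows)


def analyze_indents(
    indents: pd.DataFrame, e_gpa: float = 73.0, outlier_filter: bool = True
) -> dict:
    """Per-shell micromechanics and between-treatment statistics.

    ``indents`` columns: shell_id, treatment, load_n, diag1_um, diag2_um,
    crack_um.  Per indent, VHN and K_c are computed; per shell they are
    averaged; per treatment the shell means pass through the 1.5·IQR outlier
    filter before one-way/Welch ANOVA and both post hoc procedures.

    Returns a dict with ``per_indent``, ``per_shell`` DataFrames and a
    ``stats`` sub-dict per property (anova, welch, tukey, games_howell).
    """
    required = {"shell_id", "treatment", "load_n", "diag1_um", "diag2_um", "crack_um"}
    missing = required - set(indents.columns)
    if missing:
        raise ValueError(f"indent table missing columns: {sorted(missing)}")
    per_indent = indents.copy()
    per_indent["vhn"] = [
        vickers_hardness(r.load_n, r.diag1_um, r.diag2_um)
        for r in indents.itertuples(index=False)
    ]
    per_indent["hardness_gpa"] = per_indent["vhn"] * KGF_MM2_TO_GPA
    per_indent["kc"] = [
        fracture_toughness(e_gpa, h, r.load_n, r.crack_um)
        for h, r in zip(per_indent["hardness_gpa"], indents.itertuples(index=False))
    ]
    per_shell = (
        per_indent.groupby(["treatment", "shell_id"], sort=True)[["vhn", "hardness_gpa", "kc"]]
        .mean()
        .reset_index()
    )
    results: dict = {"per_indent": per_indent, "per_shell": per_shell, "stats": {}}
    treatments = sorted(per_shell["treatment"].unique())
    for prop in ("vhn", "kc"):
        groups = []
        for t in treatments:
            vals = per_shell.loc[per_shell["treatment"] == t, prop].to_numpy()
            if outlier_filter:
                vals, _ = iqr_outlier_filter(vals)
            groups.append(vals)
        entry = {"treatments": treatments, "groups": groups}
        if len(treatments) >= 2 and all(len(g) >= 2 for g in groups):
            entry["anova"] = one_way_anova(groups)
            try:
                entry["welch"] = welch_anova(groups)
            except ValueError:
                entry["welch"] = None
            entry["tukey"] = tukey_hsd(groups, labels=treatments)
            entry["games_howell"] = games_howell(groups, labels=treatments)
        results["stats"][prop] = entry
    return results
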