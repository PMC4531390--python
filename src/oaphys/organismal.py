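"""Whole-organism metrics: buoyant-weight growth, glycogen assay math, and
fatty-acid community analysis (Bray-Curtis + ANOSIM).

Relative growth rate of shell mass is computed on cohort means of
log-transformed buoyant weights, so it is invariant to rescaling all masses.
Fatty-acid peak areas are normalized to within-sample proportions, optionally
log-shifted, turned into a Bray-Curtis dissimilarity matrix, and compared
between treatments with the rank-based ANOSIM permutation test.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "relative_growth_rate",
    "factorial_anova",
    "glycogen_concentration",
    "normalize_fatty_acids",
    "bray_curtis_matrix",
    "anosim",
]


def relative_growth_rate(start_masses, end_masses, days: float = 29.0) -> float:
    """Cohort relative growth rate per day.

    (mean ln(end mass) − mean ln(start mass)) / days; masses in grams (any
    consistent unit — the log-difference cancels scale).
    """
    start = np.asarray(start_masses, dtype=float)
    end = np.asarray(end_masses, dtype=float)
    if start.size == 0 or end.size == 0:
        raise ValueError("mass samples must be non-empty")
    if (start <= 0).any() or (end <= 0).any():
        raise ValueError("masses must be positive")
    return float((np.log(end).mean() - np.log(start).mean()) / days)


def factorial_anova(
    values, factor_a, factor_b, with_interaction: bool = True
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (Type II sums of squares).

    Used for the time × pCO2 model on buoyant weight.  Returns the statsmodels
    ANOVA table with F and PR(>F) per term.  Every cell of the two-factor
    cross must be populated.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "a": np.asarray(factor_a, dtype=object),
                       "b": np.asarray(factor_b, dtype=object)})
    for name in ("a", "b"):
        if df[name].nunique() < 2:
            raise ValueError(f"factor {name!r} needs at least 2 levels")
    cells = df.groupby(["a", "b"], sort=True).size()
    full = pd.MultiIndex.from_product([df["a"].unique(), df["b"].unique()])
    empty = full.difference(cells.index)
    if len(empty):
        raise ValueError(f"empty design cells: {list(empty)}")
    formula = "value ~ C(a) * C(b)" if with_interaction else "value ~ C(a) + C(b)"
    model = smf.ols(formula, data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def glycogen_concentration(
    absorbances,
    blank: float,
    slope: float,
    intercept: float,
    dilution_factor: float,
    tissue_mass_mg: float,
    extract_volume_ul: float = 200.0,
    well_volume_ul: float = 50.0,
) -> tuple[float, float, bool]:
    """Glycogen content (μg glycogen per mg tissue) from triplicate A570 readings.

    Each absorbance is blank-corrected and converted to μg glycogen in the
    assay well through the linear standard curve ``A = slope·μg + intercept``;
    the well amount is scaled to a concentration, multiplied by the dilution
    factor and the extract volume, and divided by the extracted tissue mass.
    Negative corrected responses are clipped to zero with a warning.

    Returns (mean μg/mg, coefficient of variation of the triplicates,
    qc_pass = cv < 0.20).
    """
    if dilution_factor <= 0 or tissue_mass_mg <= 0:
        raise ValueError("dilution factor and tissue mass must be positive")
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    a = np.asarray(absorbances, dtype=float)
    if a.size == 0:
        raise ValueError("no absorbance readings")
    resp = a - blank - intercept
    if (resp < 0).any():
        warnings.warn("negative blank-corrected absorbance clipped to 0", stacklevel=2)
        resp = np.clip(resp, 0.0, None)
    ug_per_well = resp / slope
    ug_per_ul = ug_per_well / well_volume_ul
    ug_per_mg = ug_per_ul * dilution_factor * extract_volume_ul / tissue_mass_mg
    mean = float(ug_per_mg.mean())
    cv = float(ug_per_mg.std(ddof=1) / mean) if (a.size > 1 and mean > 0) else 0.0
    return mean, cv, cv < 0.20


def normalize_fatty_acids(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions: each peak area over the sample's total area.

    ``profiles`` is samples × fatty-acid peaks (non-negative areas); rows
    with zero total raise.
    """
    arr = profiles.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("peak areas must be non-negative")
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        bad = profiles.index[totals == 0].tolist()
        raise ValueError(f"samples with all-zero profiles: {bad}")
    return profiles.div(profiles.sum(axis=1), axis=0)


def bray_curtis_matrix(profiles: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between fatty-acid profiles.

    Peak areas are normalized to proportions first; with ``log_transform``
    the proportions are shifted by log(x + c), c = half the smallest nonzero
    proportion (zeros are otherwise undefined under the log).  BC(x, y) =
    Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on the (transformed) compositions.
    """
    props = normalize_fatty_acids(profiles)
    x = props.to_numpy(dtype=float)
    if log_transform:
        nz = x[x > 0]
        c = 0.5 * nz.min()
        x = np.log(x + c)
        x = x - x.min()  # shift to non-negative so BC stays in [0, 1]
    n = x.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        tot = (x[i] + x[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / tot, 0.0)
        dm[i, i + 1:] = d
        dm[i + 1:, i] = d
    return pd.DataFrame(dm, index=profiles.index, columns=profiles.index)


def _anosim_r(ranks: np.ndarray, within: np.ndarray, m: int) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(
    dissimilarity: pd.DataFrame | np.ndarray,
    group_labels,
    n_permutations: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> tuple[float, float]:
    """Analysis of similarities: rank-based permutation test on a distance matrix.

    R = (mean between-group rank − mean within-group rank) / (M/4) with
    M = n(n−1)/2 pairwise distances ranked with midranks for ties; R ∈ [−1, 1].
    The p-value permutes group labels, counting permutations with R at least
    the observed value; sampled permutations use
    p = (1 + #{R_perm ≥ R_obs}) / (1 + n_permutations), while ``exact``
    enumerates every label ordering (n! ≤ 5040) and reports the exhaustive
    fraction.
    """
    dm = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(group_labels)
    n = dm.shape[0]
    if dm.shape != (n, n):
        raise ValueError("dissimilarity must be square")
    if labels.size != n:
        raise ValueError("one label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")

    condensed = squareform(dm, checks=False)
    ranks = rankdata(condensed)  # midranks for ties
    m = condensed.size
    iu = np.triu_indices(n, k=1)

    def r_for(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return _anosim_r(ranks, within, m)

    r_obs = r_for(labels)

    if exact:
        if n > 7:
            raise ValueError("exact enumeration limited to n ≤ 7 samples")
        count = 0
        total = 0
        for perm in _permutations(range(n)):
            total += 1
            if r_for(labels[list(perm)]) >= r_obs - 1e-12:
                count += 1
        return float(r_obs), count / total

    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if r_for(lab) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return float(r_obs), float(p)
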