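"""Differential protein abundance between treatment groups of NSAF profiles.

For a pairwise treatment contrast the per-protein quantities are:

* fold change — ratio of group-mean NSAF (comparison group over reference);
  a protein detected in only one of the two groups carries an ``up`` /
  ``down`` exclusive flag instead of a finite ratio;
* two-sample t-test p-value, computed only for proteins expressed in every
  oyster of both groups (spectral-count abundances of partially detected
  proteins are not exchangeable enough for the test);
* Storey positive-FDR q-value with the smoother π₀ estimate;
* the differential-abundance (DA) verdict:  ≥2-fold change with detection in
  more than one oyster, OR q < 0.10 among fully expressed proteins, OR
  exclusive detection in one treatment.  Changes beyond 5-fold carry an
  extra flag.

Annotation handling is limited to parsing precomputed BLAST tabular output
and keeping each query's best hit at or below an e-value ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .proteomics import InjectionDesign, NsafMatrix

__all__ = [
    "ComparisonSpec",
    "fold_changes",
    "protein_tests",
    "storey_pi0",
    "storey_qvalues",
    "classify_differential",
    "compare",
    "run_comparisons",
    "abundance_table",
    "overlap_analysis",
    "filter_annotations",
    "BLAST_OUTFMT6_COLUMNS",
]

BLAST_OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """A pairwise contrast: fold changes are group_b relative to group_a."""

    name: str
    group_a: str  # reference treatment label
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("comparison groups must differ")


def _group_values(nsaf: NsafMatrix, design: InjectionDesign, treatment: str) -> pd.DataFrame:
    oysters = design.oysters_in(treatment)
    if not oysters:
        raise ValueError(f"no oysters with treatment {treatment!r} in design")
    return nsaf.values[oysters]


def fold_changes(nsaf: NsafMatrix, design: InjectionDesign, spec: ComparisonSpec) -> pd.DataFrame:
    """Per-protein group means, b/a fold change, detection counts, exclusivity.

    Returns a DataFrame indexed by protein with columns ``mean_nsaf_a``,
    ``mean_nsaf_b``, ``fold_change`` (NaN when the reference mean is zero),
    ``n_detected_a``, ``n_detected_b`` (oysters where the expression mask is
    true), and ``exclusive`` ∈ {None, 'a', 'b'} for proteins detected in only
    one of the two groups.
    """
    a = _group_values(nsaf, design, spec.group_a)
    b = _group_values(nsaf, design, spec.group_b)
    mask_a = nsaf.mask[a.columns]
    mask_b = nsaf.mask[b.columns]
    n_a = mask_a.sum(axis=1)
    n_b = mask_b.sum(axis=1)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_b / mean_a
    fold = fold.where(mean_a > 0, np.nan)
    exclusive = pd.Series(None, index=fold.index, dtype=object)
    exclusive[(n_b > 0) & (n_a == 0)] = "b"
    exclusive[(n_a > 0) & (n_b == 0)] = "a"
    return pd.DataFrame(
        {
            "mean_nsaf_a": mean_a,
            "mean_nsaf_b": mean_b,
            "fold_change": fold,
            "n_detected_a": n_a,
            "n_detected_b": n_b,
            "exclusive": exclusive,
        }
    )


def protein_tests(
    nsaf: NsafMatrix,
    design: InjectionDesign,
    spec: ComparisonSpec,
    equal_var: bool = True,
) -> pd.Series:
    """Two-sided two-sample t-test p per protein expressed in all oysters of both groups.

    Proteins failing the all-expressed eligibility carry NaN.  Zero variance
    in both groups with equal means gives p = 1 by convention; p-values are
    clamped to [1e-300, 1].
    """
    a = _group_values(nsaf, design, spec.group_a)
    b = _group_values(nsaf, design, spec.group_b)
    eligible = nsaf.mask[a.columns].all(axis=1) & nsaf.mask[b.columns].all(axis=1)
    p = pd.Series(np.nan, index=nsaf.values.index, name="p_value")
    if eligible.any():
        av = a.loc[eligible].to_numpy(float)
        bv = b.loc[eligible].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(av, bv, axis=1, equal_var=equal_var)
        pv = np.asarray(res.pvalue, dtype=float)
        degenerate = (av.std(axis=1) == 0) & (bv.std(axis=1) == 0)
        same_mean = degenerate & np.isclose(av.mean(axis=1), bv.mean(axis=1))
        pv[same_mean] = 1.0
        pv[degenerate & ~same_mean] = 1e-300
        p.loc[eligible] = np.clip(pv, 1e-300, 1.0)
    return p


def storey_pi0(p_values: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoother estimate of π₀, the fraction of true null hypotheses.

    π₀(λ) = #{p > λ} / (m(1−λ)) is computed over λ ∈ {0, 0.05, …, 0.90}, a
    cubic polynomial is fitted to π₀(λ) against λ and evaluated at the
    largest λ; the result is clipped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.0, 0.9001, 0.05)
    m = p.size
    if m == 0:
        raise ValueError("no p-values")
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if m < 20:  # too few points for the smoother to be meaningful
        return 1.0
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(p_values, pi0: float | None = None) -> np.ndarray | pd.Series:
    """Storey q-values (positive FDR) for a vector of p-values.

    q_(i) = min_{j ≥ i} π₀ m p_(j) / j over the p-values sorted ascending.
    With ``pi0=1`` this reduces exactly to Benjamini–Hochberg adjusted
    p-values.  NaNs pass through untouched (ineligible tests).
    """
    series = isinstance(p_values, pd.Series)
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if pv.size:
        if ((pv < 0) | (pv > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        if pi0 is None:
            pi0 = storey_pi0(pv)
        m = pv.size
        order = np.argsort(pv, kind="mergesort")
        ranked = pi0 * pv[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.clip(q, 0.0, 1.0)
        out[valid] = qv
    if series:
        return pd.Series(out, index=p_values.index, name="q_value")
    return out


def classify_differential(
    folds: pd.DataFrame,
    qvalues: pd.Series,
    fold_threshold: float = 2.0,
    q_threshold: float = 0.10,
    fivefold: float = 5.0,
) -> pd.DataFrame:
    """Apply the differential-abundance decision rule to one comparison.

    DA iff any of:

    * ``fold`` — |log2 fold| ≥ log2(fold_threshold) (inclusive) and the
      protein was detected in more than one oyster across the two groups;
    * ``q`` — q < q_threshold, which by construction is only available for
      proteins expressed in all oysters of both groups;
    * ``exclusive`` — detected in exactly one of the two treatments.

    ``direction`` is 'up'/'down' in the comparison group; ``fivefold_flag``
    marks changes beyond ``fivefold`` in either direction.
    """
    fold = folds["fold_change"]
    n_total = folds["n_detected_a"] + folds["n_detected_b"]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2f = np.log2(fold.to_numpy(float))
    abs_log2 = pd.Series(np.abs(log2f), index=folds.index)

    fold_eligible = n_total > 1
    da_fold = fold_eligible & (abs_log2 >= np.log2(fold_threshold)) & fold.notna() & (fold > 0)
    da_q = qvalues.notna() & (qvalues < q_threshold)
    da_exclusive = folds["exclusive"].notna()
    da = da_fold | da_q | da_exclusive

    direction = pd.Series(None, index=folds.index, dtype=object)
    direction[da & (fold > 1)] = "up"
    direction[da & (fold < 1)] = "down"
    direction[folds["exclusive"] == "b"] = "up"
    direction[folds["exclusive"] == "a"] = "down"

    with np.errstate(divide="ignore", invalid="ignore"):
        five = (fold > fivefold) | (fold < 1.0 / fivefold)
    fivefold_flag = five.fillna(False)

    out = folds.copy()
    out["q_value"] = qvalues
    out["da_flag"] = da
    out["da_fold"] = da_fold
    out["da_q"] = da_q
    out["da_exclusive"] = da_exclusive
    out["direction"] = direction
    out["fivefold_flag"] = fivefold_flag
    return out


def compare(
    nsaf: NsafMatrix,
    design: InjectionDesign,
    spec: ComparisonSpec,
    equal_var: bool = True,
    fold_threshold: float = 2.0,
    q_threshold: float = 0.10,
) -> pd.DataFrame:
    """Fold changes + tests + q-values + DA classification for one contrast."""
    folds = fold_changes(nsaf, design, spec)
    p = protein_tests(nsaf, design, spec, equal_var=equal_var)
    q = storey_qvalues(p)
    out = classify_differential(folds, q, fold_threshold=fold_threshold, q_threshold=q_threshold)
    out.insert(0, "comparison", spec.name)
    out["p_value"] = p
    return out


def run_comparisons(
    nsaf: NsafMatrix, design: InjectionDesign, specs: list[ComparisonSpec], **kwargs
) -> dict[str, pd.DataFrame]:
    return {spec.name: compare(nsaf, design, spec, **kwargs) for spec in specs}


def abundance_table(
    nsaf: NsafMatrix,
    design: InjectionDesign,
    comparisons: dict[str, pd.DataFrame],
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-protein report table.

    One row per retained protein: per-oyster NSAF columns (``nsaf_<oyster>``),
    per-treatment means (``avg_nsaf_<treatment>``), then per comparison the
    fold change (``up``/``down`` for exclusive detections), five-fold marker
    (``*``), q-value and DA flag/direction, and finally the best BLAST
    annotation (accession, e-value, description) where available.
    """
    out = nsaf.values.copy()
    out.columns = [f"nsaf_{o}" for o in out.columns]
    trt = design.oyster_to_treatment()
    for treatment in trt.unique():
        cols = [f"nsaf_{o}" for o in design.oysters_in(treatment)]
        out[f"avg_nsaf_{treatment}"] = out[cols].mean(axis=1)
    for name, cmp_df in comparisons.items():
        fold = cmp_df["fold_change"].map(lambda v: f"{v:.4g}" if pd.notna(v) else "")
        fold = fold.where(cmp_df["exclusive"].isna(), cmp_df["exclusive"].map({"b": "up", "a": "down"}))
        out[f"fold_{name}"] = fold
        out[f"fivefold_{name}"] = np.where(cmp_df["fivefold_flag"], "*", "")
        out[f"qvalue_{name}"] = cmp_df["q_value"]
        out[f"da_{name}"] = cmp_df["da_flag"]
        out[f"direction_{name}"] = cmp_df["direction"].fillna("")
    if annotations is not None:
        ann = annotations.set_index("protein_id")[["accession", "evalue", "description"]]
        out = out.join(ann, how="left")
    else:
        out["accession"] = ""
        out["evalue"] = np.nan
        out["description"] = ""
    out.index.name = "protein_id"
    return out


def overlap_analysis(da_results: dict[str, pd.DataFrame]) -> dict:
    """Three-set Venn region counts and pairwise direction concordance.

    ``da_results`` maps comparison names to classified tables (``da_flag``,
    ``direction`` columns).  Returns region counts keyed by membership tuples
    (e.g. ``('OA',)``, ``('OA', 'MechS-400')``) plus ``concordance`` — for
    each pair, the fraction of shared DA proteins whose direction agrees.
    """
    if len(da_results) != 3:
        raise ValueError("overlap_analysis expects exactly three comparisons")
    names = list(da_results)
    sets = {n: set(df.index[df["da_flag"]]) for n, df in da_results.items()}
    directions = {n: df["direction"] for n, df in da_results.items()}

    regions: dict[tuple, int] = {}
    union = set().union(*sets.values())
    for protein in union:
        membership = tuple(n for n in names if protein in sets[n])
        regions[membership] = regions.get(membership, 0) + 1
    for r in range(1, 4):
        for combo in combinations(names, r):
            regions.setdefault(combo, 0)

    concordance = {}
    for x, y in combinations(names, 2):
        shared = sets[x] & sets[y]
        if shared:
            same = sum(1 for pid in shared if directions[x][pid] == directions[y][pid])
            concordance[(x, y)] = same / len(shared)
        else:
            concordance[(x, y)] = np.nan
    return {"regions": regions, "union_size": len(union), "concordance": concordance}


def filter_annotations(blast: str | pd.DataFrame, max_evalue: float = 1e-10) -> pd.DataFrame:
    """Best BLAST hit per query with e-value ≤ max_evalue (inclusive).

    Accepts a path to BLAST tabular output (outfmt 6, 12 columns, optionally
    followed by a subject title column used as the description) or an
    equivalent DataFrame.  Ties on e-value break by higher bit score.
    """
    if isinstance(blast, pd.DataFrame):
        df = blast.copy()
    else:
        df = pd.read_csv(blast, sep="\t", header=None, dtype=str)
        if df.shape[1] < 12:
            raise ValueError(
                f"BLAST tabular file {blast} has {df.shape[1]} columns; expected ≥12 (outfmt 6)"
            )
        names = BLAST_OUTFMT6_COLUMNS + [f"extra{i}" for i in range(df.shape[1] - 12)]
        df.columns = names
        if "extra0" in df.columns:
            df = df.rename(columns={"extra0": "stitle"})
    df["evalue"] = pd.to_numeric(df["evalue"], errors="raise")
    df["bitscore"] = pd.to_numeric(df["bitscore"], errors="raise")
    kept = df[df["evalue"] <= max_evalue]
    best = (
        kept.sort_values(["qseqid", "evalue", "bitscore"], ascending=[True, True, False])
        .drop_duplicates("qseqid", keep="first")
    )
    return pd.DataFrame(
        {
            "protein_id": best["qseqid"].to_numpy(),
            "accession": best["sseqid"].to_numpy(),
            "evalue": best["evalue"].to_numpy(),
            "description": best["stitle"].to_numpy() if "stitle" in best.columns else "",
        }
    )
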