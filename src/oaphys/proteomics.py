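"""Label-free spectral-count quantification: PSM tables to NSAF matrices.

The chain mirrors the standard shotgun-proteomics spectral-counting workflow:

1. peptide-spectrum matches (PSMs) are filtered on their PeptideProphet-style
   posterior probability (default ≥ 0.9);
2. one retained PSM contributes one spectral count (SpC) to its
   (protein, injection) cell;
3. proteins with fewer than 8 spectral counts over the whole design are
   dropped as low-evidence identifications;
4. within each biological replicate (oyster), a protein needs ≥ 2 unique
   peptide sequences across the oyster's technical injections to count as
   expressed — otherwise its abundance is zeroed for that oyster;
5. NSAF (normalized spectral abundance factor): SpC averaged over the
   oyster's technical injections, divided by protein length L, then
   normalized by the within-oyster sum of SpC/L so each oyster's abundances
   sum to 1.

All tabular data are pandas objects; matrices are DataFrames indexed by
protein_id with injection or oyster columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "InjectionDesign",
    "SpectralCountMatrix",
    "NsafMatrix",
    "parse_psm_table",
    "filter_psms",
    "count_spectra",
    "filter_low_evidence_proteins",
    "expression_mask",
    "compute_nsaf",
    "read_protein_lengths",
    "nsaf_pipeline",
]

PSM_COLUMNS = ["peptide", "protein_id", "probability", "injection_id"]
DESIGN_COLUMNS = ["injection_id", "oyster_id", "treatment"]


@dataclass(frozen=True)
class InjectionDesign:
    """Mapping of technical injections to oysters and oysters to treatments."""

    table: pd.DataFrame  # columns: injection_id, oyster_id, treatment

    def __post_init__(self) -> None:
        missing = set(DESIGN_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table["injection_id"].duplicated().any():
            raise ValueError("duplicate injection_id in design")
        trt = self.table.groupby("oyster_id")["treatment"].nunique()
        if (trt > 1).any():
            bad = trt[trt > 1].index.tolist()
            raise ValueError(f"oysters assigned to multiple treatments: {bad}")
        counts = self.injections_per_oyster()
        if (counts != 3).any():
            off = counts[counts != 3]
            warnings.warn(
                f"expected 3 technical injections per oyster; got {off.to_dict()}",
                stacklevel=2,
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InjectionDesign":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @property
    def injections(self) -> pd.Index:
        return pd.Index(self.table["injection_id"])

    @property
    def oysters(self) -> pd.Index:
        return pd.Index(self.table["oyster_id"].unique())

    def injections_per_oyster(self) -> pd.Series:
        return self.table.groupby("oyster_id")["injection_id"].size()

    def injection_to_oyster(self) -> pd.Series:
        return self.table.set_index("injection_id")["oyster_id"]

    def oyster_to_treatment(self) -> pd.Series:
        return self.table.drop_duplicates("oyster_id").set_index("oyster_id")["treatment"]

    def oysters_in(self, treatment: str) -> list[str]:
        t = self.oyster_to_treatment()
        return t.index[t == treatment].tolist()


@dataclass
class SpectralCountMatrix:
    """Spectral counts by (protein, injection) with per-oyster unique peptides."""

    counts: pd.DataFrame            # protein_id × injection_id, int
    unique_peptides: pd.DataFrame   # protein_id × oyster_id, int
    design: InjectionDesign

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("spectral counts must be non-negative")

    @property
    def proteins(self) -> pd.Index:
        return self.counts.index

    def total_counts(self) -> pd.Series:
        """Grand total SpC per protein over all injections in the design."""
        return self.counts.sum(axis=1)


@dataclass
class NsafMatrix:
    """NSAF abundances by (protein, oyster) plus the expression mask applied."""

    values: pd.DataFrame  # protein_id × oyster_id, float, columns sum to 1
    mask: pd.DataFrame    # protein_id × oyster_id, bool
    lengths: pd.Series = field(repr=False)


def parse_psm_table(path: str | Path, design: InjectionDesign) -> pd.DataFrame:
    """Read a PSM TSV (peptide, protein_id, probability, injection_id).

    Malformed rows (non-numeric or out-of-range probability, empty peptide)
    are reported with 1-based data line numbers; injections absent from the
    design raise a design error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "protein_id": str, "injection_id": str})
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table {path} missing columns: {sorted(missing)}")
    prob = pd.to_numeric(df["probability"], errors="coerce")
    bad = df.index[prob.isna() | (prob < 0) | (prob > 1) | df["peptide"].isna() | (df["peptide"].astype(str).str.len() == 0)]
    if len(bad):
        lines = (bad + 1).tolist()[:10]
        raise ValueError(f"malformed PSM rows at data lines {lines} in {path}")
    df = df.assign(probability=prob)
    unknown = set(df["injection_id"]) - set(design.injections)
    if unknown:
        raise ValueError(f"PSM injections not in design: {sorted(unknown)[:10]}")
    return df[PSM_COLUMNS].copy()


def filter_psms(psms: pd.DataFrame, min_probability: float = 0.9) -> pd.DataFrame:
    """Retain PSMs with probability ≥ min_probability (inclusive)."""
    return psms[psms["probability"] >= min_probability].copy()


def count_spectra(psms: pd.DataFrame, design: InjectionDesign) -> SpectralCountMatrix:
    """Tabulate spectral counts per (protein, injection).

    Each PSM row is one spectral count.  Unique peptides are counted per
    (protein, oyster) as distinct peptide sequence strings pooled over the
    oyster's technical injections.
    """
    injections = design.injections
    counts = (
        psms.groupby(["protein_id", "injection_id"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=injections, fill_value=0)
    )
    counts.columns.name = "injection_id"
    inj_to_oyster = design.injection_to_oyster()
    with_oyster = psms.assign(oyster_id=psms["injection_id"].map(inj_to_oyster))
    uniq = (
        with_oyster.groupby(["protein_id", "oyster_id"], sort=True)["peptide"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(index=counts.index, columns=design.oysters, fill_value=0)
    )
    return SpectralCountMatrix(counts=counts.astype(int), unique_peptides=uniq.astype(int), design=design)


def filter_low_evidence_proteins(
    matrix: SpectralCountMatrix, min_total_spc: int = 8
) -> SpectralCountMatrix:
    """Drop proteins whose grand-total SpC is below the floor (retain at exactly 8)."""
    keep = matrix.total_counts() >= min_total_spc
    return SpectralCountMatrix(
        counts=matrix.counts.loc[keep],
        unique_peptides=matrix.unique_peptides.loc[keep],
        design=matrix.design,
    )


def expression_mask(matrix: SpectralCountMatrix, min_unique_peptides: int = 2) -> pd.DataFrame:
    """True where a protein has ≥ min_unique_peptides unique peptides in that oyster."""
    return matrix.unique_peptides >= min_unique_peptides


def read_protein_lengths(path: str | Path) -> pd.Series:
    """Protein lengths from FASTA (residue count) or a TSV (protein_id, length)."""
    path = Path(path)
    if path.suffix.lower() in {".fasta", ".fa", ".faa"}:
        lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        s = pd.Series(lengths, name="length")
    else:
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
        if not {"protein_id", "length"} <= set(df.columns):
            raise ValueError(f"protein length table {path} needs protein_id and length columns")
        s = df.set_index("protein_id")["length"]
    if (s <= 0).any():
        raise ValueError("protein lengths must be positive")
    return s.astype(float)


def compute_nsaf(
    matrix: SpectralCountMatrix,
    lengths: pd.Series,
    mask: pd.DataFrame | None = None,
) -> NsafMatrix:
    """NSAF per (protein, oyster).

    SpC is averaged over each oyster's technical injections, divided by the
    protein length, zeroed where the expression mask is false, and normalized
    so every oyster column sums to 1 over the retained proteins.
    """
    missing = matrix.proteins.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing protein lengths for {sorted(missing)[:10]}")
    if mask is None:
        mask = expression_mask(matrix)
    inj_to_oyster = matrix.design.injection_to_oyster()
    avg = matrix.counts.T.groupby(inj_to_oyster).mean().T  # protein × oyster
    avg = avg.reindex(columns=matrix.design.oysters)
    mask = mask.reindex(index=avg.index, columns=avg.columns, fill_value=False)
    saf = avg.div(lengths.loc[avg.index], axis=0)
    saf = saf.where(mask, 0.0)
    denom = saf.sum(axis=0)
    if (denom == 0).any():
        empty = denom.index[denom == 0].tolist()
        warnings.warn(f"oysters with no expressed proteins: {empty}", stacklevel=2)
        denom = denom.replace(0.0, np.nan)
    values = saf.div(denom, axis=1).fillna(0.0)
    return NsafMatrix(values=values, mask=mask, lengths=lengths.loc[avg.index])


def nsaf_pipeline(
    psms: pd.DataFrame,
    design: InjectionDesign,
    lengths: pd.Series,
    min_probability: float = 0.9,
    min_total_spc: int = 8,
    min_unique_peptides: int = 2,
) -> NsafMatrix:
    """Full chain: probability filter → counts → evidence floor → mask → NSAF."""
    kept = filter_psms(psms, min_probability)
    matrix = count_spectra(kept, design)
    matrix = filter_low_evidence_proteins(matrix, min_total_spc)
    mask = expression_mask(matrix, min_unique_peptides)
    return compute_nsaf(matrix, lengths, mask)
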