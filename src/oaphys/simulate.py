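"""Seeded synthetic datasets emulating the study designs, with ground truth.

Four generators cover the pipeline's input surfaces:

* ``simulate_psm_experiment`` — a 2-treatment × (± mechanical stress) shotgun
  proteomics design: 4 treatments × 4 oysters × 3 technical injections
  (48 injections).  Per (protein, oyster, injection) spectral counts are
  negative-binomial with mean = baseline abundance × protein length ×
  treatment fold effect × per-oyster biological factor; each count becomes a
  PSM row carrying a PeptideProphet-style probability drawn from a true-hit /
  decoy beta mixture so the 0.9 filter is informative.
* ``simulate_micromech`` — Vickers indents (7–8 per shell, 5–7 shells per
  treatment) with configurable between-treatment hardness offsets.
* ``simulate_profiles`` — 21-peak fatty-acid profiles (Dirichlet, optional
  group concentration shift) and glycogen assay plates with configurable CV.
* ``simulate_growth`` — start/end buoyant weights under per-treatment
  relative growth rates.

Every generator is deterministic for a fixed seed and emits a truth table
sufficient to score the downstream analysis (DA sensitivity/FPR, ANOVA and
ANOSIM error rates, growth-rate recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "reference_config",
    "simulate_psm_experiment",
    "simulate_micromech",
    "simulate_profiles",
    "simulate_growth",
]

_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generators.

    The defaults reproduce the study's scale: 4 treatments (400 and 2800 μatm,
    each with and without mechanical stress) × 4 oysters × 3 injections, and
    per-protein mean spectral counts of a few per injection so that the
    8-count evidence floor and 2-unique-peptide mask both bite.
    """

    seed: int
    n_proteins: int = 1000
    length_range: tuple[int, int] = (150, 600)
    treatments: tuple[str, ...] = ("400", "400-MechS", "2800", "2800-MechS")
    oysters_per_treatment: int = 4
    injections_per_oyster: int = 3
    # baseline per-residue abundance: counts mean = exp(N(mu, sigma)) * length
    baseline_log_mu: float = np.log(0.016)
    baseline_log_sigma: float = 1.0
    dispersion: float = 20.0          # negative-binomial size (technical)
    biological_cv: float = 0.3        # lognormal sd of per-oyster factors
    da_fraction: float = 0.10
    fold_effects: tuple[float, ...] = (2.0, 4.0)
    true_hit_beta: tuple[float, float] = (20.0, 1.0)
    decoy_beta: tuple[float, float] = (1.0, 8.0)
    decoy_fraction: float = 0.10
    peptides_per_protein_mean: float = 8.0
    # micromechanics
    mech_treatments: tuple[str, ...] = ("400", "1000", "2800")
    shells_per_treatment: tuple[int, int] = (5, 7)
    indents_per_shell: tuple[int, int] = (7, 8)
    vhn_mean: float = 240.0
    vhn_shell_sd: float = 25.0
    vhn_indent_sd: float = 20.0
    vhn_offsets: tuple[float, ...] = (0.0, -30.0, -20.0)
    crack_mean_um: float = 55.0
    crack_sd_um: float = 8.0
    crack_offsets_um: tuple[float, ...] = (0.0, 0.0, 8.0)
    indent_load_n: float = 0.245
    # profiles
    n_fatty_acids: int = 21
    profile_treatments: tuple[str, ...] = ("400", "800", "2800")
    samples_per_profile_treatment: tuple[int, ...] = (8, 7, 8)
    dirichlet_concentration: float = 40.0
    profile_shift: float = 0.0        # relative shift of concentrations per group
    glycogen_mean_ug_mg: float = 70.0
    glycogen_cv: float = 0.08
    glycogen_slope: float = 0.5       # absorbance per μg glycogen in well
    glycogen_intercept: float = 0.02
    glycogen_blank: float = 0.05
    dilution_factor: float = 30.0
    # growth
    growth_treatments: tuple[str, ...] = ("400", "800", "1000", "2800")
    oysters_per_growth_treatment: int = 24
    start_mass_g: float = 7.2
    start_mass_cv: float = 0.15
    growth_rates_per_day: tuple[float, ...] = (0.003, 0.003, 0.002, 0.002)
    growth_days: float = 29.0
    growth_noise_cv: float = 0.03

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be ≥ 1")
        if not 0.0 <= self.da_fraction <= 1.0:
            raise ValueError("da_fraction must lie in [0, 1]")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy_fraction must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def reference_config(seed: int = 0) -> SimulationConfig:
    """The documented reference proteomics simulation: 1000 proteins, 4 vs 4."""
    return SimulationConfig(seed=seed)


def _peptide(protein_idx: int, pep_idx: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(_AMINO, size=8))
    return f"{body}P{protein_idx}N{pep_idx}"  # suffix guarantees cross-protein uniqueness


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    # numpy's negative_binomial: n = size, p = size/(size+mean)
    mean = np.clip(mean, 1e-12, None)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_psm_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (psm_table, design_table, protein_table, truth_table).

    Truth holds one row per protein: its length, baseline abundance, the
    multiplicative effect applied in each non-reference treatment, the
    per-comparison true fold (b/a group mean ratio of generating means), and
    a boolean DA label per comparison.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=n)
    baseline = np.exp(rng.normal(config.baseline_log_mu, config.baseline_log_sigma, size=n))

    treatments = list(config.treatments)
    ref = treatments[0]
    # per-treatment multiplicative effects; reference treatment is 1
    effects = pd.DataFrame(1.0, index=range(n), columns=treatments)
    is_da = rng.random(n) < config.da_fraction
    for t in treatments[1:]:
        apply = is_da & (rng.random(n) < 0.5)
        if t == treatments[-1]:
            # guarantee every DA protein acts somewhere
            silent = is_da & (effects.loc[:, treatments[1:]].eq(1.0).all(axis=1))
            apply = apply | silent.to_numpy()
        mag = rng.choice(config.fold_effects, size=n)
        updown = np.where(rng.random(n) < 0.5, mag, 1.0 / mag)
        effects.loc[apply, t] = updown[apply]

    design_rows = []
    for t in treatments:
        for o in range(1, config.oysters_per_treatment + 1):
            oyster = f"{t}-{o}"
            for i in range(1, config.injections_per_oyster + 1):
                design_rows.append(
                    {"injection_id": f"{oyster}-inj{i}", "oyster_id": oyster, "treatment": t}
                )
    design = pd.DataFrame(design_rows)

    n_pep = np.maximum(2, rng.poisson(config.peptides_per_protein_mean, size=n))
    peptides = [
        [_peptide(pi, j, rng) for j in range(n_pep[pi])] for pi in range(n)
    ]

    psm_rows: list[dict] = []
    a_true, b_true = config.true_hit_beta
    a_dec, b_dec = config.decoy_beta
    oysters = design.drop_duplicates("oyster_id")
    for _, orow in oysters.iterrows():
        t = orow["treatment"]
        bio = np.exp(rng.normal(0.0, config.biological_cv, size=n))
        mean_o = baseline * lengths * effects[t].to_numpy() * bio
        injections = design.loc[design["oyster_id"] == orow["oyster_id"], "injection_id"]
        for inj in injections:
            counts = _nb_counts(rng, mean_o, config.dispersion)
            nz = np.nonzero(counts)[0]
            for pi in nz:
                k = int(counts[pi])
                pep_idx = rng.integers(0, n_pep[pi], size=k)
                decoy = rng.random(k) < config.decoy_fraction
                probs = np.where(
                    decoy,
                    rng.beta(a_dec, b_dec, size=k),
                    rng.beta(a_true, b_true, size=k),
                )
                for j in range(k):
                    psm_rows.append(
                        {
                            "peptide": peptides[pi][pep_idx[j]],
                            "protein_id": f"prot{pi:05d}",
                            "probability": round(float(probs[j]), 6),
                            "injection_id": inj,
                            "is_decoy": bool(decoy[j]),
                        }
                    )
    psms = pd.DataFrame(
        psm_rows, columns=["peptide", "protein_id", "probability", "injection_id", "is_decoy"]
    )

    protein_table = pd.DataFrame(
        {"protein_id": [f"prot{i:05d}" for i in range(n)], "length": lengths}
    )

    comparisons = {
        "OA": (ref, "2800"),
        "MechS-400": (ref, "400-MechS"),
        "MechS-2800": ("2800", "2800-MechS"),
    }
    truth = protein_table.copy()
    truth["baseline"] = baseline
    for t in treatments:
        truth[f"effect_{t}"] = effects[t].to_numpy()
    for name, (ga, gb) in comparisons.items():
        if ga not in treatments or gb not in treatments:
            continue
        fold = effects[gb].to_numpy() / effects[ga].to_numpy()
        truth[f"true_fold_{name}"] = fold
        truth[f"true_da_{name}"] = ~np.isclose(fold, 1.0)
    return psms, design, protein_table, truth


def simulate_micromech(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Indent table (shell_id, treatment, load_n, diag1_um, diag2_um, crack_um) + truth."""
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    truth_rows = []
    for t, dv, dc in zip(config.mech_treatments, config.vhn_offsets, config.crack_offsets_um):
        truth_rows.append(
            {"treatment": t, "true_vhn_mean": config.vhn_mean + dv,
             "true_crack_mean_um": config.crack_mean_um + dc}
        )
        n_shells = int(rng.integers(config.shells_per_treatment[0], config.shells_per_treatment[1] + 1))
        for s in range(1, n_shells + 1):
            shell_mean = rng.normal(config.vhn_mean + dv, config.vhn_shell_sd)
            n_ind = int(rng.integers(config.indents_per_shell[0], config.indents_per_shell[1] + 1))
            for _ in range(n_ind):
                vhn = max(rng.normal(shell_mean, config.vhn_indent_sd), 20.0)
                # invert the Vickers relation to get the diagonal implied by VHN
                d_mm = np.sqrt(1.8544 * (config.indent_load_n / 9.80665) / vhn)
                d_um = d_mm * 1e3
                jitter = rng.normal(0.0, 0.4, size=2)
                crack = max(
                    rng.normal(config.crack_mean_um + dc, config.crack_sd_um), d_um * 0.75
                )
                rows.append(
                    {
                        "shell_id": f"{t}-S{s}",
                        "treatment": t,
                        "load_n": config.indent_load_n,
                        "diag1_um": d_um + jitter[0],
                        "diag2_um": d_um + jitter[1],
                        "crack_um": crack,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_profiles(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fatty-acid peak areas, glycogen assay plate, and their truth tables."""
    rng = np.random.default_rng(config.seed + 2)
    fa_names = [f"FA{i + 1:02d}" for i in range(config.n_fatty_acids)]
    base_conc = rng.gamma(2.0, 1.0, size=config.n_fatty_acids)
    base_conc = base_conc / base_conc.sum() * config.dirichlet_concentration

    fa_rows = []
    gly_rows = []
    truth_rows = []
    for gi, (t, n_samp) in enumerate(
        zip(config.profile_treatments, config.samples_per_profile_treatment)
    ):
        conc = base_conc.copy()
        if config.profile_shift and gi > 0:
            shift = 1.0 + config.profile_shift * np.where(
                np.arange(config.n_fatty_acids) % 2 == 0, 1.0, -0.5
            )
            conc = np.clip(conc * shift, 0.05, None)
        for s in range(1, n_samp + 1):
            sample_id = f"{t}-F{s}"
            props = rng.dirichlet(conc)
            total_area = rng.lognormal(np.log(5e6), 0.2)
            fa_rows.append(
                {"sample_id": sample_id, "treatment": t,
                 **{fa: props[j] * total_area for j, fa in enumerate(fa_names)}}
            )
            true_gly = rng.lognormal(np.log(config.glycogen_mean_ug_mg), 0.35)
            mass_mg = rng.uniform(19.3, 84.7)
            # invert the plate math to get the noise-free well absorbance
            ug_per_well = true_gly * mass_mg / (config.dilution_factor * 200.0) * 50.0
            a_clean = config.glycogen_slope * ug_per_well + config.glycogen_intercept + config.glycogen_blank
            reps = a_clean * (1.0 + rng.normal(0.0, config.glycogen_cv, size=3))
            gly_rows.append(
                {
                    "sample_id": sample_id,
                    "treatment": t,
                    "a570_1": reps[0],
                    "a570_2": reps[1],
                    "a570_3": reps[2],
                    "blank": config.glycogen_blank,
                    "dilution": config.dilution_factor,
                    "mass_mg": mass_mg,
                }
            )
            truth_rows.append(
                {"sample_id": sample_id, "treatment": t, "true_glycogen_ug_mg": true_gly,
                 "configured_cv": config.glycogen_cv, "profile_shift": config.profile_shift}
            )
    return pd.DataFrame(fa_rows), pd.DataFrame(gly_rows), pd.DataFrame(truth_rows)


def simulate_growth(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Buoyant-weight table (oyster_id, treatment, timepoint, mass_g) + truth."""
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    truth_rows = []
    for t, rate in zip(config.growth_treatments, config.growth_rates_per_day):
        truth_rows.append({"treatment": t, "true_rgr_per_day": rate})
        for o in range(1, config.oysters_per_growth_treatment + 1):
            oyster = f"{t}-G{o}"
            start = rng.lognormal(
                np.log(config.start_mass_g), config.start_mass_cv
            )
            end = start * np.exp(rate * config.growth_days) * np.exp(
                rng.normal(0.0, config.growth_noise_cv)
            )
            rows.append({"oyster_id": oyster, "treatment": t, "timepoint": "start", "mass_g": start})
            rows.append({"oyster_id": oyster, "treatment": t, "timepoint": "end", "mass_g": end})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
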