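"""Synthetic cohorts, cell-line panels, drug-response tables and growth assays.

This module generates data with the statistical structure the downstream
pipeline assumes, so every stage can be exercised end to end without any
external download:

* patient bulk expression as linear-scale mixtures of a dominant tumor
  subtype plus stromal/immune contamination, log2-transformed, with
  log-normal measurement noise;
* cell-line expression as subtype profiles distorted by a per-gene batch
  shift/scale (the systematic offset between cell-line and tumor profiling);
* monotherapy viability tables from per-(subtype, drug) Hill curves;
* well-level growth-area observations from the co-culture simulator.

All randomness flows from a single seed through named substreams
(:mod:`hetmix._rng`), so identical configurations reproduce bit-identical
outputs and modules can be tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .datatypes import (
    ROLE_CELL_LINE,
    ROLE_PATIENT,
    ExpressionMatrix,
    SignatureMatrix,
    linear_to_log2,
    log2_to_linear,
)
from .mixsim import GrowthParams, HillParams, hill_viability, simulate_mixture

__all__ = [
    "SubtypeSpec",
    "ResistantClone",
    "CohortConfig",
    "generate_cohort",
    "generate_cell_line_panel",
    "generate_reference_profiles",
    "generate_monotherapy_table",
    "generate_growth_experiment",
    "resistance_factors",
    "line_dose_response",
]

PATIENT_BATCH = "patient"
CELL_LINE_BATCH = "cell-line"


@dataclass(frozen=True)
class SubtypeSpec:
    """A latent tumor subtype: expression profile, growth, and drug response.

    Parameters
    ----------
    name
        Subtype label.
    marker_genes
        Genes over-expressed in this subtype relative to the others.
    base_profile
        Per-gene mean log2 expression of a pure population of this subtype,
        indexed by gene id.
    doubling_time
        Unperturbed doubling time in hours (> 0).
    dose_response
        Mapping drug name -> :class:`~hetmix.mixsim.HillParams`.
    cell_lines
        Names of the cell lines modelling this subtype (may be empty).
    cell_area
        Imaging footprint per cell, used when converting simulated counts to
        growth areas.
    """

    name: str
    marker_genes: tuple[str, ...]
    base_profile: pd.Series
    doubling_time: float
    dose_response: Mapping[str, HillParams] = field(default_factory=dict)
    cell_lines: tuple[str, ...] = ()
    cell_area: float = 1.0

    def __post_init__(self) -> None:
        if self.doubling_time <= 0:
            raise ValueError(f"doubling_time of {self.name!r} must be positive")
        missing = set(self.marker_genes) - set(self.base_profile.index)
        if missing:
            raise ValueError(
                f"marker genes of {self.name!r} outside gene universe: {sorted(missing)[:5]}"
            )
        for drug, p in self.dose_response.items():
            if not 0.0 <= p.emax <= 1.0:
                raise ValueError(f"emax of ({self.name!r}, {drug!r}) must lie in [0, 1]")


@dataclass(frozen=True)
class ResistantClone:
    """A drug-resistant derivative of a parental cell line.

    The clone's expression equals the parent subtype profile plus a bounded
    perturbation restricted to a resistance gene set, and its IC50 for the
    resisted drug is multiplied by a factor drawn uniformly from
    ``ic50_factor_range`` (default 10-100x).
    """

    name: str
    parent_line: str
    upregulated_genes: tuple[str, ...]
    resistant_drug: str
    log2_shift: float = 1.0
    ic50_factor_range: tuple[float, float] = (10.0, 100.0)


@dataclass
class CohortConfig:
    """Configuration of a synthetic patient cohort and matched line panel.

    ``subtypes`` define the tumor compartments; ``nontumor_profiles`` the
    contaminating compartments (per-gene log2 means).  Each patient carries a
    single dominant subtype drawn from ``subtype_probs``; the tumor content
    of the biopsy is drawn from ``Beta(*tumor_fraction_beta)`` unless a fixed
    ``tumor_fraction`` is given, and the remainder is split across non-tumor
    types.  ``noise_sd`` is measurement noise in log2 units.  Cell-line
    columns receive a per-gene batch shift ~ N(0, batch_shift_sd) and scale
    ~ N(1, batch_scale_sd), shared across lines, emulating the systematic
    offset between profiling platforms.
    """

    subtypes: tuple[SubtypeSpec, ...]
    nontumor_profiles: Mapping[str, pd.Series]
    n_patients: int = 208
    subtype_probs: Mapping[str, float] | None = None
    tumor_fraction_beta: tuple[float, float] = (5.0, 2.0)
    tumor_fraction: float | None = None
    noise_sd: float = 0.25
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.05
    batch_shift: np.ndarray | None = None
    batch_scale: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.subtypes:
            raise ValueError("at least one subtype required")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        genes = self.subtypes[0].base_profile.index
        for spec in self.subtypes:
            if not spec.base_profile.index.equals(genes):
                raise ValueError("all subtype profiles must share one gene universe")
        for name, prof in self.nontumor_profiles.items():
            if not prof.index.equals(genes):
                raise ValueError(f"non-tumor profile {name!r} on a different gene universe")
        n_markers = len({g for s in self.subtypes for g in s.marker_genes})
        if len(genes) < n_markers:
            raise ValueError("n_genes must be >= number of marker genes")
        if self.subtype_probs is None:
            p = 1.0 / len(self.subtypes)
            self.subtype_probs = {s.name: p for s in self.subtypes}
        probs = np.array([self.subtype_probs[s.name] for s in self.subtypes])
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("subtype probabilities must sum to 1")
        if self.tumor_fraction is not None and not 0.0 < self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in (0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.subtypes[0].base_profile.index

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def subtype_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.subtypes)

    @property
    def nontumor_names(self) -> tuple[str, ...]:
        return tuple(self.nontumor_profiles)

    def subtype(self, name: str) -> SubtypeSpec:
        for s in self.subtypes:
            if s.name == name:
                return s
        raise KeyError(f"unknown subtype {name!r}")

    def line_to_subtype(self) -> dict[str, str]:
        return {line: s.name for s in self.subtypes for line in s.cell_lines}


def _linear_profiles(config: CohortConfig) -> pd.DataFrame:
    """Linear-scale reference profile per compartment (tumor + non-tumor)."""
    cols = {}
    for spec in config.subtypes:
        cols[spec.name] = log2_to_linear(spec.base_profile)
    for name, prof in config.nontumor_profiles.items():
        cols[name] = log2_to_linear(prof)
    return pd.DataFrame(cols)


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SignatureMatrix]:
    """Generate patient bulk expression plus ground truth and signatures.

    Each bulk column is, on the linear scale, the fraction-weighted sum of
    its dominant subtype profile and the non-tumor profiles; the mixture is
    then log2(x + 1)-transformed and Gaussian noise of ``config.noise_sd``
    log2 units is added.

    Returns
    -------
    bulk : ExpressionMatrix
        Patient samples, role ``"patient"``, batch ``"patient"``.
    truth : DataFrame
        Per sample: ``subtype``, ``tumor_fraction`` and the full fraction
        vector over compartments.
    signatures : SignatureMatrix
        The true linear-scale compartment profiles with all subtype marker
        genes recorded for fraction estimation.
    """
    rng_assign = substream(config.seed, "cohort-assign")
    rng_frac = substream(config.seed, "cohort-fractions")
    rng_noise = substream(config.seed, "cohort-noise")

    profiles = _linear_profiles(config)
    subtype_names = list(config.subtype_names)
    nontumor = list(config.nontumor_names)
    probs = np.array([config.subtype_probs[n] for n in subtype_names])

    samples = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    assignments = rng_assign.choice(len(subtype_names), size=config.n_patients, p=probs)

    frac_rows = np.zeros((config.n_patients, len(profiles.columns)))
    col_pos = {c: j for j, c in enumerate(profiles.columns)}
    for i, k in enumerate(assignments):
        if config.tumor_fraction is not None:
            f_tumor = config.tumor_fraction
        else:
            f_tumor = float(rng_frac.beta(*config.tumor_fraction_beta))
        frac_rows[i, col_pos[subtype_names[k]]] = f_tumor
        if nontumor:
            split = rng_frac.dirichlet(np.ones(len(nontumor)))
            for name, w in zip(nontumor, split):
                frac_rows[i, col_pos[name]] = (1.0 - f_tumor) * w

    bulk_linear = profiles.to_numpy() @ frac_rows.T
    values = np.log2(bulk_linear + 1.0)
    if config.noise_sd > 0:
        values = values + rng_noise.normal(0.0, config.noise_sd, size=values.shape)
    bulk = ExpressionMatrix(
        pd.DataFrame(values, index=config.gene_ids, columns=samples),
        pd.Series(ROLE_PATIENT, index=samples),
        pd.Series(PATIENT_BATCH, index=samples),
    )

    truth = pd.DataFrame(frac_rows, index=samples, columns=list(profiles.columns))
    truth.insert(0, "tumor_fraction", [frac_rows[i, col_pos[subtype_names[k]]] for i, k in enumerate(assignments)])
    truth.insert(0, "subtype", [subtype_names[k] for k in assignments])

    # marker_genes left unset: the true signature is genome-wide, so
    # estimation can use every shared gene and stays fully identifiable.
    signatures = SignatureMatrix(profiles, tumor_types=tuple(subtype_names))
    return bulk, truth, signatures


def _batch_effects(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = substream(config.seed, "batch-effects")
    if config.batch_shift is not None:
        shift = np.asarray(config.batch_shift, dtype=float)
    else:
        shift = rng.normal(0.0, config.batch_shift_sd, size=config.n_genes) if config.batch_shift_sd > 0 else np.zeros(config.n_genes)
    if config.batch_scale is not None:
        scale = np.asarray(config.batch_scale, dtype=float)
    else:
        scale = rng.normal(1.0, config.batch_scale_sd, size=config.n_genes) if config.batch_scale_sd > 0 else np.ones(config.n_genes)
    if shift.shape != (config.n_genes,) or scale.shape != (config.n_genes,):
        raise ValueError("batch_shift/batch_scale must have one entry per gene")
    return shift, scale


def generate_cell_line_panel(
    config: CohortConfig,
    resistant_clones: Sequence[ResistantClone] = (),
) -> ExpressionMatrix:
    """Generate the cell-line expression panel with batch distortion.

    Each line's log2 column is its subtype base profile transformed by the
    per-gene batch scale and shift, plus measurement noise.  Resistant clones
    are the parent profile plus ``log2_shift`` on their resistance gene set,
    before the same batch transform — a perturbation deliberately smaller
    than the distance between subtypes, so clones co-cluster with their
    parents.
    """
    shift, scale = _batch_effects(config)
    rng = substream(config.seed, "panel-noise")
    line_map = config.line_to_subtype()
    if not line_map and not resistant_clones:
        raise ValueError("no cell lines declared on any subtype")
    for clone in resistant_clones:
        if clone.parent_line not in line_map:
            raise ValueError(f"unknown parent line {clone.parent_line!r} for clone {clone.name!r}")

    cols: dict[str, np.ndarray] = {}
    for line, subtype_name in line_map.items():
        profile = config.subtype(subtype_name).base_profile.to_numpy()
        cols[line] = profile * scale + shift
    for clone in resistant_clones:
        parent_profile = config.subtype(line_map[clone.parent_line]).base_profile.copy()
        missing = set(clone.upregulated_genes) - set(parent_profile.index)
        if missing:
            raise ValueError(f"resistance genes outside universe: {sorted(missing)[:5]}")
        parent_profile.loc[list(clone.upregulated_genes)] += clone.log2_shift
        cols[clone.name] = parent_profile.to_numpy() * scale + shift

    values = pd.DataFrame(cols, index=config.gene_ids)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    samples = values.columns
    return ExpressionMatrix(
        values,
        pd.Series(ROLE_CELL_LINE, index=samples),
        pd.Series(CELL_LINE_BATCH, index=samples),
    )


def generate_reference_profiles(
    config: CohortConfig,
    n_per_type: int = 5,
    noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Single-cell-like labelled profiles for signature construction.

    Emulates a small annotated reference of per-cell-type expression
    profiles: ``n_per_type`` noisy log2 replicates around each compartment's
    mean profile.  Returns the genes x profiles table and the per-profile
    cell-type labels.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    rng = substream(config.seed, "reference-profiles")
    cols: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    means = {s.name: s.base_profile.to_numpy() for s in config.subtypes}
    means.update({n: p.to_numpy() for n, p in config.nontumor_profiles.items()})
    for type_name, mean in means.items():
        for rep in range(n_per_type):
            name = f"{type_name}|ref{rep + 1}"
            noise = rng.normal(0.0, noise_sd, size=mean.shape) if noise_sd > 0 else 0.0
            cols[name] = mean + noise
            labels[name] = type_name
    return pd.DataFrame(cols, index=config.gene_ids), pd.Series(labels)


def resistance_factors(
    clones: Sequence[ResistantClone], seed: int = 0
) -> dict[str, float]:
    """Per-clone IC50 multipliers for the resisted drug.

    Drawn uniformly from each clone's ``ic50_factor_range`` via one named
    substream, so the monotherapy table and the growth simulator see the
    same resistance level for a given seed.
    """
    rng = substream(seed, "resistance-factors")
    return {c.name: float(rng.uniform(*c.ic50_factor_range)) for c in clones}


def line_dose_response(
    specs: Sequence[SubtypeSpec],
    resistant_clones: Sequence[ResistantClone] = (),
    seed: int = 0,
) -> dict[str, dict[str, HillParams]]:
    """Per-line Hill parameters, including resistant clones' shifted IC50s."""
    params: dict[str, dict[str, HillParams]] = {}
    for spec in specs:
        for line in spec.cell_lines:
            params[line] = dict(spec.dose_response)
    factors = resistance_factors(resistant_clones, seed)
    for clone in resistant_clones:
        if clone.parent_line not in params:
            raise ValueError(f"unknown parent line {clone.parent_line!r}")
        clone_params = dict(params[clone.parent_line])
        if clone.resistant_drug in clone_params:
            base = clone_params[clone.resistant_drug]
            clone_params[clone.resistant_drug] = HillParams(
                base.ic50 * factors[clone.name], base.hill, base.emax
            )
        params[clone.name] = clone_params
    return params


def _check_grid(grid: Sequence[float]) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("conc_grid must be non-empty")
    if (grid < 0).any():
        raise ValueError("concentrations must be non-negative")
    if not np.all(np.diff(grid) >= 0):
        raise ValueError("conc_grid must be ascending")
    return grid


def generate_monotherapy_table(
    specs: Sequence[SubtypeSpec],
    drugs: Sequence[str],
    conc_grid: Sequence[float] | Mapping[str, Sequence[float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    resistant_clones: Sequence[ResistantClone] = (),
) -> pd.DataFrame:
    """Tidy monotherapy viability table for every declared cell line.

    One row per (cell line, drug, concentration) with viability from the
    line's subtype Hill curve, optionally with bounded multiplicative noise,
    clamped to [0, 1].  ``conc_grid`` may be a single ascending grid shared
    by all drugs or a mapping drug -> grid (drug potencies differ by orders
    of magnitude, so per-drug grids are the norm).  Resistant clones inherit
    the parent curve with the IC50 of the resisted drug multiplied by a
    random 10-100x factor.
    """
    if isinstance(conc_grid, Mapping):
        grids = {d: _check_grid(g) for d, g in conc_grid.items()}
    else:
        shared = _check_grid(conc_grid)
        grids = {d: shared for d in drugs}
    rng = substream(seed, "monotherapy-noise")
    line_params = line_dose_response(specs, resistant_clones, seed)

    rows = []
    for line, params in line_params.items():
        for drug in drugs:
            if drug not in params or drug not in grids:
                continue
            p = params[drug]
            grid = grids[drug]
            viab = hill_viability(grid, p.ic50, p.hill, p.emax)
            viab = np.atleast_1d(viab)
            if noise_sd > 0:
                viab = viab * np.exp(rng.normal(0.0, noise_sd, size=viab.shape))
            viab = np.clip(viab, 0.0, 1.0)
            for c, v in zip(grid, viab):
                rows.append((line, drug, float(c), float(v)))
    return pd.DataFrame(rows, columns=["cell_line", "drug", "concentration", "viability"])


@dataclass
class SensitivityScreen:
    """Synthetic inputs for the expression -> AUC imputation workflow.

    ``X_train`` / ``auc`` emulate a screened cell-line panel: expression
    profiles plus per-drug area-under-curve responses in which each drug's
    AUC decreases with the mean expression of its linked gene set (higher
    pathway activity = more sensitive, lower AUC).  ``clone_profiles`` maps
    each resistant clone to replicate expression profiles of its parental
    (sensitive) and resistant states; the resistant state carries the
    clone's upregulated resistance gene set.  ``linked_drug`` names, per
    clone, the drug whose response gene set the clone upregulates — the
    drug the screen should nominate as resistant-selective.
    """

    X_train: pd.DataFrame
    auc: pd.DataFrame  # training lines x drugs
    clone_profiles: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    linked_drug: dict[str, str]


def generate_sensitivity_screen(
    config: CohortConfig,
    clones: Sequence[ResistantClone],
    drug_gene_sets: Mapping[str, Sequence[str]],
    n_background_drugs: int = 18,
    n_training_lines: int = 120,
    n_replicates: int = 5,
    genes_per_background_set: int = 10,
    train_noise_sd: float = 1.0,
    replicate_noise_sd: float = 0.1,
    auc_effect: float = 0.3,
    auc_noise_sd: float = 0.02,
    seed: int = 0,
) -> SensitivityScreen:
    """Generate a training panel plus clone profiles for the drug screen.

    ``drug_gene_sets`` maps named drugs to the gene sets driving their
    sensitivity (e.g. the resistance-pathway sets the clones upregulate).
    Background drugs get disjoint random gene sets from the remaining
    genes, so their imputed responses are exchangeable between clone
    states.
    """
    rng = substream(seed, "sensitivity-screen")
    named_genes = [g for gs in drug_gene_sets.values() for g in gs]
    clone_genes = [g for c in clones for g in c.upregulated_genes]
    core = list(dict.fromkeys(named_genes + clone_genes))
    remaining = [g for g in config.gene_ids if g not in set(core)]
    n_bg_genes = n_background_drugs * genes_per_background_set
    bg_genes = list(rng.choice(remaining, size=n_bg_genes, replace=False))
    genes = pd.Index(core + bg_genes)

    gene_sets: dict[str, list[str]] = {d: list(gs) for d, gs in drug_gene_sets.items()}
    for i in range(n_background_drugs):
        name = f"background-{i + 1:02d}"
        gene_sets[name] = bg_genes[
            i * genes_per_background_set : (i + 1) * genes_per_background_set
        ]

    baseline = 5.0
    lines = [f"CCL{i + 1:03d}" for i in range(n_training_lines)]
    X_train = pd.DataFrame(
        baseline + rng.normal(0.0, train_noise_sd, size=(len(genes), n_training_lines)),
        index=genes,
        columns=lines,
    )

    auc = {}
    for drug, gs in gene_sets.items():
        activity = (X_train.loc[gs] - baseline).mean(axis=0)
        auc[drug] = 0.8 - auc_effect * activity + rng.normal(0.0, auc_noise_sd, size=n_training_lines)
    auc = pd.DataFrame(auc, index=lines)

    line_map = config.line_to_subtype()
    clone_profiles: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for clone in clones:
        parent_profile = config.subtype(line_map[clone.parent_line]).base_profile.loc[genes]
        resistant_profile = parent_profile.copy()
        up = [g for g in clone.upregulated_genes if g in set(genes)]
        resistant_profile.loc[up] += clone.log2_shift
        reps_s = {
            f"{clone.parent_line}|rep{r + 1}": parent_profile.to_numpy()
            + rng.normal(0.0, replicate_noise_sd, size=len(genes))
            for r in range(n_replicates)
        }
        reps_r = {
            f"{clone.name}|rep{r + 1}": resistant_profile.to_numpy()
            + rng.normal(0.0, replicate_noise_sd, size=len(genes))
            for r in range(n_replicates)
        }
        clone_profiles[clone.name] = (
            pd.DataFrame(reps_s, index=genes),
            pd.DataFrame(reps_r, index=genes),
        )

    linked: dict[str, str] = {}
    for clone in clones:
        up = set(clone.upregulated_genes)
        overlaps = {
            d: len(up & set(gs)) / len(gs) for d, gs in drug_gene_sets.items()
        }
        best = max(sorted(overlaps), key=overlaps.get)
        if overlaps[best] >= 0.99:  # only full-set upregulation counts as linked
            linked[clone.name] = best
    return SensitivityScreen(
        X_train=X_train, auc=auc, clone_profiles=clone_profiles, linked_drug=linked
    )


def generate_growth_experiment(
    params: GrowthParams,
    seeding: Mapping[str, float],
    treatments: Mapping[str, Sequence[tuple[str, float]]],
    n_replicates: int = 6,
    well_noise_sd: float = 0.05,
    duration: float = 120.0,
    dt: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a plate of treated co-culture wells and report areas.

    For each named condition the mixture trajectory is simulated once
    (growth is deterministic given the treatment); per replicate well,
    per-channel areas at treatment start (t = 0) and at the endpoint
    (default 120 h = day 5) are obtained by converting counts through each
    line's cell-area constant and applying multiplicative log-normal
    measurement noise.

    Returns a tidy DataFrame with columns
    ``condition, replicate, channel, area_start, area_end``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not treatments:
        raise ValueError("at least one treatment condition required")
    if sum(float(v) for v in seeding.values()) <= 0:
        raise ValueError("empty mixture: total seeding must be positive")
    for cond, treatment in treatments.items():
        for drug, conc in treatment:
            if conc < 0:
                raise ValueError(f"negative dose for {drug!r} in condition {cond!r}")
    rng = substream(seed, "well-noise")

    rows = []
    for cond, treatment in treatments.items():
        traj = simulate_mixture(params, seeding, treatment, duration=duration, dt=dt)
        start_counts = traj.iloc[0]
        end_counts = traj.iloc[-1]
        for rep in range(1, n_replicates + 1):
            for line in params.lines:
                area = params.cell_area[line]
                noise_start = np.exp(rng.normal(0.0, well_noise_sd)) if well_noise_sd > 0 else 1.0
                noise_end = np.exp(rng.normal(0.0, well_noise_sd)) if well_noise_sd > 0 else 1.0
                rows.append(
                    (
                        cond,
                        rep,
                        line,
                        float(start_counts[line] * area * noise_start),
                        float(end_counts[line] * area * noise_end),
                    )
                )
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "channel", "area_start", "area_end"]
    )
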