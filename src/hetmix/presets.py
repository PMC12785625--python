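"""Ready-made study conditions for the two CRPC-like modelling settings.

Two presets mirror the clinical contexts the pipeline is designed for:

``unstratified_crpc``
    A cohort of molecularly unstratified castration-resistant prostate
    cancer (CRPC)-like patients carrying four latent tumor subtypes — an
    AR-negative lineage, a lineage co-expressing AR and constitutively
    active AR variants, a variant-only lineage, and a neuroendocrine-like
    (NEPC-like) lineage — each with a matched cell line.  The NEPC-like
    line is flagged excludable, standing in for a line whose culturing
    requirements keep it out of a co-culture model.

``taxane_resistant_crpc``
    A smaller cohort of taxane-exposed patients, plus docetaxel-resistant
    clones of the three culturable lines.  Each clone is its parent profile
    perturbed on a resistance gene set (growth-factor/RTK/RAS/ERK-like for
    the AR-variant lineage, PI3K/AKT/mTOR/NAMPT-like for the AR-negative
    lineage), a perturbation deliberately smaller than the between-subtype
    distance, and carries a 10-100x IC50 shift for the taxane.

Drug names carry a ``-like`` suffix: the dose-response curves are synthetic
constructions that reproduce the qualitative sensitivity structure of the
modelled compounds, not fits to measured pharmacology.  All doses are in nM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .mixsim import GrowthParams, HillParams, hill_ic50_for_viability, seeding_ratio
from .synthgen import (
    CohortConfig,
    ResistantClone,
    SubtypeSpec,
    line_dose_response,
)

__all__ = [
    "DRUG_DOCETAXEL",
    "DRUG_DAPORINAD",
    "DRUG_VINORELBINE",
    "DRUG_DASATINIB",
    "DRUG_SELUMETINIB",
    "TEST_DOSES",
    "CSUSTAINED",
    "EXCLUDABLE_LINES",
    "unstratified_crpc",
    "taxane_resistant_crpc",
    "marker_sets",
    "resistance_gene_sets",
    "growth_params",
    "mixture_seeding",
    "combo_treatments",
    "drug_concentration_grids",
    "ComboScenario",
    "complementary_combo_scenario",
    "synergy_combo_scenario",
]

# Drug analogs and their standard single test doses (nM), patterned on the
# doses used in mixed-cell validation experiments for the modelled compounds.
DRUG_DOCETAXEL = "docetaxel-like"
DRUG_DAPORINAD = "daporinad-like"
DRUG_VINORELBINE = "vinorelbine-like"
DRUG_DASATINIB = "dasatinib-like"
DRUG_SELUMETINIB = "selumetinib-like"

TEST_DOSES: dict[str, float] = {
    DRUG_DOCETAXEL: 3.0,
    DRUG_DAPORINAD: 5.0,
    DRUG_VINORELBINE: 8.0,
    DRUG_DASATINIB: 400.0,
    DRUG_SELUMETINIB: 1000.0,
}

# Clinically sustainable plasma-concentration caps used to bound the partner
# dose grids during combination ranking (synthetic values, nM).
CSUSTAINED: dict[str, float] = {
    DRUG_DOCETAXEL: 12.0,
    DRUG_DAPORINAD: 20.0,
    DRUG_VINORELBINE: 32.0,
    DRUG_DASATINIB: 1600.0,
    DRUG_SELUMETINIB: 4000.0,
}

SUBTYPE_AR_NEG = "AR-neg"
SUBTYPE_AR_VARIANT = "AR-variant"
SUBTYPE_VARIANT_ONLY = "variant-only"
SUBTYPE_NEPC = "NEPC-like"

LINE_BY_SUBTYPE = {
    SUBTYPE_AR_NEG: "DU145-like",
    SUBTYPE_AR_VARIANT: "22RV1-like",
    SUBTYPE_VARIANT_ONLY: "R1D567-like",
    SUBTYPE_NEPC: "H660-like",
}

# The NEPC-like line needs culturing conditions incompatible with the
# co-culture plate, so it is never seeded into the mixed-cell model.
EXCLUDABLE_LINES: frozenset[str] = frozenset({"H660-like"})

DOUBLING_TIMES = {
    SUBTYPE_AR_NEG: 28.0,
    SUBTYPE_AR_VARIANT: 56.0,
    SUBTYPE_VARIANT_ONLY: 56.0,
    SUBTYPE_NEPC: 70.0,
}

CELL_AREAS = {
    SUBTYPE_AR_NEG: 1.0,
    SUBTYPE_AR_VARIANT: 1.2,
    SUBTYPE_VARIANT_ONLY: 1.1,
    SUBTYPE_NEPC: 0.9,
}

SUBTYPE_PROBS = {
    SUBTYPE_AR_NEG: 0.30,
    SUBTYPE_AR_VARIANT: 0.30,
    SUBTYPE_VARIANT_ONLY: 0.25,
    SUBTYPE_NEPC: 0.15,
}

# Target viability of each subtype at the drug's standard test dose.  These
# encode the complementary-sensitivity structure of the cohort: the taxane
# hits the AR-negative and variant-only lineages, the NAMPT inhibitor hits
# the AR-variant and NEPC-like lineages (plus variant-only mildly), the
# vinca alkaloid is moderately active across lineages, and the kinase
# inhibitors are near-inert in the treatment-naive setting.
_VIABILITY_TARGETS: dict[str, dict[str, float]] = {
    DRUG_DOCETAXEL: {
        SUBTYPE_AR_NEG: 0.41,
        SUBTYPE_AR_VARIANT: 0.97,
        SUBTYPE_VARIANT_ONLY: 0.43,
        SUBTYPE_NEPC: 0.95,
    },
    DRUG_DAPORINAD: {
        SUBTYPE_AR_NEG: 0.97,
        SUBTYPE_AR_VARIANT: 0.64,
        SUBTYPE_VARIANT_ONLY: 0.81,
        SUBTYPE_NEPC: 0.50,
    },
    DRUG_VINORELBINE: {
        SUBTYPE_AR_NEG: 0.55,
        SUBTYPE_AR_VARIANT: 0.60,
        SUBTYPE_VARIANT_ONLY: 0.58,
        SUBTYPE_NEPC: 0.70,
    },
    DRUG_DASATINIB: {
        SUBTYPE_AR_NEG: 0.96,
        SUBTYPE_AR_VARIANT: 0.96,
        SUBTYPE_VARIANT_ONLY: 0.90,
        SUBTYPE_NEPC: 0.96,
    },
    DRUG_SELUMETINIB: {
        SUBTYPE_AR_NEG: 0.96,
        SUBTYPE_AR_VARIANT: 0.96,
        SUBTYPE_VARIANT_ONLY: 0.96,
        SUBTYPE_NEPC: 0.96,
    },
}

_HILL_SLOPE = 2.0
_EMAX = 0.95


def _dose_response_for(subtype: str) -> dict[str, HillParams]:
    out = {}
    for drug, targets in _VIABILITY_TARGETS.items():
        ic50 = hill_ic50_for_viability(
            targets[subtype], TEST_DOSES[drug], _HILL_SLOPE, _EMAX
        )
        out[drug] = HillParams(ic50=ic50, hill=_HILL_SLOPE, emax=_EMAX)
    return out


# ---------------------------------------------------------------------------
# Gene universe layout.  Gene ids are positional, so block boundaries are a
# pure function of (markers_per_type, n_genes) and can be recomputed by the
# marker-set helpers without carrying state around.
# ---------------------------------------------------------------------------

_N_STROMAL_MARKERS = 50
_N_IMMUNE_MARKERS = 50
_N_RESISTANCE_GENES = 50
_N_SIGNATURE_GENES = 30  # AR / NEPC scoring subsets


def _gene_ids(n_genes: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")


def _blocks(markers_per_type: int) -> dict[str, slice]:
    m = markers_per_type
    subtype_order = [SUBTYPE_AR_NEG, SUBTYPE_AR_VARIANT, SUBTYPE_VARIANT_ONLY, SUBTYPE_NEPC]
    blocks: dict[str, slice] = {}
    start = 0
    for name in subtype_order:
        blocks[name] = slice(start, start + m)
        start += m
    blocks["stroma"] = slice(start, start + _N_STROMAL_MARKERS)
    start += _N_STROMAL_MARKERS
    blocks["immune"] = slice(start, start + _N_IMMUNE_MARKERS)
    start += _N_IMMUNE_MARKERS
    blocks["rtk-ras"] = slice(start, start + _N_RESISTANCE_GENES)
    start += _N_RESISTANCE_GENES
    blocks["pi3k-nampt"] = slice(start, start + _N_RESISTANCE_GENES)
    blocks["_end"] = slice(start + _N_RESISTANCE_GENES, start + _N_RESISTANCE_GENES)
    return blocks


def marker_sets(markers_per_type: int = 400, n_genes: int = 20000) -> dict[str, list[str]]:
    """AR and NEPC scoring gene sets (GMT-exportable).

    The AR set is the leading slice of the AR-variant lineage's markers
    (also mildly elevated in the variant-only lineage); the NEPC set is the
    leading slice of the NEPC-like lineage's markers.
    """
    genes = _gene_ids(n_genes)
    blocks = _blocks(markers_per_type)
    ar = list(genes[blocks[SUBTYPE_AR_VARIANT]][:_N_SIGNATURE_GENES])
    nepc = list(genes[blocks[SUBTYPE_NEPC]][:_N_SIGNATURE_GENES])
    return {"AR_signature": ar, "NEPC_signature": nepc}


def resistance_gene_sets(markers_per_type: int = 400, n_genes: int = 20000) -> dict[str, list[str]]:
    """The two resistance-pathway gene sets used by the taxane-exposed preset."""
    genes = _gene_ids(n_genes)
    blocks = _blocks(markers_per_type)
    return {
        "rtk-ras": list(genes[blocks["rtk-ras"]]),
        "pi3k-nampt": list(genes[blocks["pi3k-nampt"]]),
    }


def _build_subtypes(
    seed: int,
    n_genes: int,
    markers_per_type: int,
    marker_log2fc: float,
) -> tuple[tuple[SubtypeSpec, ...], dict[str, pd.Series]]:
    genes = _gene_ids(n_genes)
    blocks = _blocks(markers_per_type)
    if blocks["_end"].start > n_genes:
        raise ValueError("n_genes too small for the preset's marker blocks")

    rng = substream(seed, "preset-baseline")
    baseline = pd.Series(rng.uniform(2.0, 8.0, size=n_genes), index=genes)
    ar_genes = marker_sets(markers_per_type, n_genes)["AR_signature"]

    subtypes = []
    for name in (SUBTYPE_AR_NEG, SUBTYPE_AR_VARIANT, SUBTYPE_VARIANT_ONLY, SUBTYPE_NEPC):
        profile = baseline.copy()
        markers = tuple(genes[blocks[name]])
        profile.loc[list(markers)] += marker_log2fc
        if name == SUBTYPE_VARIANT_ONLY:
            # variant-only tumors retain a partial AR transcriptional program
            profile.loc[ar_genes] += marker_log2fc / 2.0
        subtypes.append(
            SubtypeSpec(
                name=name,
                marker_genes=markers,
                base_profile=profile,
                doubling_time=DOUBLING_TIMES[name],
                dose_response=_dose_response_for(name),
                cell_lines=(LINE_BY_SUBTYPE[name],),
                cell_area=CELL_AREAS[name],
            )
        )

    nontumor = {}
    for name in ("stroma", "immune"):
        profile = baseline.copy()
        profile.iloc[blocks[name]] += marker_log2fc
        nontumor[name] = profile
    return tuple(subtypes), nontumor


def unstratified_crpc(
    seed: int = 0,
    n_genes: int = 20000,
    n_patients: int = 208,
    markers_per_type: int = 400,
    marker_log2fc: float = 2.0,
    noise_sd: float = 0.25,
    tumor_fraction: float | None = None,
) -> CohortConfig:
    """Cohort configuration for the unstratified CRPC-like setting."""
    subtypes, nontumor = _build_subtypes(seed, n_genes, markers_per_type, marker_log2fc)
    return CohortConfig(
        subtypes=subtypes,
        nontumor_profiles=nontumor,
        n_patients=n_patients,
        subtype_probs=dict(SUBTYPE_PROBS),
        noise_sd=noise_sd,
        tumor_fraction=tumor_fraction,
        seed=seed,
    )


def taxane_resistant_crpc(
    seed: int = 0,
    n_genes: int = 20000,
    n_patients: int = 79,
    markers_per_type: int = 400,
    marker_log2fc: float = 2.0,
    noise_sd: float = 0.25,
    resistance_log2_shift: float = 1.0,
) -> tuple[CohortConfig, tuple[ResistantClone, ...]]:
    """Cohort configuration plus resistant clones for the taxane-exposed setting."""
    config = unstratified_crpc(
        seed=seed,
        n_genes=n_genes,
        n_patients=n_patients,
        markers_per_type=markers_per_type,
        marker_log2fc=marker_log2fc,
        noise_sd=noise_sd,
    )
    sets = resistance_gene_sets(markers_per_type, n_genes)
    half = _N_RESISTANCE_GENES // 2
    clones = (
        ResistantClone(
            name="doceR-22RV1-like",
            parent_line="22RV1-like",
            upregulated_genes=tuple(sets["rtk-ras"]),
            resistant_drug=DRUG_DOCETAXEL,
            log2_shift=resistance_log2_shift,
        ),
        ResistantClone(
            name="doceR-DU145-like",
            parent_line="DU145-like",
            upregulated_genes=tuple(sets["pi3k-nampt"]),
            resistant_drug=DRUG_DOCETAXEL,
            log2_shift=resistance_log2_shift,
        ),
        ResistantClone(
            name="doceR-R1D567-like",
            parent_line="R1D567-like",
            upregulated_genes=tuple(sets["rtk-ras"][:half] + sets["pi3k-nampt"][:half]),
            resistant_drug=DRUG_DOCETAXEL,
            log2_shift=resistance_log2_shift,
        ),
    )
    return config, clones


# ---------------------------------------------------------------------------
# Growth-experiment scenarios
# ---------------------------------------------------------------------------


def growth_params(
    config: CohortConfig,
    lines: Sequence[str] | None = None,
    combo_model: str = "ida-min",
    capacity: float = 2e6,
    resistant_clones: Sequence[ResistantClone] = (),
    seed: int = 0,
) -> GrowthParams:
    """GrowthParams for a panel of the preset's cell lines.

    ``lines`` defaults to every non-excludable line declared on the config's
    subtypes.  Resistant clones inherit the parent's growth constants with
    their shifted dose-response.
    """
    line_map = config.line_to_subtype()
    dr = line_dose_response(config.subtypes, resistant_clones, seed)
    clone_parent = {c.name: c.parent_line for c in resistant_clones}
    if lines is None:
        lines = [ln for ln in line_map if ln not in EXCLUDABLE_LINES]
    doubling, area, dose_response = {}, {}, {}
    for line in lines:
        base_line = clone_parent.get(line, line)
        if base_line not in line_map:
            raise KeyError(f"unknown cell line {line!r}")
        spec = config.subtype(line_map[base_line])
        doubling[line] = spec.doubling_time
        area[line] = spec.cell_area
        dose_response[line] = dr[line]
    return GrowthParams(
        doubling_time=doubling,
        cell_area=area,
        capacity=capacity,
        combo_model=combo_model,
        dose_response=dose_response,
    )


def mixture_seeding(params: GrowthParams, total_cells: float = 50_000.0) -> dict[str, float]:
    """Seeding counts at the doubling-time-proportional integer ratio.

    50,000 cells per well by default, split so that slower-growing lines are
    seeded proportionally more (the 1:2:2-style compensation for unequal
    unperturbed growth rates).
    """
    lines = params.lines
    ratio = seeding_ratio([params.doubling_time[l] for l in lines])
    unit = total_cells / ratio.sum()
    return {line: float(r * unit) for line, r in zip(lines, ratio)}


def combo_treatments(
    drug_a: str, dose_a: float, drug_b: str, dose_b: float
) -> dict[str, list[tuple[str, float]]]:
    """The four standard plate conditions of a combination experiment."""
    return {
        "vehicle": [],
        "mono_a": [(drug_a, dose_a)],
        "mono_b": [(drug_b, dose_b)],
        "combo": [(drug_a, dose_a), (drug_b, dose_b)],
    }


def drug_concentration_grids(n_points: int = 8) -> dict[str, np.ndarray]:
    """Per-drug ascending dose grids from Csustained/2^(n-1) up to Csustained."""
    return {
        drug: cmax * np.power(2.0, np.arange(n_points) - (n_points - 1))
        for drug, cmax in CSUSTAINED.items()
    }


@dataclass(frozen=True)
class ComboScenario:
    """A fully specified combination growth experiment."""

    params: GrowthParams
    seeding: Mapping[str, float]
    treatments: Mapping[str, Sequence[tuple[str, float]]]
    drug_a: str
    dose_a: float
    drug_b: str
    dose_b: float


def complementary_combo_scenario(
    seed: int = 0, config: CohortConfig | None = None
) -> ComboScenario:
    """Taxane + NAMPT-inhibitor combo on the three-line mixed-cell model.

    The scenario with complementary per-line sensitivities: the taxane
    inhibits the AR-negative and variant-only lines, the NAMPT inhibitor the
    AR-variant line, and no within-line interaction (independent drug
    action, minimum-viability rule).  This is the setting where mixture-
    level analysis detects combination benefit that aggregation of per-line
    responses misses.
    """
    if config is None:
        config = unstratified_crpc(seed=seed, n_genes=2000)
    params = growth_params(config, combo_model="ida-min")
    return ComboScenario(
        params=params,
        seeding=mixture_seeding(params),
        treatments=combo_treatments(
            DRUG_DOCETAXEL,
            TEST_DOSES[DRUG_DOCETAXEL],
            DRUG_DAPORINAD,
            TEST_DOSES[DRUG_DAPORINAD],
        ),
        drug_a=DRUG_DOCETAXEL,
        dose_a=TEST_DOSES[DRUG_DOCETAXEL],
        drug_b=DRUG_DAPORINAD,
        dose_b=TEST_DOSES[DRUG_DAPORINAD],
    )


# Scenario-local viability targets for the synergy experiment: cytostatic
# doses at which all three lines are co-sensitive to both drugs, so the
# multiplicative (Bliss-style) within-line interaction drives every line
# below stasis while either monotherapy alone still permits growth.
_SYNERGY_DOSE_A = 1.5
_SYNERGY_DOSE_B = 8.0
_SYNERGY_TARGETS = {
    "DU145-like": (0.60, 0.58),
    "22RV1-like": (0.62, 0.55),
    "R1D567-like": (0.58, 0.62),
}


def synergy_combo_scenario(
    seed: int = 0, config: CohortConfig | None = None
) -> ComboScenario:
    """Taxane + vinca-alkaloid combo with within-line synergy.

    All three lines are moderately sensitive to both drugs at the scenario's
    low doses, and the within-line combination follows the multiplicative
    viability rule, so the combo out-inhibits both monotherapies in every
    component line as well as in the mixture.  Dose-response curves here are
    scenario-local (a low-dose assay window), independent of the cohort
    preset's single-dose curves.
    """
    if config is None:
        config = unstratified_crpc(seed=seed, n_genes=2000)
    params = growth_params(config, combo_model="bliss")
    dose_response = {}
    for line, (va, vb) in _SYNERGY_TARGETS.items():
        dose_response[line] = {
            DRUG_DOCETAXEL: HillParams(
                hill_ic50_for_viability(va, _SYNERGY_DOSE_A, _HILL_SLOPE, _EMAX),
                _HILL_SLOPE,
                _EMAX,
            ),
            DRUG_VINORELBINE: HillParams(
                hill_ic50_for_viability(vb, _SYNERGY_DOSE_B, _HILL_SLOPE, _EMAX),
                _HILL_SLOPE,
                _EMAX,
            ),
        }
    params = GrowthParams(
        doubling_time=dict(params.doubling_time),
        cell_area=dict(params.cell_area),
        capacity=params.capacity,
        combo_model="bliss",
        dose_response=dose_response,
    )
    return ComboScenario(
        params=params,
        seeding=mixture_seeding(params),
        treatments=combo_treatments(
            DRUG_DOCETAXEL, _SYNERGY_DOSE_A, DRUG_VINORELBINE, _SYNERGY_DOSE_B
        ),
        drug_a=DRUG_DOCETAXEL,
        dose_a=_SYNERGY_DOSE_A,
        drug_b=DRUG_VINORELBINE,
        dose_b=_SYNERGY_DOSE_B,
    )
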