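"""Synthetic feature tables with the statistical structure of a multi-year,
multi-site grape-berry survey.

The generator emulates a 7-vineyard (3-macrozone) x 3-vintage x 3-stage x
3-replicate design (189 samples) of untargeted LC-MS intensities, or a
63-sample GC-MS-like preset (single stage, 48 features). Intensities follow
a log-normal model: on the natural-log scale each feature's signal is

    baseline + stage trend + vintage effect + macrozone effect
             + vineyard-within-macrozone effect + N(0, noise_sd)

with each effect drawn once per (feature, level) and carried only by a
stated fraction of features. The matrix is exponentiated to positive
intensities and multiplied by a per-sample dilution factor (log-uniform in
[0.5, 2]) so that median fold change normalization has something to remove.

The default regime is the *confounded* one: the vintage effect standard
deviation is three times the macrozone's, so unsupervised structure
clusters by vintage, not geography — the situation the orthogonal
constraint exists to fix. Every drawn effect is stored in a truth record so
recovery tests can query what was planted instead of re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import FeatureAnnotation, FeatureTable, MACROZONE_OF_VINEYARD, StudyDesign

__all__ = ["SyntheticSpec", "generate_design", "generate_metabolome",
           "confounded_scenario", "PRESETS"]

VINEYARDS = tuple(MACROZONE_OF_VINEYARD)  # AM BA BM CS FA MN PM order of dict
VINTAGES = (2006, 2007, 2008)
STAGES = (1, 2, 3)


@dataclass
class SyntheticSpec:
    """Variance components, design counts and noise model of the generator.

    Effect standard deviations are on the natural-log scale (0.25 is about
    a 25 % coefficient of variation). Defaults put the vintage effect at
    three times the macrozone effect — the confounded regime the analysis
    is built for. Fractions give the share of features carrying each
    effect; the vintage and producer shares follow the proportions of
    features a univariate screen is expected to flag.
    """

    n_features: int = 551
    vintages: tuple = VINTAGES
    stages: tuple = STAGES
    replicates: int = 3
    vineyards: tuple = VINEYARDS
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    stage_sd: float = 0.5
    vintage_sd: float = 0.75
    macrozone_sd: float = 0.25
    vineyard_sd: float = 0.20
    noise_sd: float = 0.35
    frac_stage: float = 0.6
    frac_vintage: float = 0.67
    frac_macrozone: float = 0.5
    frac_vineyard: float = 0.69
    dilution: bool = True
    dilution_range: tuple = (0.5, 2.0)
    marker_groups: tuple = (
        # (group name, number of features, macrozone elevated, log-effect)
        ("AC1", 6, "Valpolicella", 0.7),
        ("ST1", 6, "LakeGarda", 0.7),
        ("FLAV1", 6, "Soave", 0.7),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stage_sd", "vintage_sd", "macrozone_sd", "vineyard_sd",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_stage", "frac_vintage", "frac_macrozone",
                     "frac_vineyard"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def generate_design(spec: SyntheticSpec) -> StudyDesign:
    """Full factorial vineyard x vintage x stage x replicate design."""
    rows = []
    for vy in spec.vineyards:
        for vt in spec.vintages:
            for st in spec.stages:
                for r in range(1, spec.replicates + 1):
                    rows.append(
                        {
                            "sample": f"{vy}_{vt}_s{st}_r{r}",
                            "vineyard": vy,
                            "vintage": vt,
                            "stage": st,
                            "replicate": r,
                        }
                    )
    df = pd.DataFrame(rows).set_index("sample")
    return StudyDesign(df)


def generate_metabolome(
    spec: SyntheticSpec,
) -> tuple[FeatureTable, StudyDesign, dict]:
    """Generate (table, design, truth) under the spec's variance components.

    The truth record stores every drawn effect keyed by factor, the carrier
    masks, the per-sample dilution factors and the marker-group membership,
    so downstream recovery tests never need to re-derive them.
    """
    rng = np.random.default_rng(spec.seed)
    design = generate_design(spec)
    n = len(design.samples)
    p = spec.n_features
    feats = [f"F{j + 1:04d}" for j in range(p)]

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=p)
    carries = {
        "stage": rng.random(p) < spec.frac_stage,
        "vintage": rng.random(p) < spec.frac_vintage,
        "macrozone": rng.random(p) < spec.frac_macrozone,
        "vineyard": rng.random(p) < spec.frac_vineyard,
    }
    # stage trend: monotone per feature, random sign and magnitude
    stage_slope = (
        np.abs(rng.normal(0, spec.stage_sd, size=p))
        * rng.choice([-1.0, 1.0], size=p)
        * carries["stage"]
    )
    vintage_eff = {
        vt: rng.normal(0, spec.vintage_sd, size=p) * carries["vintage"]
        for vt in spec.vintages
    }
    zones = sorted(set(MACROZONE_OF_VINEYARD[v] for v in spec.vineyards))
    zone_eff = {
        z: rng.normal(0, spec.macrozone_sd, size=p) * carries["macrozone"]
        for z in zones
    }
    viney_eff = {
        vy: rng.normal(0, spec.vineyard_sd, size=p) * carries["vineyard"]
        for vy in spec.vineyards
    }
    # planted marker groups: disjoint feature blocks elevated in one macrozone
    group_members: dict[str, list] = {}
    cursor = 0
    for gname, gsize, gzone, geff in spec.marker_groups:
        members = list(range(cursor, min(cursor + gsize, p)))
        cursor += gsize
        group_members[gname] = [feats[j] for j in members]
        for j in members:
            zone_eff[gzone][j] += geff

    log_signal = np.tile(baseline, (n, 1))
    stage_center = np.mean(spec.stages)
    for i, s in enumerate(design.samples):
        row = design.table.loc[s]
        log_signal[i] += stage_slope * (row["stage"] - stage_center)
        log_signal[i] += vintage_eff[row["vintage"]]
        log_signal[i] += zone_eff[row["macrozone"]]
        log_signal[i] += viney_eff[row["vineyard"]]
    log_signal += rng.normal(0, spec.noise_sd, size=(n, p))
    X = np.exp(log_signal)
    if spec.dilution:
        lo, hi = np.log(spec.dilution_range[0]), np.log(spec.dilution_range[1])
        dil = np.exp(rng.uniform(lo, hi, size=n))
    else:
        dil = np.ones(n)
    X = X * dil[:, None]
    table = FeatureTable(pd.DataFrame(X, index=design.samples, columns=feats))
    truth = {
        "baseline": baseline,
        "carries": carries,
        "stage_slope": stage_slope,
        "vintage_effect": vintage_eff,
        "macrozone_effect": zone_eff,
        "vineyard_effect": viney_eff,
        "dilution": pd.Series(dil, index=design.samples),
        "marker_groups": group_members,
        "spec": spec,
    }
    return table, design, truth


def annotation_from_truth(truth: dict, features: list) -> FeatureAnnotation:
    """Feature annotation naming the planted marker groups (synthetic)."""
    group_of = {}
    for g, members in truth["marker_groups"].items():
        for f in members:
            group_of[f] = g
    df = pd.DataFrame(
        {
            "chemical_class": [group_of.get(f, "unassigned") for f in features],
            "marker_group": [group_of.get(f, pd.NA) for f in features],
            "internal_standard_key": "d13-hexanol",
        },
        index=features,
    )
    return FeatureAnnotation(df)


PRESETS = {
    "strong_vintage": {},  # the defaults: vintage_sd = 3 x macrozone_sd
    "no_vintage": {"vintage_sd": 0.0},
    "null": {
        "stage_sd": 0.0,
        "vintage_sd": 0.0,
        "macrozone_sd": 0.0,
        "vineyard_sd": 0.0,
        "frac_stage": 0.0,
        "frac_vintage": 0.0,
        "frac_macrozone": 0.0,
        "frac_vineyard": 0.0,
        "marker_groups": (),
    },
    "gcms": {"n_features": 48, "stages": (3,), "dilution": False},
}


def confounded_scenario(
    preset: str, seed: int = 0, **overrides
) -> tuple[FeatureTable, StudyDesign, dict]:
    """Ready-made generator presets for the headline experiments.

    ``strong_vintage`` is the default confounded regime, ``no_vintage``
    removes the vintage effect, ``null`` has no planted effects at all, and
    ``gcms`` is the single-stage 63 x 48 volatile-metabolite layout.
    """
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    spec = SyntheticSpec(seed=seed, **{**PRESETS[preset], **overrides})
    return generate_metabolome(spec)
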