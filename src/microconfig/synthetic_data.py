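"""Synthetic cohort generation with planted structure.

The generator emulates a three-group 16S study at the genus level: a control
group and a Crohn's-disease (CD) group, both with longitudinal replicates and
a two-study design, plus a hidradenitis-suppurativa (HS) group that is a
mixture of two microbiota configurations (a fraction carries a CD-like
community, the rest a control-like one).

Counts come from a log-normal latent-factor model: genera belong to k
co-abundance blocks driven by shared per-sample latent factors (so planted
co-abundance structure is recoverable by clustering); configuration effects
shift a set of "normal-associated" genera down and "CD-associated" genera up
in CD-like communities; patient and study random effects give longitudinal
and batch structure.  Per-sample compositions are converted to multinomial
counts at a drawn sequencing depth.  Diet frequencies, binary drug covariates
(with planted odds ratios against configuration), demographics and
inflammatory markers (latently correlated with chosen genera) complete the
cohort.  Every planted quantity is recorded in a :class:`TruthRecord`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables_io import AbundanceTable

MARKER_IDS = (
    "IL-12", "IL-23", "IL-6", "TNFa", "leptin", "adiponectin",
    "CRP", "C5a", "Gas6", "faecal_calprotectin",
)

NORMAL_CONFIG = "normal"
CD_CONFIG = "cd_like"


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    The defaults reproduce the shape of the pooled study population: 95
    control patients with 164 samples, 102 CD patients with 212 samples, 55
    HS patients with one sample each, of whom an expected 40% carry the
    CD-like configuration.  Genus count, block structure and effect sizes are
    design choices documented in the methods note.
    """

    n_control_patients: int = 95
    n_control_samples: int = 164
    n_cd_patients: int = 102
    n_cd_samples: int = 212
    n_hs: int = 55
    n_genera: int = 120
    n_blocks: int = 4
    block_corr: float = 0.7            # within-block latent correlation
    n_config_genera: int = 30          # genera shifted per direction
    config_effect: float = 2.5         # log-fold shift (natural log)
    pathogen_base_shift: float = -1.5  # pathogens are rare in healthy communities
    commensal_base_shift: float = 0.5  # config-informative commensals are common
    hs_cd_fraction: float = 0.4
    depth_mean: float = 20000.0
    depth_sigma: float = 0.35
    min_depth: int = 1000
    base_logmean_sd: float = 1.5
    latent_sd: float = 0.5
    patient_sd: float = 0.25
    study_sd: float = 0.2
    control_study_a_fraction: float = 0.4
    n_food_items: int = 40
    n_western_items: int = 10
    diet_shift: float = 1.0            # log-SD units added to western items in CD/HS
    diet_noise_sd: float = 0.6
    consumption_prob: float = 0.85
    soft_drink_config_shift: float = 1.0
    antibiotics_or: float = 4.0        # odds ratio of antibiotics given CD-like config
    cardio_or: float = 0.25            # cardiovascular drugs: lower in CD-like
    age_shift_nm: float = 8.0          # years added to normal-configuration HS patients
    marker_coupling: float = 0.6       # latent correlation of coupled markers
    marker_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("block_corr", "hs_cd_fraction", "consumption_prob",
                     "control_study_a_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.marker_coupling <= 1.0:
            raise ValueError("marker_coupling must be in [-1, 1]")
        if 2 * self.n_config_genera > self.n_genera:
            raise ValueError("configuration genus sets larger than n_genera")
        if self.n_blocks < 1 or self.n_blocks > self.n_genera:
            raise ValueError("n_blocks outside [1, n_genera]")
        if self.n_control_samples < self.n_control_patients:
            raise ValueError("fewer control samples than patients")
        if self.n_cd_samples < self.n_cd_patients:
            raise ValueError("fewer CD samples than patients")
        if self.n_western_items > self.n_food_items:
            raise ValueError("more western items than food items")


@dataclass
class TruthRecord:
    """Every planted quantity of a generated cohort."""

    configuration: pd.Series           # per-sample true configuration
    genus_block: pd.Series             # per-genus co-abundance block (1..k)
    normal_genera: list
    cd_genera: list
    covariate_odds_ratios: dict        # exposure -> planted OR vs CD-like config
    marker_couplings: list             # (marker, genus or set name, latent corr)
    diet_shifted_items: list
    depths: pd.Series                  # drawn sequencing depth per sample
    spec: CohortSpec


@dataclass
class Cohort:
    abundance: AbundanceTable          # counts mode
    metadata: pd.DataFrame
    diet: pd.DataFrame
    markers: pd.DataFrame              # HS samples only; NaN elsewhere dropped
    truth: TruthRecord

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.abundance.to_tsv(directory / "abundance.tsv")
        self.metadata.to_csv(directory / "metadata.tsv", sep="\t",
                             index_label="sample_id")
        self.diet.to_csv(directory / "diet.tsv", sep="\t", index_label="sample_id")
        self.markers.to_csv(directory / "markers.tsv", sep="\t",
                            index_label="sample_id")
        truth = self.truth.configuration.rename("configuration").to_frame()
        truth.to_csv(directory / "truth_configuration.tsv", sep="\t",
                     index_label="sample_id")


def _assign_samples(rng, prefix, n_patients, n_samples):
    """Patient ids and per-sample patient assignment with longitudinal extras."""
    patients = [f"{prefix}P{i:03d}" for i in range(n_patients)]
    owner = list(patients)  # every patient has >= 1 sample
    extra = n_samples - n_patients
    if extra:
        owner += [patients[i] for i in rng.integers(0, n_patients, size=extra)]
    owner.sort()
    sample_ids = []
    seen: dict[str, int] = {}
    for p in owner:
        seen[p] = seen.get(p, 0) + 1
        sample_ids.append(f"{p}_t{seen[p]}")
    return patients, sample_ids, owner


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> Cohort:
    """Generate one synthetic cohort with planted structure (see module docs)."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    genus_ids = [f"Genus_{i:03d}" for i in range(spec.n_genera)]
    block = np.repeat(np.arange(spec.n_blocks), int(np.ceil(spec.n_genera / spec.n_blocks)))
    block = block[: spec.n_genera]
    genus_block = pd.Series(block + 1, index=genus_ids, name="block")

    # configuration genus sets: normal-associated genera from the first two
    # blocks, CD-associated from the last two (pathogen-like) blocks
    normal_pool = [g for g, b in zip(genus_ids, block) if b < spec.n_blocks / 2]
    cd_pool = [g for g, b in zip(genus_ids, block) if b >= spec.n_blocks / 2]
    normal_genera = normal_pool[: spec.n_config_genera]
    cd_genera = cd_pool[: spec.n_config_genera]
    effect = np.zeros(spec.n_genera)
    gi = {g: i for i, g in enumerate(genus_ids)}
    for g in normal_genera:
        effect[gi[g]] = -spec.config_effect
    for g in cd_genera:
        effect[gi[g]] = +spec.config_effect

    # sample frame -------------------------------------------------------
    ctrl_p, ctrl_s, ctrl_owner = _assign_samples(
        rng, "C", spec.n_control_patients, spec.n_control_samples)
    cd_p, cd_s, cd_owner = _assign_samples(rng, "D", spec.n_cd_patients,
                                           spec.n_cd_samples)
    hs_p, hs_s, hs_owner = _assign_samples(rng, "H", spec.n_hs, spec.n_hs)

    sample_ids = ctrl_s + cd_s + hs_s
    owners = ctrl_owner + cd_owner + hs_owner
    groups = (["control"] * len(ctrl_s) + ["CD"] * len(cd_s) + ["HS"] * len(hs_s))

    # study assignment: HS from study_A; controls split; CD from study_B
    ctrl_study = {p: ("study_A" if rng.random() < spec.control_study_a_fraction
                      else "study_B") for p in ctrl_p}
    study = ([ctrl_study[p] for p in ctrl_owner]
             + ["study_B"] * len(cd_s) + ["study_A"] * len(hs_s))

    # configuration: patient-level
    hs_config = {p: (CD_CONFIG if rng.random() < spec.hs_cd_fraction else NORMAL_CONFIG)
                 for p in hs_p}
    config = ([NORMAL_CONFIG] * len(ctrl_s) + [CD_CONFIG] * len(cd_s)
              + [hs_config[p] for p in hs_owner])
    config = pd.Series(config, index=sample_ids, name="configuration")

    n = len(sample_ids)
    is_cd_like = (config == CD_CONFIG).to_numpy(dtype=float)

    # abundance ----------------------------------------------------------
    base = rng.normal(0.0, spec.base_logmean_sd, size=spec.n_genera)
    for g in normal_genera:
        base[gi[g]] += spec.commensal_base_shift
    for g in cd_genera:
        base[gi[g]] += spec.pathogen_base_shift
    study_eff = {s: rng.normal(0.0, spec.study_sd, size=spec.n_genera)
                 for s in ("study_A", "study_B")}
    all_patients = ctrl_p + cd_p + hs_p
    patient_eff = {p: rng.normal(0.0, spec.patient_sd, size=spec.n_genera)
                   for p in all_patients}

    z_block = rng.normal(size=(n, spec.n_blocks))
    eps = rng.normal(size=(n, spec.n_genera))
    latent = (np.sqrt(spec.block_corr) * z_block[:, block]
              + np.sqrt(1.0 - spec.block_corr) * eps)

    log_intensity = (
        base[None, :]
        + spec.latent_sd * latent
        + is_cd_like[:, None] * effect[None, :]
        + np.array([patient_eff[p] for p in owners])
        + np.array([study_eff[s] for s in study])
    )
    log_intensity -= log_intensity.max(axis=1, keepdims=True)
    probs = np.exp(log_intensity)
    probs /= probs.sum(axis=1, keepdims=True)

    depths = np.maximum(
        rng.lognormal(np.log(spec.depth_mean), spec.depth_sigma, size=n).astype(int),
        spec.min_depth,
    )
    counts = rng.multinomial(depths, probs)
    abundance = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=genus_ids), mode="counts")
    rel = counts / counts.sum(axis=1, keepdims=True)

    # diet ---------------------------------------------------------------
    food_ids = ["carbonated_soft_drinks"] + [f"food_{i:02d}"
                                             for i in range(1, spec.n_food_items)]
    western = food_ids[: spec.n_western_items]
    diet_base = rng.normal(0.0, 0.5, size=spec.n_food_items)
    in_disease = np.isin(groups, ["CD", "HS"]).astype(float)
    shift = np.zeros((n, spec.n_food_items))
    west_idx = np.arange(spec.n_western_items)
    shift[:, west_idx] += (in_disease[:, None]
                           * spec.diet_shift * spec.diet_noise_sd)
    # soft drinks additionally track the CD-like configuration (HS sub-structure)
    shift[:, 0] += is_cd_like * spec.soft_drink_config_shift * spec.diet_noise_sd
    log_freq = (diet_base[None, :] + shift
                + rng.normal(0.0, spec.diet_noise_sd, size=(n, spec.n_food_items)))
    consumed = rng.random((n, spec.n_food_items)) < spec.consumption_prob
    diet = pd.DataFrame(np.where(consumed, np.exp(log_freq), 0.0),
                        index=sample_ids, columns=food_ids).round(3)

    # covariates ---------------------------------------------------------
    def bernoulli_logit(base_p: float, odds_ratio: float) -> np.ndarray:
        logit = np.log(base_p / (1 - base_p)) + np.log(odds_ratio) * is_cd_like
        return rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    antibiotics = bernoulli_logit(0.35, spec.antibiotics_or)
    cardio = bernoulli_logit(0.35, spec.cardio_or)
    current_abx = rng.random(n) < 0.15
    surgery = rng.random(n) < 0.30
    anti_tnf_cur = rng.random(n) < 0.20
    anti_tnf_prev = rng.random(n) < 0.20
    immunomod = rng.random(n) < 0.15

    patient_age = {p: rng.normal(40.0, 12.0) for p in all_patients}
    age = np.array([patient_age[p] for p in owners])
    is_hs = np.array([g == "HS" for g in groups])
    age = age + np.where(is_hs & (is_cd_like == 0), spec.age_shift_nm, 0.0)
    age = np.clip(age, 18.0, 85.0)
    age_at_dx = np.where(is_hs | np.array([g == "CD" for g in groups]),
                         np.clip(age - rng.uniform(2.0, 15.0, size=n), 16.0, None),
                         np.nan)
    hurley = np.where(is_hs, rng.integers(1, 4, size=n), np.nan)
    gender = rng.choice(["F", "M"], size=n)

    metadata = pd.DataFrame({
        "patient_id": owners,
        "group": groups,
        "study": study,
        "age": np.round(age, 1),
        "age_at_diagnosis": np.round(age_at_dx, 1),
        "hurley": hurley,
        "gender": gender,
        "antibiotics_last_year": antibiotics,
        "current_antibiotics": current_abx,
        "cardiovascular_drugs": cardio,
        "surgery": surgery,
        "anti_tnf_current": anti_tnf_cur,
        "anti_tnf_previous": anti_tnf_prev,
        "immunomodulator": immunomod,
    }, index=pd.Index(sample_ids, name="sample_id"))

    # inflammatory markers (HS samples) ----------------------------------
    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    hs_mask = is_hs
    hs_ids = [s for s, m in zip(sample_ids, hs_mask) if m]
    rel_hs = rel[hs_mask]
    normal_sum = (rel_hs[:, [gi[g] for g in normal_genera]].sum(axis=1)
                  if hs_ids else np.zeros(0))
    couplings = [
        ("IL-12", normal_genera[0], -spec.marker_coupling),
        ("Gas6", "normal_set_sum", +spec.marker_coupling),
        ("IL-23", cd_genera[0], +spec.marker_coupling),
        ("C5a", cd_genera[1], +spec.marker_coupling),
        ("faecal_calprotectin", cd_genera[2], +spec.marker_coupling),
        ("adiponectin", normal_genera[1], +spec.marker_coupling),
    ]
    coupled = {m: (g, r) for m, g, r in couplings}
    marker_rows = {}
    for marker in MARKER_IDS:
        noise = rng.normal(0.0, 1.0, size=len(hs_ids))
        if hs_ids and marker in coupled and spec.marker_coupling != 0.0:
            target, r = coupled[marker]
            pred = normal_sum if target == "normal_set_sum" else rel_hs[:, gi[target]]
            y = r * zscore(pred) + np.sqrt(max(1.0 - r**2, 0.0)) * noise
        else:
            y = noise
        # positive assay-scale concentrations
        marker_rows[marker] = np.round(np.exp(2.0 + spec.marker_noise_sd * y), 3)
    markers = pd.DataFrame(marker_rows, index=pd.Index(hs_ids, name="sample_id"))

    truth = TruthRecord(
        configuration=config,
        genus_block=genus_block,
        normal_genera=normal_genera,
        cd_genera=cd_genera,
        covariate_odds_ratios={
            "antibiotics_last_year": spec.antibiotics_or,
            "cardiovascular_drugs": spec.cardio_or,
        },
        marker_couplings=[(m, g, r) for m, g, r in couplings
                          if spec.marker_coupling != 0.0],
        diet_shifted_items=western if spec.diet_shift else [],
        depths=pd.Series(depths, index=sample_ids, name="depth"),
        spec=spec,
    )
    return Cohort(abundance=abundance, metadata=metadata, diet=diet,
                  markers=markers, truth=truth)


def null_spec(spec: CohortSpec | None = None) -> CohortSpec:
    """Copy of ``spec`` with every planted coupling zeroed."""
    spec = spec or CohortSpec()
    return replace(
        spec,
        config_effect=0.0,
        diet_shift=0.0,
        soft_drink_config_shift=0.0,
        antibiotics_or=1.0,
        cardio_or=1.0,
        age_shift_nm=0.0,
        marker_coupling=0.0,
    )


def generate_null_cohort(spec: CohortSpec | None = None,
                         seed: int | None = None) -> Cohort:
    """Cohort with identical shape but all group/configuration couplings zeroed."""
    return generate_cohort(null_spec(spec), seed=seed)


def small_spec(**overrides) -> CohortSpec:
    """A reduced cohort for calibration runs and fast tests: two balanced
    single-sample-per-patient groups, fewer genera, shallower depth."""
    defaults = dict(
        n_control_patients=30, n_control_samples=30,
        n_cd_patients=30, n_cd_samples=30,
        n_hs=0, n_genera=80, depth_mean=5000.0, min_depth=500,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)
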