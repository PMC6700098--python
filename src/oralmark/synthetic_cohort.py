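"""Synthetic discovery/validation cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
compositional 16S count data (Dirichlet-multinomial) at realistic depth
with a handful of planted "oral" taxa enriched under PPI exposure, a
validation cohort resampled from the same subjects one interval later with
a fraction of exposure switchers, liver-severity scores confounded with
exposure, exponential liver-related mortality over a 36-month window, and
log-normal gut-barrier markers shifted in dysbiotic subjects.

Every draw flows from one seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .otu_preprocess import OtuTable, write_otu_table

__all__ = ["SimulationConfig", "GroundTruth", "Cohort",
           "generate_cohort", "generate_markers", "write_fixture"]

PLANTED_LINEAGES = [
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
    "f__Streptococcaceae; g__Streptococcus; s__salivarius",
    "k__Bacteria; p__Firmicutes; c__Negativicutes; o__Veillonellales; "
    "f__Veillonellaceae; g__Veillonella; s__parvula",
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
    "f__Streptococcaceae; g__Streptococcus; s__parasanguinis",
]

BACKGROUND_FAMILIES = [
    ("f__Lachnospiraceae", "g__Blautia"),
    ("f__Ruminococcaceae", "g__Faecalibacterium"),
    ("f__Ruminococcaceae", "g__Subdoligranulum"),
    ("f__Bacteroidaceae", "g__Bacteroides"),
    ("f__Porphyromonadaceae", "g__Parabacteroides"),
    ("f__Enterobacteriaceae", "g__Escherichia-Shigella"),
    ("f__Enterococcaceae", "g__Enterococcus"),
    ("f__Micrococcaceae", "g__Rothia"),
    ("f__Staphylococcaceae", "g__Staphylococcus"),
    ("f__Prevotellaceae", "g__Prevotella"),
]


@dataclass
class SimulationConfig:
    """Study-shaped scenario parameters (counts, rates, effect sizes).

    The default scenario: 50 PPI users and 40 non-users at discovery, 68
    subjects resampled after one year as the validation cohort, 10% of them
    switching PPI status between samplings, and a 36-month mortality
    window.
    """

    # cohort shape
    n_ppi: int = 50
    n_noppi: int = 40
    n_validation: int = 68
    switch_fraction: float = 0.10
    # composition model
    m_taxa: int = 200
    n_planted_oral: int = 3
    fold_change: float = 8.0
    susceptible_fraction: float = 1.0   # fraction of PPI users truly dysbiotic
    depth_min: int = 20_000
    depth_max: int = 60_000
    base_sigma: float = 2.0             # log-normal spread of the mean profile
    planted_base_abundance: float = 0.005
    theta: float = 50.0                 # Dirichlet concentration (overdispersion)
    # severity / confounding
    meld_mean: float = 11.0
    meld_sd: float = 3.0
    meld_ppi_shift: float = 1.0         # gamma: exposure-severity confounding
    # hazard model (monthly); baseline at Child-Pugh 6, MELD 11, no dysbiosis.
    # lambda0 is set so the default scenario yields ~2% three-year liver
    # mortality without PPI, ~18% with, ~10% overall.
    lambda0: float = 0.0004
    hr_dysbiosis: float = 8.0
    hr_no_dysbiosis: float = 1.0
    beta_child_pugh: float = float(np.log(1.6))
    beta_meld: float = float(np.log(1.05))
    random_censor_rate: float = 0.005   # monthly; transplant / lost to follow-up
    horizon_months: float = 36.0
    # barrier markers: log-normal, dysbiotic location shifted by delta_sd sds
    marker_medians: dict = field(
        default_factory=lambda: {"calprotectin": 20.0, "zonulin": 70.0, "lps": 0.5}
    )
    marker_sigmas: dict = field(
        default_factory=lambda: {"calprotectin": 1.3, "zonulin": 0.45, "lps": 1.2}
    )
    delta_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if not 0 <= self.switch_fraction <= 1:
            raise ValueError("switch_fraction must lie in [0, 1]")
        if not 0 <= self.susceptible_fraction <= 1:
            raise ValueError("susceptible_fraction must lie in [0, 1]")
        if self.n_validation > self.n_ppi + self.n_noppi:
            raise ValueError("validation cohort cannot exceed the subject pool")
        if self.depth_min < self.m_taxa:
            raise ValueError("depth range infeasible for the number of taxa")
        if self.n_planted_oral > self.m_taxa:
            raise ValueError("cannot plant more taxa than exist")
        if self.planted_base_abundance * self.n_planted_oral >= 1:
            raise ValueError("planted base abundance must leave room for the rest")


@dataclass
class GroundTruth:
    planted_taxon_ids: list[str]
    true_dysbiosis: dict[str, bool]     # subject -> truly dysbiotic
    hr_dysbiosis: float
    hr_no_dysbiosis: float
    seed: int


@dataclass
class Cohort:
    table: OtuTable                     # discovery + validation samples
    metadata: pd.DataFrame              # one row per sample
    truth: GroundTruth

    def sample_ids(self, cohort: str) -> list[str]:
        return self.metadata.loc[
            self.metadata["cohort"] == cohort, "sample_id"
        ].tolist()


def _taxon_catalogue(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    ids, lineages = [], []
    for i in range(cfg.m_taxa):
        ids.append(f"OTU_{i + 1:04d}")
        if i < cfg.n_planted_oral:
            lineages.append(PLANTED_LINEAGES[i % len(PLANTED_LINEAGES)])
        else:
            fam, gen = BACKGROUND_FAMILIES[i % len(BACKGROUND_FAMILIES)]
            lineages.append(
                "k__Bacteria; p__Bacteria_p; c__c; o__o; "
                f"{fam}; {gen}; s__sp{i + 1}"
            )
    return ids, lineages


def _base_profile(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    raw = rng.lognormal(mean=0.0, sigma=cfg.base_sigma, size=cfg.m_taxa)
    raw[: cfg.n_planted_oral] = 0.0
    raw = raw / raw.sum() * (1 - cfg.planted_base_abundance * cfg.n_planted_oral)
    raw[: cfg.n_planted_oral] = cfg.planted_base_abundance
    return raw


def _subject_profile(base: np.ndarray, enriched: bool, cfg: SimulationConfig
                     ) -> np.ndarray:
    if not enriched:
        return base
    prof = base.copy()
    prof[: cfg.n_planted_oral] *= cfg.fold_change
    return prof / prof.sum()


def _draw_sample(profile: np.ndarray, cfg: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    depth = int(np.exp(rng.uniform(np.log(cfg.depth_min), np.log(cfg.depth_max))))
    props = rng.dirichlet(cfg.theta * profile)
    return rng.multinomial(depth, props)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic study: counts, clinical metadata, truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_ppi + cfg.n_noppi
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    ppi = np.array([True] * cfg.n_ppi + [False] * cfg.n_noppi)

    # severity, confounded with exposure
    meld = rng.normal(cfg.meld_mean + cfg.meld_ppi_shift * ppi, cfg.meld_sd)
    meld = np.clip(meld, 6.0, 30.0).round(1)
    child_pugh = np.clip(
        np.rint(5 + 0.4 * (meld - 9) + rng.normal(0, 0.8, n)), 5, 11
    ).astype(int)

    # true dysbiosis: susceptible PPI users carry the oralization signal
    susceptible = rng.random(n) < cfg.susceptible_fraction
    dysbiotic = ppi & susceptible

    taxon_ids, lineages = _taxon_catalogue(cfg)
    base = _base_profile(cfg, rng)

    # discovery samples
    columns, sample_rows = [], []
    for i, subj in enumerate(subjects):
        prof = _subject_profile(base, dysbiotic[i], cfg)
        columns.append(_draw_sample(prof, cfg, rng))
        sample_rows.append((f"{subj}_d", subj, "discovery", bool(ppi[i])))

    # validation: a subset of subjects resampled; some switch exposure
    val_idx = np.sort(rng.choice(n, size=cfg.n_validation, replace=False))
    n_switch = int(round(cfg.switch_fraction * cfg.n_validation))
    switch_idx = set(rng.choice(val_idx, size=n_switch, replace=False).tolist())
    ppi_val = ppi.copy()
    for i in switch_idx:
        ppi_val[i] = not ppi_val[i]
    for i in val_idx:
        subj = subjects[i]
        enriched = ppi_val[i] and susceptible[i]
        prof = _subject_profile(base, enriched, cfg)
        columns.append(_draw_sample(prof, cfg, rng))
        sample_rows.append((f"{subj}_v", subj, "validation", bool(ppi_val[i])))

    counts = np.column_stack(columns).astype(np.int64)
    table = OtuTable(taxon_ids, lineages, [r[0] for r in sample_rows], counts)

    # survival: exponential with subject-specific hazard, admin-censored at 36m
    log_mult = (cfg.beta_child_pugh * (child_pugh - 6)
                + cfg.beta_meld * (meld - 11)
                + np.where(dysbiotic, np.log(cfg.hr_dysbiosis),
                           np.where(ppi, np.log(cfg.hr_no_dysbiosis), 0.0)))
    lam = cfg.lambda0 * np.exp(log_mult)
    death_t = rng.exponential(1 / lam)
    if cfg.random_censor_rate > 0:
        cens_t = rng.exponential(1 / cfg.random_censor_rate, size=n)
    else:
        cens_t = np.full(n, np.inf)
    followup = np.minimum(np.minimum(death_t, cens_t), cfg.horizon_months)
    event = np.where(death_t <= np.minimum(cens_t, cfg.horizon_months),
                     "liver_death", "censored")
    reason = np.where(
        event == "liver_death", "",
        np.where(cens_t < cfg.horizon_months,
                 np.where(rng.random(n) < 0.5, "transplant", "lost"),
                 "alive_end"),
    )

    truth = GroundTruth(
        planted_taxon_ids=taxon_ids[: cfg.n_planted_oral],
        true_dysbiosis={s: bool(d) for s, d in zip(subjects, dysbiotic)},
        hr_dysbiosis=cfg.hr_dysbiosis,
        hr_no_dysbiosis=cfg.hr_no_dysbiosis,
        seed=cfg.seed,
    )

    markers = generate_markers(truth, cfg, rng, subjects)

    subj_info = {
        s: {
            "child_pugh": int(child_pugh[i]),
            "meld": float(meld[i]),
            "followup_months": float(round(followup[i], 2)),
            "event": event[i],
            "censor_reason": reason[i],
        }
        for i, s in enumerate(subjects)
    }
    meta_rows = []
    for sid, subj, coh, use in sample_rows:
        info = subj_info[subj]
        meta_rows.append(
            {
                "sample_id": sid,
                "subject_id": subj,
                "cohort": coh,
                "ppi_use": use,
                **{k: info[k] for k in ("child_pugh", "meld", "followup_months",
                                        "event", "censor_reason")},
                **{m: markers[m][subj] for m in markers},
            }
        )
    metadata = pd.DataFrame(meta_rows)
    return Cohort(table=table, metadata=metadata, truth=truth)


def generate_markers(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    subjects: list[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Log-normal barrier markers; dysbiotic subjects shifted by delta_sd sds.

    With ``delta_sd = 0`` the groups are exchangeable by construction.
    """
    subjects = subjects or list(truth.true_dysbiosis)
    out: dict[str, dict[str, float]] = {}
    for marker, med in config.marker_medians.items():
        sigma = config.marker_sigmas[marker]
        vals = {}
        for s in subjects:
            shift = config.delta_sd * sigma if truth.true_dysbiosis[s] else 0.0
            vals[s] = float(round(rng.lognormal(np.log(med) + shift, sigma), 2))
        out[marker] = vals
    return out


def write_fixture(cohort: Cohort, out_dir: str | Path, format: str = "tsv") -> dict:
    """Write the cohort in the exact formats the analysis readers consume.

    The ground truth goes to a separate JSON file that no analysis stage
    reads — it exists only so tests can check recovery.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_path = out / ("otu_table.biom" if format == "biom" else "otu_table.tsv")
    write_otu_table(cohort.table, table_path, format=format)
    meta_path = out / "metadata.csv"
    cohort.metadata.to_csv(meta_path, index=False)
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(dataclasses.asdict(cohort.truth), indent=2))
    return {"otu_table": table_path, "metadata": meta_path,
            "ground_truth": truth_path}
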