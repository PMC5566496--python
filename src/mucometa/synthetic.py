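"""Synthetic cohort generator.

Produces paired genus-level OTU tables, 1D 1H MAS-NMR-like spectra, sample
metadata and qPCR Ct tables for a colorectal-cancer mucosal sampling design
(each patient biopsied on tumour and at 5 cm / 10 cm off tumour), together
with the ground truth used to plant every effect.  Every downstream stage of
the pipeline is testable against these known truths without any sequencing
or spectroscopy data.

Counts follow a Dirichlet-multinomial compositional model with patient-level
random effects and planted log-fold-change effects on covariates (site,
histology).  Spectra are sums of Lorentzian multiplets at literature chemical
shifts, scaled by per-sample concentrations, a per-sample log-normal dilution
factor, and additive Gaussian noise.  Ct values follow the exponential qPCR
model: Ct_target = Ct_pan - log2(copy ratio) + noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "OtuSimConfig",
    "MetaboliteTemplate",
    "SimTruth",
    "default_metabolite_templates",
    "default_otu_config",
    "simulate_metadata",
    "simulate_otu_table",
    "simulate_spectra",
    "simulate_qpcr",
]

SITES = ("tumour", "5cm", "10cm")

#: Typical 3-bond proton J-coupling at 400 MHz, in ppm (~7 Hz).
DEFAULT_J_PPM = 0.0175

PPM_LO, PPM_HI = -1.0, 10.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class CohortConfig:
    """Cohort design: who is sampled where, and histology prevalences.

    Prevalences default to the proportions of an 18-patient right-sided
    colon-cancer cohort: EMVI 5/18, LVI 6/18, PNVI 1/18, KRAS 2/18,
    differentiation well/moderate/poor = 1/11/6 and T stage 0..4 =
    3/1/1/5/8, N stage 0/1/2 = 11/4/3.
    """

    n_patients: int = 18
    sites: tuple[str, ...] = SITES
    seed: int = 0
    emvi_prevalence: float = 5 / 18
    lvi_prevalence: float = 6 / 18
    pnvi_prevalence: float = 1 / 18
    kras_prevalence: float = 2 / 18
    differentiation_probs: Mapping[str, float] = field(
        default_factory=lambda: {"well": 1 / 18, "moderate": 11 / 18, "poor": 6 / 18}
    )
    t_stage_probs: Mapping[int, float] = field(
        default_factory=lambda: {0: 3 / 18, 1: 1 / 18, 2: 1 / 18, 3: 5 / 18, 4: 8 / 18}
    )
    n_stage_probs: Mapping[int, float] = field(
        default_factory=lambda: {0: 11 / 18, 1: 4 / 18, 2: 3 / 18}
    )
    #: when True, T3/T4 tumours are biased towards poor differentiation
    associate_differentiation_with_t: bool = True

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if len(set(self.sites)) != len(self.sites):
            raise ConfigError("site labels must be unique")
        for name in ("emvi", "lvi", "pnvi", "kras"):
            p = getattr(self, f"{name}_prevalence")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} prevalence {p} outside [0, 1]")
        for probs, label in (
            (self.differentiation_probs, "differentiation"),
            (self.t_stage_probs, "T stage"),
            (self.n_stage_probs, "N stage"),
        ):
            vals = np.asarray(list(probs.values()), dtype=float)
            if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
                raise ConfigError(f"{label} probabilities must be a distribution")


@dataclass
class OtuSimConfig:
    """Compositional count model configuration.

    ``planted_effects`` entries are ``(taxon, covariate, log_fold_change)``
    where covariate is either ``"site=<label>"`` or the name of a binary
    metadata column (EMVI, LVI, PNVI, KRAS, poor_differentiation ...).
    """

    n_taxa: int = 60
    taxon_names: tuple[str, ...] = ()
    base_log_abundances: np.ndarray | None = None
    patient_effect_sd: float = 1.1
    planted_effects: tuple[tuple[str, str, float], ...] = ()
    depth_range: tuple[int, int] = (5_000, 50_000)
    overdispersion: float = 0.02

    def __post_init__(self) -> None:
        if not self.taxon_names:
            self.taxon_names = tuple(f"Genus_{i:03d}" for i in range(1, self.n_taxa + 1))
        if len(self.taxon_names) != self.n_taxa:
            raise ConfigError("taxon_names length must equal n_taxa")
        if self.base_log_abundances is None:
            # smoothly decaying baseline: a few dominant genera, a long tail
            self.base_log_abundances = np.linspace(3.0, -3.0, self.n_taxa)
        self.base_log_abundances = np.asarray(self.base_log_abundances, dtype=float)
        if self.base_log_abundances.shape != (self.n_taxa,):
            raise ConfigError("base_log_abundances must have one entry per taxon")
        if self.patient_effect_sd < 0:
            raise ConfigError("patient_effect_sd must be nonnegative")
        if self.depth_range[0] < self.n_taxa:
            raise ConfigError("minimum depth must be >= n_taxa")
        if self.depth_range[0] > self.depth_range[1]:
            raise ConfigError("depth_range must be (min, max) with min <= max")
        if self.overdispersion < 0:
            raise ConfigError("overdispersion must be nonnegative")
        for taxon, _, _ in self.planted_effects:
            if taxon not in self.taxon_names:
                raise ConfigError(f"planted effect refers to unknown taxon {taxon!r}")


@dataclass
class MetaboliteTemplate:
    """A metabolite's multiplet pattern and its tumour-vs-normal behaviour.

    ``peaks`` entries are ``(centre_ppm, multiplicity, j_spacing_ppm,
    rel_intensity)``; multiplicity 1/2/3/4 = singlet/doublet/triplet/quartet
    with 1 : 1:1 : 1:2:1 : 1:3:3:1 line ratios.  ``tumour_log_fc`` is the
    natural-log fold change of the metabolite's concentration on tumour.
    """

    name: str
    peaks: tuple[tuple[float, int, float, float], ...]
    linewidth_ppm: float = 0.0015
    tumour_log_fc: float = 0.0
    base_concentration: float = 1.0

    def __post_init__(self) -> None:
        for centre, mult, j, rel in self.peaks:
            if not PPM_LO <= centre <= PPM_HI:
                raise ConfigError(
                    f"{self.name}: peak centre {centre} ppm outside {PPM_LO}..{PPM_HI}"
                )
            if mult < 1 or rel <= 0 or (mult > 1 and j <= 0):
                raise ConfigError(f"{self.name}: invalid peak {(centre, mult, j, rel)}")
        if self.linewidth_ppm <= 0:
            raise ConfigError(f"{self.name}: linewidth must be positive")


@dataclass
class SimTruth:
    """Ground truth planted by a simulation step; one entry per sample."""

    sample_ids: list[str] = field(default_factory=list)
    class_labels: dict[str, str] = field(default_factory=dict)
    dilution_factors: dict[str, float] = field(default_factory=dict)
    concentrations: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    ct_copy_ratios: dict[str, float] = field(default_factory=dict)
    log_abundances: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def default_metabolite_templates() -> list[MetaboliteTemplate]:
    """Mucosal metabolite panel at literature 1H chemical shifts.

    Shifts and multiplicities follow standard tissue assignments (lactate
    doublet 1.33 / quartet 4.15, alanine doublet 1.47, taurine 3.26/3.42,
    lipid methyl/methylene envelopes ...).  Tumour log fold changes encode
    the qualitative tumour/normal directions: lactate, taurine, glycine,
    alanine, formate, isoglutamine and cholines up; lipid and triglyceride
    resonances down; creatine, leucine and valine unchanged.
    """
    J = DEFAULT_J_PPM
    t = MetaboliteTemplate
    return [
        t("acetate", ((1.92, 1, 0.0, 3.0),), tumour_log_fc=-0.15),
        t("alanine", ((1.47, 2, J, 3.0),), tumour_log_fc=0.7, base_concentration=1.5),
        t("creatine", ((3.02, 1, 0.0, 3.0), (3.93, 1, 0.0, 2.0)), tumour_log_fc=0.0),
        t("formate", ((8.45, 1, 0.0, 1.0),), tumour_log_fc=0.6),
        t("glycerophosphocholine", ((3.22, 1, 0.0, 9.0),), tumour_log_fc=0.5),
        t("glycine", ((3.56, 1, 0.0, 2.0),), tumour_log_fc=0.7),
        t("isobutyrate", ((1.00, 2, J, 6.0),), tumour_log_fc=-0.15),
        t("isoglutamine", ((2.34, 1, 0.0, 2.0),), tumour_log_fc=0.6),
        t(
            "lactate",
            ((1.33, 2, J, 3.0), (4.15, 4, J, 1.0)),
            tumour_log_fc=1.0,
            base_concentration=2.0,
        ),
        t("leucine", ((1.72, 1, 0.0, 3.0),), tumour_log_fc=0.0),
        t("lipid_c=c-ch2", ((2.02, 1, 0.0, 4.0),), tumour_log_fc=-0.5, base_concentration=3.0),
        t(
            "lipid_(ch2)n",
            ((1.29, 1, 0.0, 10.0),),
            linewidth_ppm=0.004,
            tumour_log_fc=-0.7,
            base_concentration=3.0,
        ),
        t(
            "lipid_ch3",
            ((0.90, 1, 0.0, 6.0),),
            linewidth_ppm=0.003,
            tumour_log_fc=-0.7,
            base_concentration=3.0,
        ),
        t("phosphocholine", ((3.22, 1, 0.0, 9.0), (4.19, 3, J, 2.0)), tumour_log_fc=0.6),
        t("scylloinositol", ((3.34, 1, 0.0, 6.0),), tumour_log_fc=0.1),
        t("taurine", ((3.26, 3, J, 2.0), (3.42, 3, J, 2.0)), tumour_log_fc=1.0, base_concentration=2.0),
        t("valine", ((1.02, 2, J, 3.0),), tumour_log_fc=0.0),
    ]


#: genera planted with known associations, mirroring a tumour-enriched
#: community structure (Fusobacterium up on tumour, Bacteroides with EMVI,
#: Roseburia down with LVI, ...)
DEFAULT_PLANTED_EFFECTS: tuple[tuple[str, str, float], ...] = (
    ("Fusobacterium", "site=tumour", 2.0),
    ("Streptococcus", "poor_differentiation", 1.2),
    ("Solobacterium", "poor_differentiation", 1.2),
    ("Subdoligranulum", "poor_differentiation", -1.2),
    ("Bacteroides", "EMVI", 1.0),
    ("Roseburia", "LVI", -1.0),
    ("Aggregatibacter", "KRAS", 1.5),
)

DEFAULT_GENERA = (
    "Bacteroides",
    "Lachnospiracea_incertae_sedis",
    "Blautia",
    "Fusobacterium",
    "Streptococcus",
    "Clostridium_sensu_stricto",
    "Sutterella",
    "Escherichia_Shigella",
    "Prevotella",
    "Paraprevotella",
    "Roseburia",
    "Solobacterium",
    "Clostridium_XI",
    "Subdoligranulum",
    "Aggregatibacter",
    "Shewanella",
    "Acidovorax",
    "Faecalibacterium",
)


def default_otu_config(n_taxa: int = 60, **overrides) -> OtuSimConfig:
    """OTU simulation defaults with named genera and planted effects."""
    if n_taxa < len(DEFAULT_GENERA):
        raise ConfigError(f"n_taxa must be >= {len(DEFAULT_GENERA)} for the default panel")
    names = DEFAULT_GENERA + tuple(
        f"Genus_{i:03d}" for i in range(1, n_taxa - len(DEFAULT_GENERA) + 1)
    )
    overrides.setdefault("planted_effects", DEFAULT_PLANTED_EFFECTS)
    return OtuSimConfig(n_taxa=n_taxa, taxon_names=names, **overrides)


# ----------------------------------------------------------------- metadata


def simulate_metadata(cfg: CohortConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw per-patient histology and expand to one row per sample.

    Returns a metadata table with ``n_patients * len(sites)`` rows; histology
    features are constant within a patient.  Deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:02d}"
        t_levels = sorted(cfg.t_stage_probs)
        t_probs = np.array([cfg.t_stage_probs[k] for k in t_levels], float)
        t_stage = int(rng.choice(t_levels, p=t_probs / t_probs.sum()))
        d_levels = list(cfg.differentiation_probs)
        d_probs = np.array([cfg.differentiation_probs[k] for k in d_levels], float)
        if cfg.associate_differentiation_with_t and t_stage >= 3 and "poor" in d_levels:
            d_probs = d_probs.copy()
            d_probs[d_levels.index("poor")] *= 2.5
        differentiation = str(rng.choice(d_levels, p=d_probs / d_probs.sum()))
        n_levels = sorted(cfg.n_stage_probs)
        n_probs = np.array([cfg.n_stage_probs[k] for k in n_levels], float)
        n_stage = int(rng.choice(n_levels, p=n_probs / n_probs.sum()))
        patient = {
            "patient_id": pid,
            "T_stage": t_stage,
            "N_stage": n_stage,
            "differentiation": differentiation,
            "EMVI": int(rng.random() < cfg.emvi_prevalence),
            "LVI": int(rng.random() < cfg.lvi_prevalence),
            "PNVI": int(rng.random() < cfg.pnvi_prevalence),
            "KRAS": int(rng.random() < cfg.kras_prevalence),
        }
        patient["poor_differentiation"] = int(differentiation == "poor")
        for site in cfg.sites:
            rows.append({"sample_id": f"{pid}_{site}", "site": site, **patient})
    meta = pd.DataFrame(rows).set_index("sample_id")
    truth = SimTruth(
        sample_ids=list(meta.index),
        class_labels={
            sid: ("tumour" if site == "tumour" else "normal")
            for sid, site in meta["site"].items()
        },
    )
    return meta, truth


# ---------------------------------------------------------------- OTU table


def _covariate_indicator(meta: pd.DataFrame, covariate: str) -> np.ndarray:
    if "=" in covariate:
        col, _, value = covariate.partition("=")
        if col not in meta.columns:
            raise ConfigError(f"unknown covariate column {col!r} in planted effect")
        return (meta[col].astype(str) == value).to_numpy(float)
    if covariate not in meta.columns:
        raise ConfigError(f"unknown covariate {covariate!r} in planted effect")
    return meta[covariate].to_numpy(float)


def simulate_otu_table(
    meta: pd.DataFrame, cfg: OtuSimConfig, seed: int
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a samples x genera count table under the compositional model.

    Per-sample expected log abundance = base + patient effect + sum of
    planted covariate effects; proportions are the softmax of that vector.
    Counts are multinomial at a uniformly drawn depth, with Dirichlet
    perturbation of the proportions when ``overdispersion > 0``
    (concentration = proportions / overdispersion, so overdispersion -> 0
    recovers the exact multinomial).
    """
    if len(meta) < 1:
        raise ConfigError("metadata must contain at least one sample")
    rng = np.random.default_rng(seed)
    patients = meta["patient_id"].unique()
    patient_effect = {
        pid: rng.normal(0.0, cfg.patient_effect_sd, size=cfg.n_taxa) for pid in patients
    }
    effect_matrix = np.zeros((len(meta), cfg.n_taxa))
    for taxon, covariate, lfc in cfg.planted_effects:
        j = cfg.taxon_names.index(taxon)
        effect_matrix[:, j] += lfc * _covariate_indicator(meta, covariate)

    counts = np.zeros((len(meta), cfg.n_taxa), dtype=np.int64)
    truth = SimTruth(
        sample_ids=list(meta.index),
        planted_effects=list(cfg.planted_effects),
    )
    lo, hi = cfg.depth_range
    for i, sid in enumerate(meta.index):
        loga = cfg.base_log_abundances + patient_effect[meta["patient_id"].iloc[i]]
        loga = loga + effect_matrix[i]
        p = np.exp(loga - loga.max())
        p /= p.sum()
        if cfg.overdispersion > 0:
            p = rng.dirichlet(p / cfg.overdispersion)
        depth = int(rng.integers(lo, hi + 1))
        counts[i] = rng.multinomial(depth, p)
        truth.log_abundances[sid] = loga.tolist()
    table = pd.DataFrame(counts, index=meta.index, columns=list(cfg.taxon_names))
    return table, truth


# ------------------------------------------------------------------ spectra


def _lorentzian(ppm: np.ndarray, centre: float, hwhm: float) -> np.ndarray:
    return hwhm**2 / ((ppm - centre) ** 2 + hwhm**2)


def multiplet_profile(ppm: np.ndarray, template: MetaboliteTemplate) -> np.ndarray:
    """Unit-concentration spectral profile of one metabolite.

    Multiplet line intensities follow Pascal's triangle (1 / 1:1 / 1:2:1 /
    1:3:3:1) centred on the reported shift with lines ``j_spacing`` apart.
    """
    out = np.zeros_like(ppm)
    for centre, mult, j, rel in template.peaks:
        weights = np.array([float(math.comb(mult - 1, k)) for k in range(mult)])
        weights /= weights.sum()
        offsets = (np.arange(mult) - (mult - 1) / 2.0) * j
        for w, off in zip(weights, offsets):
            out += rel * w * _lorentzian(ppm, centre + off, template.linewidth_ppm)
    return out


def simulate_spectra(
    meta: pd.DataFrame,
    templates: Sequence[MetaboliteTemplate] | None = None,
    noise_sd: float = 0.005,
    dilution_log_sd: float = 0.3,
    seed: int = 0,
    conc_log_sd: float = 0.25,
    shift_sd: float = 0.003,
    resolution: float = 0.00055,
    lo: float = PPM_LO,
    hi: float = PPM_HI,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one 1D 1H spectrum per metadata row.

    Each spectrum is ``dilution_i * sum_m conc_im * multiplet(template_m)``
    plus Gaussian noise, where ``conc_im`` is the template's base
    concentration, times ``exp(tumour_log_fc)`` on tumour samples, times a
    log-normal sample fluctuation.  Dilution factors are log-normal with
    ``dilution_log_sd``; a small random ppm-axis offset (``shift_sd``)
    emulates imperfect referencing so that calibration has work to do.

    Returns a DataFrame with a ``ppm`` column plus one intensity column per
    sample, and the SimTruth holding dilutions, concentrations and labels.
    """
    if templates is None:
        templates = default_metabolite_templates()
    if not templates:
        raise ConfigError("templates must be non-empty")
    rng = np.random.default_rng(seed)
    n_points = int(round((hi - lo) / resolution))
    ppm = lo + (np.arange(n_points) + 0.5) * resolution
    truth = SimTruth(sample_ids=list(meta.index))
    data = {"ppm": ppm}
    for sid in meta.index:
        is_tumour = meta.loc[sid, "site"] == "tumour"
        dilution = float(np.exp(rng.normal(0.0, dilution_log_sd)))
        shift = float(rng.normal(0.0, shift_sd)) if shift_sd > 0 else 0.0
        spectrum = np.zeros(n_points)
        concs: dict[str, float] = {}
        for tpl in templates:
            conc = tpl.base_concentration * float(np.exp(rng.normal(0.0, conc_log_sd)))
            if is_tumour:
                conc *= float(np.exp(tpl.tumour_log_fc))
            concs[tpl.name] = conc
            spectrum += conc * multiplet_profile(ppm - shift, tpl)
        if noise_sd > 0:
            spectrum = spectrum + rng.normal(0.0, noise_sd, size=n_points)
        data[sid] = dilution * spectrum
        truth.dilution_factors[sid] = dilution
        truth.concentrations[sid] = concs
        truth.class_labels[sid] = "tumour" if is_tumour else "normal"
    return pd.DataFrame(data), truth


# --------------------------------------------------------------------- qPCR


def simulate_qpcr(
    meta: pd.DataFrame,
    copy_ratio_model: Mapping[str, float] | None = None,
    seed: int = 0,
    ratio_log2_sd: float = 1.0,
    ct_pan_mean: float = 18.0,
    ct_pan_sd: float = 1.0,
    noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate Fusobacterium nucleatum / pan-bacterial 16S Ct pairs.

    ``copy_ratio_model`` maps site label to the median Fn:pan copy ratio
    (default: tumour four-fold higher than off-tumour sites).  Per sample,
    the true ratio is log-normal around the site median and
    ``Ct_fn = Ct_pan - log2(ratio) + noise``: Ct is inversely proportional
    to log copy number, so a smaller Ct difference means more Fn.
    """
    if copy_ratio_model is None:
        copy_ratio_model = {"tumour": 0.04, "5cm": 0.01, "10cm": 0.01}
    for site, ratio in copy_ratio_model.items():
        if ratio <= 0:
            raise ConfigError(f"copy ratio for site {site!r} must be positive")
    rng = np.random.default_rng(seed)
    records = []
    truth = SimTruth(sample_ids=list(meta.index))
    for sid in meta.index:
        site = meta.loc[sid, "site"]
        if site not in copy_ratio_model:
            raise ConfigError(f"no copy ratio configured for site {site!r}")
        ratio = float(
            copy_ratio_model[site] * 2.0 ** rng.normal(0.0, ratio_log2_sd)
        )
        ct_pan = float(rng.normal(ct_pan_mean, ct_pan_sd))
        ct_fn = ct_pan - float(np.log2(ratio)) + float(rng.normal(0.0, noise_sd))
        records.append({"sample_id": sid, "target": "pan", "ct": ct_pan})
        records.append({"sample_id": sid, "target": "fn", "ct": ct_fn})
        truth.ct_copy_ratios[sid] = ratio
    return pd.DataFrame(records), truth
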