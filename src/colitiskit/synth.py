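"""Synthetic colitis-cohort generator.

Emulates the data structure of a T-cell-transfer (TCT) colitis study so the
whole downstream pipeline (histomorphometry, latent-variable modelling,
enrichment, microbiome ordination) can be exercised without any external
download. The generative backbone is deliberately minimal:

* a single non-negative latent *inflammation score* per animal drives both
  the distal crypt-height profile and the 54-analyte Luminex-style panel
  (analyte = baseline + loading x score + Gaussian noise), reproducing the
  empirical observation that one principal component carries most of the
  panel covariance and tracks epithelial hyperplasia;
* three inflammation classes: *control* (score exactly 0), *focal* (a
  contiguous elevated window within the distal colon), *continuous*
  (uniform distal hyperplasia in a configured 300-600 um range);
* treatment kinetics per analyte (immediate drop / graded decline /
  transient rise-then-decay / unaffected), exponential epithelial recovery,
  and lagged loss of innate infiltrate — the phenomenology of acute mTOR
  inhibition;
* organoid condition means tied to differentiation state, cell-type-mixture
  expression matrices with chemokines loaded on the transit-amplifying-cell
  (TAC) signature, and Dirichlet-multinomial taxon count tables.

Everything is deterministic for a fixed seed; per-stage substreams are
spawned from a single root ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .histo import CryptProfile

# --------------------------------------------------------------------------
# default analyte panel: 37 cytokines/chemokines/growth factors (pg/ml)
# and 17 phosphoproteins (relative fluorescence units)
# --------------------------------------------------------------------------

# (name, unit, baseline, relative inflammation weight)
# Loadings are weight x baseline so that strongly loaded analytes move by
# about one baseline per unit of inflammation score regardless of their
# absolute concentration scale. Chemokines for innate-cell chemotaxis,
# inflammatory interleukins and growth factors load positively; Th2-type
# interleukins stay near zero; MAPK/insulin-receptor phosphosites load
# negatively while mTOR/NF-kB phosphosites load positively.
_PANEL_SPEC: list[tuple[str, str, float, float]] = [
    ("IL-1a", "pg/ml", 45.0, 1.0),
    ("IL-1b", "pg/ml", 120.0, 1.0),
    ("IL-2", "pg/ml", 15.0, 0.5),
    ("IL-3", "pg/ml", 4.0, 0.1),
    ("IL-4", "pg/ml", 6.0, 0.1),
    ("IL-5", "pg/ml", 10.0, 0.1),
    ("IL-6", "pg/ml", 30.0, 1.0),
    ("IL-9", "pg/ml", 55.0, 0.1),
    ("IL-10", "pg/ml", 40.0, 0.15),
    ("IL-12p40", "pg/ml", 80.0, 0.9),
    ("IL-12p70", "pg/ml", 25.0, 0.1),
    ("IL-13", "pg/ml", 60.0, 0.1),
    ("IL-15", "pg/ml", 35.0, 0.5),
    ("IL-17A", "pg/ml", 20.0, 1.0),
    ("IL-17F", "pg/ml", 18.0, 0.5),
    ("IL-18", "pg/ml", 90.0, 0.5),
    ("IL-22", "pg/ml", 22.0, 1.0),
    ("IL-23", "pg/ml", 28.0, 0.5),
    ("IL-31", "pg/ml", 12.0, 0.05),
    ("IL-33", "pg/ml", 140.0, 0.05),
    ("Eotaxin", "pg/ml", 260.0, 0.8),
    ("G-CSF", "pg/ml", 75.0, 1.0),
    ("GM-CSF", "pg/ml", 26.0, 0.8),
    ("M-CSF", "pg/ml", 48.0, 1.0),
    ("IFN-g", "pg/ml", 33.0, 1.0),
    ("KC", "pg/ml", 110.0, 1.2),
    ("MCP-1", "pg/ml", 150.0, 1.2),
    ("MIG", "pg/ml", 95.0, 1.1),
    ("MIP-1a", "pg/ml", 65.0, 1.2),
    ("MIP-1b", "pg/ml", 70.0, 1.1),
    ("MIP-2", "pg/ml", 42.0, 1.1),
    ("RANTES", "pg/ml", 58.0, 1.1),
    ("TNF-a", "pg/ml", 85.0, 1.0),
    ("LIF", "pg/ml", 17.0, 1.0),
    ("VEGF", "pg/ml", 130.0, 1.0),
    ("PDGF-BB", "pg/ml", 210.0, 0.4),
    ("FGF-basic", "pg/ml", 180.0, 0.4),
    ("p-Akt", "RFU", 2600.0, 0.8),
    ("p-cJun", "RFU", 1400.0, 0.4),
    ("p-CREB", "RFU", 3100.0, -0.2),
    ("p-Erk1/2", "RFU", 4200.0, -0.3),
    ("p-GSK3", "RFU", 2900.0, -0.3),
    ("p-Jnk", "RFU", 1700.0, 0.4),
    ("p-Mek1", "RFU", 3600.0, -0.5),
    ("p-p38", "RFU", 2200.0, 0.4),
    ("p-Stat1", "RFU", 1900.0, 0.4),
    ("p-Stat3", "RFU", 2400.0, 0.8),
    ("p-p90Rsk", "RFU", 2000.0, -0.2),
    ("p-IR", "RFU", 3300.0, -0.5),
    ("p-IRS-1", "RFU", 2700.0, -0.4),
    ("p-IkBa", "RFU", 1600.0, 0.8),
    ("p-p70S6K", "RFU", 1500.0, 0.9),
    ("p-S6RP", "RFU", 3800.0, 0.9),
    ("p-Atf2", "RFU", 1300.0, 0.4),
]

DEFAULT_ANALYTES: tuple[str, ...] = tuple(name for name, *_ in _PANEL_SPEC)
DEFAULT_UNITS: tuple[str, ...] = tuple(unit for _, unit, *_ in _PANEL_SPEC)
DEFAULT_BASELINES: tuple[float, ...] = tuple(b for *_, b, _w in _PANEL_SPEC)
DEFAULT_LOADINGS: tuple[float, ...] = tuple(b * w for *_, b, w in _PANEL_SPEC)
#: analyte-level measurement noise, 12% of baseline
DEFAULT_NOISE_SD: tuple[float, ...] = tuple(0.12 * b for *_, b, _w in _PANEL_SPEC)

CYTOKINE_NAMES: tuple[str, ...] = tuple(
    name for name, unit, *_ in _PANEL_SPEC if unit == "pg/ml"
)

CELL_TYPES = ("T_cell", "macrophage", "neutrophil", "pDC")
INNATE_CELL_TYPES = ("macrophage", "neutrophil")


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for one synthetic TCT cohort.

    Class sizes default to 8 control / 7 focal / 6 continuous animals; the
    colon is 7 cm with the proximal/distal junction at its midpoint, and
    crypt heights rest at 180 um with continuous-disease hyperplasia drawn
    inside 300-600 um.
    """

    n_control: int = 8
    n_focal: int = 7
    n_continuous: int = 6
    colon_length_um: float = 70_000.0
    junction_fraction: float = 0.5
    n_measurements: int = 280
    baseline_crypt_um: float = 180.0
    hyperplasia_range_um: tuple[float, float] = (300.0, 600.0)
    crypt_noise_sd_um: float = 15.0
    off_axis_fraction: float = 0.03
    analyte_names: tuple[str, ...] = DEFAULT_ANALYTES
    analyte_units: tuple[str, ...] = DEFAULT_UNITS
    analyte_baselines: tuple[float, ...] = DEFAULT_BASELINES
    inflammation_loading: tuple[float, ...] = DEFAULT_LOADINGS
    noise_sd: tuple[float, ...] = DEFAULT_NOISE_SD
    # latent-score ranges per class; heights map as baseline + score * span
    focal_score_range: tuple[float, float] = (0.35, 0.55)
    focal_window_fraction: tuple[float, float] = (0.2, 0.6)
    # analytes whose organoid expression rises with goblet differentiation
    goblet_elevated: tuple[str, ...] = ("MIP-1a",)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_focal, self.n_continuous) < 0:
            raise ValueError("class sizes must be >= 0")
        if self.colon_length_um <= 0:
            raise ValueError("colon length must be positive")
        if not 0 < self.junction_fraction < 1:
            raise ValueError("junction_fraction must lie in (0, 1)")
        if self.n_measurements < 2:
            raise ValueError("need at least 2 measurement positions")
        lo, hi = self.hyperplasia_range_um
        if not 0 < lo < hi:
            raise ValueError("hyperplasia range must satisfy 0 < low < high")
        if self.baseline_crypt_um <= 0 or self.baseline_crypt_um >= lo:
            raise ValueError("baseline crypt height must be positive and below the hyperplastic range")
        if not self.analyte_names:
            raise ValueError("analyte list must not be empty")
        n = len(self.analyte_names)
        for name, seq in (
            ("analyte_units", self.analyte_units),
            ("analyte_baselines", self.analyte_baselines),
            ("inflammation_loading", self.inflammation_loading),
            ("noise_sd", self.noise_sd),
        ):
            if len(seq) != n:
                raise ValueError(f"{name} must have one entry per analyte")
        if any(u not in ("pg/ml", "RFU") for u in self.analyte_units):
            raise ValueError("analyte units must be 'pg/ml' or 'RFU'")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd entries must be >= 0")
        if not all(u in self.analyte_names for u in self.goblet_elevated):
            raise ValueError("goblet_elevated names must be panel analytes")

    @property
    def junction_um(self) -> float:
        return self.junction_fraction * self.colon_length_um

    @property
    def n_animals(self) -> int:
        return self.n_control + self.n_focal + self.n_continuous

    @property
    def height_span_um(self) -> float:
        """Crypt-height gain per unit inflammation score."""
        return self.hyperplasia_range_um[1] - self.baseline_crypt_um

    def score_to_height(self, score) -> np.ndarray:
        return self.baseline_crypt_um + np.asarray(score, float) * self.height_span_um

    def height_to_score(self, height) -> np.ndarray:
        return (np.asarray(height, float) - self.baseline_crypt_um) / self.height_span_um


@dataclass
class Animal:
    """One synthetic animal: latent state plus its measured readouts."""

    id: str
    true_class: str
    inflammation_score: float
    weight_loss_score: float
    crypt_profile: CryptProfile
    panel_row: np.ndarray
    infiltrate_fractions: dict[str, float]

    def __post_init__(self) -> None:
        if self.inflammation_score < 0:
            raise ValueError("inflammation score must be >= 0")
        if self.true_class == "control" and self.inflammation_score != 0:
            raise ValueError("control animals must have inflammation score 0")
        fracs = np.array(list(self.infiltrate_fractions.values()), float)
        if np.any(fracs < 0) or np.any(fracs > 1) or fracs.sum() > 1 + 1e-9:
            raise ValueError("infiltrate fractions must lie in [0,1] and sum to <= 1")


@dataclass(frozen=True)
class TreatmentModel:
    """Kinetic response of the cohort to a drug (e.g. rapamycin).

    Each analyte carries one kinetic class — ``immediate_drop`` and
    ``graded_decline`` relax exponentially toward the control baseline with
    the given half-time, ``transient_increase`` adds a rise-then-decay bump
    peaking near the half-time, ``unaffected`` analytes do not move. Crypt
    heights relax with ``epithelial_recovery_halftime_h``; innate infiltrate
    fractions hold for ``infiltrate_lag_h`` then decay.
    """

    name: str
    kinetic_class: dict[str, str]
    halftime_h: dict[str, float]
    epithelial_recovery_halftime_h: float
    infiltrate_lag_h: float
    control_baseline: dict[str, float]
    baseline_crypt_um: float
    infiltrate_decay_halftime_h: float = 12.0
    transient_amplitude: float = 0.8

    _CLASSES = ("immediate_drop", "graded_decline", "transient_increase", "unaffected")

    def __post_init__(self) -> None:
        for analyte, cls in self.kinetic_class.items():
            if cls not in self._CLASSES:
                raise ValueError(f"unknown kinetic class {cls!r} for analyte {analyte!r}")
        for analyte, ht in self.halftime_h.items():
            if ht <= 0:
                raise ValueError(f"half-time for {analyte!r} must be positive")
        missing = set(self.kinetic_class) - set(self.halftime_h)
        if missing:
            raise ValueError(f"analytes missing a half-time: {sorted(missing)}")
        if self.epithelial_recovery_halftime_h <= 0 or self.infiltrate_decay_halftime_h <= 0:
            raise ValueError("recovery half-times must be positive")
        if self.infiltrate_lag_h < 0:
            raise ValueError("infiltrate lag must be >= 0")


def default_treatment(config: CohortConfig, name: str = "rapamycin") -> TreatmentModel:
    """Rapamycin-like kinetics: mTOR targets and M-CSF drop within ~1 h,
    chemokines decline over ~12 h, IL-6 transiently rises, the rest hold."""
    immediate = {"M-CSF", "p-p70S6K", "p-S6RP"}
    graded = {
        "MIP-1a", "MIP-1b", "MIP-2", "MCP-1", "KC", "RANTES", "MIG", "Eotaxin",
        "IL-1a", "IL-1b", "IL-17A", "G-CSF", "GM-CSF", "IFN-g", "TNF-a", "LIF",
        "VEGF", "IL-22", "IL-12p40", "p-Stat3", "p-IkBa", "p-Akt",
    }
    transient = {"IL-6"}
    kinetic, halftime = {}, {}
    for analyte in config.analyte_names:
        if analyte in immediate:
            kinetic[analyte], halftime[analyte] = "immediate_drop", 1.0
        elif analyte in graded:
            kinetic[analyte], halftime[analyte] = "graded_decline", 12.0
        elif analyte in transient:
            kinetic[analyte], halftime[analyte] = "transient_increase", 8.0
        else:
            kinetic[analyte], halftime[analyte] = "unaffected", 1.0
    return TreatmentModel(
        name=name,
        kinetic_class=kinetic,
        halftime_h=halftime,
        epithelial_recovery_halftime_h=24.0,
        infiltrate_lag_h=24.0,
        control_baseline=dict(zip(config.analyte_names, config.analyte_baselines)),
        baseline_crypt_um=config.baseline_crypt_um,
    )


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _draw_score(true_class: str, config: CohortConfig, rng: np.random.Generator) -> float:
    if true_class == "control":
        return 0.0
    if true_class == "focal":
        return float(rng.uniform(*config.focal_score_range))
    if true_class == "continuous":
        lo, hi = config.hyperplasia_range_um
        # per-animal centre sits in the upper half of the hyperplastic range,
        # clear of the ends and of the focal severity band
        centre = rng.uniform(lo + 0.4 * (hi - lo), hi - 50.0)
        return float(config.height_to_score(centre))
    raise ValueError(f"unknown class {true_class!r}")


def sample_crypt_profile(
    true_class: str,
    config: CohortConfig,
    rng: np.random.Generator,
    score: float | None = None,
    animal_id: str = "animal",
) -> CryptProfile:
    """Draw one positional crypt-height profile for the given class.

    Measurements are evenly spaced over the colon (spacing = length / n).
    Continuous profiles keep every valid distal height inside the
    hyperplasia range; focal profiles elevate one contiguous distal window
    covering 20-60% of the distal region; controls stay near baseline.
    The infiltrate score co-locates with hyperplasia. A small fraction of
    records is flagged off-axis (heights inflated by crossing several
    crypts) and must be removed by cleaning before analysis.
    """
    if score is None:
        score = _draw_score(true_class, config, rng)
    spacing = config.colon_length_um / config.n_measurements
    positions = np.arange(config.n_measurements) * spacing
    distal = positions < config.junction_um
    base = config.baseline_crypt_um
    sd = config.crypt_noise_sd_um
    heights = rng.normal(base, sd, size=config.n_measurements)

    lo, hi = config.hyperplasia_range_um
    elevated = np.zeros(config.n_measurements, dtype=bool)
    if true_class == "continuous":
        centre = config.score_to_height(score)
        heights[distal] = np.clip(rng.normal(centre, sd, size=distal.sum()), lo, hi)
        elevated = distal.copy()
    elif true_class == "focal":
        frac = rng.uniform(*config.focal_window_fraction)
        junction = config.junction_um
        length = frac * junction
        start = rng.uniform(0.0, junction - length)
        window = distal & (positions >= start) & (positions < start + length)
        level = config.score_to_height(score)
        heights[window] = np.clip(rng.normal(level, sd, size=window.sum()), lo, hi)
        elevated = window
    elif true_class != "control":
        raise ValueError(f"unknown class {true_class!r}")

    heights = np.maximum(heights, 1.0)
    infiltrate = np.where(elevated, np.where(heights > 450.0, 3, 2), 0)
    # sparse low-grade foci outside hyperplastic areas in diseased animals
    if true_class != "control":
        stray = (~elevated) & (rng.random(config.n_measurements) < 0.05)
        infiltrate = np.where(stray, 1, infiltrate)
    off_axis = rng.random(config.n_measurements) < config.off_axis_fraction
    heights = np.where(off_axis, heights * rng.uniform(1.5, 2.5, size=len(heights)), heights)

    data = pd.DataFrame(
        {
            "position_um": positions,
            "region": np.where(distal, "distal", "proximal"),
            "height_um": heights,
            "infiltrate_score": infiltrate,
            "off_axis": off_axis,
        }
    )
    return CryptProfile(animal_id=animal_id, data=data, junction_um=config.junction_um)


def _panel_row(score: float, config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    base = np.asarray(config.analyte_baselines, float)
    loading = np.asarray(config.inflammation_loading, float)
    sd = np.asarray(config.noise_sd, float)
    row = base + loading * score + rng.normal(0.0, 1.0, size=len(base)) * sd
    pg = np.array([u == "pg/ml" for u in config.analyte_units])
    row[pg] = np.maximum(row[pg], 0.0)  # concentrations truncate at zero
    return row


def _infiltrate_fractions(score: float, rng: np.random.Generator) -> dict[str, float]:
    # CD45+ cells are 0.1-0.3% of colonic cells in controls (mostly pDCs)
    # and expand with inflammation toward a T cell / macrophage / neutrophil mix.
    total = 0.002 + 0.10 * score
    if score == 0:
        shares = np.array([0.1, 0.1, 0.05, 0.75])
    else:
        shares = rng.dirichlet([4.0, 3.0, 3.0, 0.5])
    frac = np.minimum(total * shares, 1.0)
    return dict(zip(CELL_TYPES, frac.tolist()))


def generate_cohort(config: CohortConfig) -> list[Animal]:
    """Generate a full cohort; deterministic for a fixed config seed."""
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    cohort: list[Animal] = []
    plan = (
        [("control", i) for i in range(config.n_control)]
        + [("focal", i) for i in range(config.n_focal)]
        + [("continuous", i) for i in range(config.n_continuous)]
    )
    prefix = {"control": "ctrl", "focal": "focal", "continuous": "cinfl"}
    for true_class, i in plan:
        animal_id = f"{prefix[true_class]}_{i + 1:02d}"
        score = _draw_score(true_class, config, rng)
        profile = sample_crypt_profile(true_class, config, rng, score=score, animal_id=animal_id)
        panel = _panel_row(score, config, rng)
        weight_loss = max(0.0, 3.0 * score + rng.normal(0.0, 0.3))
        cohort.append(
            Animal(
                id=animal_id,
                true_class=true_class,
                inflammation_score=score,
                weight_loss_score=weight_loss,
                crypt_profile=profile,
                panel_row=panel,
                infiltrate_fractions=_infiltrate_fractions(score, rng),
            )
        )
    return cohort


def cohort_panel(cohort: list[Animal], config: CohortConfig) -> pd.DataFrame:
    """Stack per-animal analyte vectors into a samples x analytes frame."""
    return pd.DataFrame(
        np.vstack([a.panel_row for a in cohort]),
        index=[a.id for a in cohort],
        columns=list(config.analyte_names),
    )


# --------------------------------------------------------------------------
# treatment kinetics
# --------------------------------------------------------------------------

def _decay(x0: float, target: float, t: float, halftime: float) -> float:
    return target + (x0 - target) * 2.0 ** (-t / halftime)


def apply_treatment(
    cohort: list[Animal], model: TreatmentModel, duration_h: float, config: CohortConfig
) -> list[Animal]:
    """Deterministic kinetic response of a cohort after ``duration_h`` hours.

    At duration 0 the cohort is returned unchanged; as duration grows,
    dropping/declining analytes approach the control baseline exponentially,
    transient analytes rise then decay, crypt heights relax toward baseline,
    and innate infiltrate fractions fall after the configured lag.
    """
    if duration_h < 0:
        raise ValueError("duration must be >= 0")
    unknown = set(model.kinetic_class) - set(config.analyte_names)
    if unknown:
        raise ValueError(f"treatment model names unknown analytes: {sorted(unknown)}")
    if duration_h == 0:
        return cohort
    t = duration_h
    names = list(config.analyte_names)
    out: list[Animal] = []
    for animal in cohort:
        row = animal.panel_row.copy()
        for j, analyte in enumerate(names):
            cls = model.kinetic_class.get(analyte, "unaffected")
            if cls == "unaffected":
                continue
            ht = model.halftime_h[analyte]
            target = model.control_baseline[analyte]
            if cls in ("immediate_drop", "graded_decline"):
                row[j] = _decay(row[j], target, t, ht)
            else:  # transient_increase: decay toward baseline plus a bump
                bump = model.transient_amplitude * row[j] * (t / ht) * np.exp(1.0 - t / ht)
                row[j] = _decay(row[j], target, t, ht) + bump
        prof = animal.crypt_profile
        h0 = prof.data["height_um"].to_numpy(float)
        h = model.baseline_crypt_um + (h0 - model.baseline_crypt_um) * 2.0 ** (
            -t / model.epithelial_recovery_halftime_h
        )
        data = prof.data.copy()
        data["height_um"] = h
        fracs = dict(animal.infiltrate_fractions)
        if t > model.infiltrate_lag_h:
            for ct in INNATE_CELL_TYPES:
                if ct in fracs:
                    fracs[ct] *= 2.0 ** (-(t - model.infiltrate_lag_h) / model.infiltrate_decay_halftime_h)
        out.append(
            replace(
                animal,
                crypt_profile=replace(prof, data=data),
                panel_row=row,
                infiltrate_fractions=fracs,
            )
        )
    return out


# --------------------------------------------------------------------------
# organoid panels
# --------------------------------------------------------------------------

ORGANOID_CONDITIONS = ("mixed", "stem", "enterocyte", "goblet")
#: effective inflammation-like score of each culture condition: stem-enriched
#: and mixed organoids express the inflammation-loaded analytes strongly,
#: differentiated (absorptive/secretory) organoids barely at all
ORGANOID_SCORES = {"mixed": 0.6, "stem": 0.8, "enterocyte": 0.15, "goblet": 0.1}


def organoid_condition_means(condition: str, config: CohortConfig) -> np.ndarray:
    """Noise-free panel means for one organoid culture condition."""
    if condition not in ORGANOID_CONDITIONS:
        raise ValueError(f"unknown organoid condition {condition!r}")
    base = np.asarray(config.analyte_baselines, float)
    loading = np.asarray(config.inflammation_loading, float)
    mean = base + loading * ORGANOID_SCORES[condition]
    if condition == "goblet":
        for name in config.goblet_elevated:
            j = config.analyte_names.index(name)
            mean[j] += 1.5 * abs(loading[j])  # MIP-1a-like goblet induction
    return mean


def sample_organoid_panel(
    condition: str, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """One noisy analyte vector for an organoid culture condition."""
    mean = organoid_condition_means(condition, config)
    row = mean + rng.normal(0.0, 1.0, size=len(mean)) * np.asarray(config.noise_sd, float)
    pg = np.array([u == "pg/ml" for u in config.analyte_units])
    row[pg] = np.maximum(row[pg], 0.0)
    return row


# --------------------------------------------------------------------------
# expression matrices and gene sets
# --------------------------------------------------------------------------

EPITHELIAL_TYPES = ("stem", "tac", "enterocyte", "goblet", "enteroendocrine", "secpro")

#: the four chemokine genes carried by the transit-amplifying-cell signature
TAC_CHEMOKINES = ("Cxcl1", "Cxcl2", "Cxcl5", "Ccl20")

_MARKERS: dict[str, tuple[str, ...]] = {
    "stem": ("Lgr5", "Ascl2", "Olfm4", "Smoc2", "Rnf43", "Axin2"),
    "tac": ("Mki67", "Ccnb1", "Top2a", "Birc5", "Mcm2", "Pcna") + TAC_CHEMOKINES,
    "enterocyte": ("Alpi", "Fabp2", "Slc5a1", "Krt20", "Car4", "Aqp8"),
    "goblet": ("Muc2", "Tff3", "Agr2", "Fcgbp", "Zg16", "Clca1"),
    "enteroendocrine": ("Chga", "Chgb", "Neurod1", "Sct", "Tac1", "Pyy"),
    "secpro": ("Atoh1", "Dll1", "Spdef", "Gfi1", "Sox4", "Foxa3"),
}


def default_signatures(n_background: int = 200, marker_gain: float = 3.0) -> pd.DataFrame:
    """Gene x cell-type mean-expression table (log2-like scale, baseline 5)."""
    genes = [g for ms in _MARKERS.values() for g in ms]
    genes += [f"Gene{i:04d}" for i in range(n_background)]
    sig = pd.DataFrame(5.0, index=genes, columns=list(EPITHELIAL_TYPES))
    for ct, markers in _MARKERS.items():
        sig.loc[list(markers), ct] += marker_gain
    return sig


def default_gene_sets() -> dict[str, list[str]]:
    """Marker gene sets per epithelial cell type, plus a goblet-deficient
    (Atoh1-null-like) set that pools proliferative/absorptive markers."""
    sets = {f"{ct}_signature": list(ms) for ct, ms in _MARKERS.items()}
    sets["atoh_null_up"] = list(_MARKERS["tac"][:6]) + list(_MARKERS["enterocyte"][:4])
    return sets


def default_mixtures(
    n_noninflamed: int = 4, n_inflamed: int = 6, rng: np.random.Generator | None = None,
    jitter: float = 60.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample epithelial cell-type proportions for the microarray design.

    Inflamed colons carry an expanded TAC compartment and depleted goblet /
    enteroendocrine / enterocyte compartments; proportions get per-sample
    Dirichlet jitter (concentration ``jitter``). Returns (mixtures, labels).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    base = {
        "noninflamed": np.array([0.08, 0.15, 0.35, 0.28, 0.05, 0.09]),
        "inflamed": np.array([0.06, 0.55, 0.17, 0.08, 0.03, 0.11]),
    }
    rows, labels = [], []
    for label, n in (("noninflamed", n_noninflamed), ("inflamed", n_inflamed)):
        for i in range(n):
            rows.append(rng.dirichlet(base[label] * jitter))
            labels.append(label)
    idx = [f"{lab[:3]}_{i + 1}" for i, lab in enumerate(labels)]
    mixtures = pd.DataFrame(rows, index=idx, columns=list(EPITHELIAL_TYPES))
    return mixtures, pd.Series(labels, index=idx, name="label")


def sample_expression_matrix(
    mixtures: pd.DataFrame,
    signatures: pd.DataFrame,
    rng: np.random.Generator,
    noise_sd: float = 0.25,
) -> pd.DataFrame:
    """Mixture-weighted expression: genes x samples = signatures @ mixturesT + noise."""
    if not np.allclose(mixtures.sum(axis=1).to_numpy(), 1.0, atol=1e-8):
        raise ValueError("each sample's cell-type proportions must sum to 1")
    missing = [c for c in mixtures.columns if c not in signatures.columns]
    if missing:
        raise ValueError(f"signatures lack cell types: {missing}")
    sig = signatures[mixtures.columns].to_numpy(float)
    expr = sig @ mixtures.to_numpy(float).T
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    return pd.DataFrame(expr, index=signatures.index, columns=mixtures.index)


# --------------------------------------------------------------------------
# microbiome count tables
# --------------------------------------------------------------------------

_TAXA = [
    ("Firmicutes", "Lactobacillus"), ("Firmicutes", "Clostridium"),
    ("Firmicutes", "Ruminococcus"), ("Firmicutes", "Faecalibaculum"),
    ("Firmicutes", "Turicibacter"), ("Firmicutes", "Roseburia"),
    ("Bacteroidetes", "Bacteroides"), ("Bacteroidetes", "Prevotella"),
    ("Bacteroidetes", "Alistipes"), ("Bacteroidetes", "Muribaculum"),
    ("Proteobacteria", "Escherichia"), ("Proteobacteria", "Helicobacter"),
    ("Proteobacteria", "Sutterella"), ("Verrucomicrobia", "Akkermansia"),
    ("Actinobacteria", "Bifidobacterium"), ("Deferribacteres", "Mucispirillum"),
]

DEFAULT_TAXON_NAMES = tuple(f"k__Bacteria;p__{p};g__{g}" for p, g in _TAXA)


def default_taxon_profiles() -> pd.DataFrame:
    """Group x taxon proportion profiles: inflamed guts shift toward
    Proteobacteria and away from Lactobacillus/Muribaculum."""
    control = np.array([0.18, 0.06, 0.08, 0.07, 0.05, 0.06, 0.12, 0.05, 0.06, 0.12,
                        0.01, 0.01, 0.02, 0.06, 0.03, 0.02])
    inflamed = np.array([0.04, 0.09, 0.05, 0.03, 0.02, 0.03, 0.16, 0.08, 0.09, 0.04,
                         0.12, 0.08, 0.05, 0.03, 0.01, 0.08])
    prof = pd.DataFrame(
        [control / control.sum(), inflamed / inflamed.sum()],
        index=["control", "inflamed"],
        columns=list(DEFAULT_TAXON_NAMES),
    )
    return prof


def sample_counts_table(
    groups: pd.Series,
    group_profiles: pd.DataFrame,
    depth: int,
    rng: np.random.Generator,
    concentration: float = 150.0,
) -> pd.DataFrame:
    """Sample x taxon counts: multinomial draws from Dirichlet-perturbed
    group profiles. Every row sums exactly to ``depth``.

    ``concentration`` scales the Dirichlet around the group profile; larger
    values mean samples hew closer to their group's composition. Taxa with
    zero group proportion stay at exactly zero (disjoint supports stay
    disjoint at any depth).
    """
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    if not np.allclose(group_profiles.sum(axis=1).to_numpy(), 1.0, atol=1e-8):
        raise ValueError("group profiles must each sum to 1")
    rows = []
    for sample, group in groups.items():
        p = group_profiles.loc[group].to_numpy(float)
        support = p > 0
        perturbed = np.zeros_like(p)
        perturbed[support] = rng.dirichlet(p[support] * concentration)
        rows.append(rng.multinomial(depth, perturbed))
    return pd.DataFrame(rows, index=groups.index, columns=group_profiles.columns)


# --------------------------------------------------------------------------
# on-disk cohort representation
# --------------------------------------------------------------------------

def cohort_tables(cohort: list[Animal], config: CohortConfig) -> dict[str, pd.DataFrame]:
    """The three tidy tables describing a cohort (measurements, panel, metadata)."""
    meas = []
    for a in cohort:
        d = a.crypt_profile.data.copy()
        d.insert(0, "animal_id", a.id)
        meas.append(d)
    measurements = pd.concat(meas, ignore_index=True)
    panel = cohort_panel(cohort, config)
    panel.index.name = "animal_id"
    meta = pd.DataFrame(
        {
            "animal_id": [a.id for a in cohort],
            "true_class": [a.true_class for a in cohort],
            "inflammation_score": [a.inflammation_score for a in cohort],
            "weight_loss_score": [a.weight_loss_score for a in cohort],
            "mean_distal_height_um": [a.crypt_profile.mean_distal_height() for a in cohort],
            "cd45_fraction": [sum(a.infiltrate_fractions.values()) for a in cohort],
        }
    )
    return {"crypt_measurements": measurements, "panel": panel.reset_index(), "metadata": meta}
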