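"""Synthetic study generator: ground-truth-known LC-MS peak-area tables.

Emulates a single-ascending-dose clinical PK study of a therapeutic IgG1 in
which the drug is affinity-purified from serum alongside a heavy
isotope-labelled internal calibrant, LysC-digested, and quantified by
peptide-level extracted-ion-chromatogram peak areas. The generator produces
the long-format light/heavy peak-area table the downstream quantitation
stage consumes, together with the noise-free truth (trajectories, attribute
fractions, total concentration) it was built from, so every pipeline stage
can be validated without clinical data.

Study structure emulated (defaults): 3 subjects, one IV bolus, 11 sampling
times (pre-bleed, 10 min, 1 h, 4 h, 12 h, days 2 and 4, weeks 1, 2, 3 and
6), biexponential total-drug decay with a terminal half-life of ~3 weeks,
and four attribute trajectories — deamidation rising ~5%->~38%, Man5 falling
~3%->~0.6%, pyroGlu ~96%->~100%, Fc Met-ox ~8.5%->~7% over 42 days. Noise is
multiplicative lognormal on every peak area with a configurable CV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .pk_model import AttributeModelParams, Trajectory, reference_params, simulate

__all__ = [
    "AttributeSpec",
    "PeptideSpec",
    "StudyConfig",
    "SyntheticStudy",
    "default_config",
    "default_sample_times",
    "generate_study",
    "generate_standard_curve",
    "write_peak_table",
    "read_peak_table",
    "load_config",
    "save_config",
]

PEAK_TABLE_COLUMNS = ["subject", "time_days", "peptide_id", "mod_form", "light_area", "heavy_area"]

#: Pre-bleed, 10 min, 1 h, 4 h, 12 h, day 2, day 4, weeks 1/2/3/6 — in days.
def default_sample_times() -> list[float]:
    return [0.0, 10.0 / 1440.0, 1.0 / 24.0, 4.0 / 24.0, 0.5, 2.0, 4.0, 7.0, 14.0, 21.0, 42.0]


@dataclass(frozen=True)
class AttributeSpec:
    """One quality attribute: its name, true model parameters (including the
    batch's initial modified fraction ``f``), and its mechanistic archetype
    (``"deamidation"`` equal-clearance or ``"man5"`` no-conversion)."""

    name: str
    params: AttributeModelParams
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("deamidation", "man5"):
            raise ValueError(f"attribute kind must be 'deamidation' or 'man5', got {self.kind!r}")


@dataclass(frozen=True)
class PeptideSpec:
    """One LysC peptide of the drug.

    ``ionization_factor`` converts concentration to detector peak area (area
    per mass/L, arbitrary scale, > 0). ``modifies`` names the attribute whose
    modified form this peptide reports, or None for a clean (reference-
    eligible) peptide. ``carryover_area`` injects a pre-dose light signal
    (assay carryover), and ``extra_decay_rate`` (1/day) superimposes
    peptide-specific in vivo degradation on the light signal — both exist to
    exercise the quantitation stage's exclusion screens.
    """

    peptide_id: str
    ionization_factor: float
    modifies: str | None = None
    carryover_area: float = 0.0
    extra_decay_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.ionization_factor <= 0:
            raise ValueError(
                f"ionization_factor must be > 0 for {self.peptide_id!r}, "
                f"got {self.ionization_factor}"
            )
        if self.carryover_area < 0:
            raise ValueError(f"carryover_area must be >= 0 for {self.peptide_id!r}")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to generate one synthetic study deterministically."""

    n_subjects: int = 3
    # mg; with V in L, model concentrations are mg/L = ug/mL. 700 mg is a
    # realistic single high IV dose and puts light/heavy ratios in the
    # assay's linear range (~0.05-1 against the 200 ug/mL calibrant).
    dose_amount: float = 700.0
    sample_times: list[float] = field(default_factory=default_sample_times)
    attribute_specs: list[AttributeSpec] = field(default_factory=list)
    peptide_panel: list[PeptideSpec] = field(default_factory=list)
    calibrant_amount: float = 2.5  # ug of heavy-labelled calibrant spiked per sample
    serum_volume: float = 12.5  # uL of serum per sample
    noise_cv: float = 0.10  # proportional CV of every peak area
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        times = np.asarray(self.sample_times, dtype=float)
        if times.size < 2 or times[0] != 0.0:
            raise ValueError("sample_times must start at 0 (pre-bleed) and have >= 2 points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.dose_amount <= 0:
            raise ValueError(f"dose_amount must be > 0, got {self.dose_amount}")
        if self.calibrant_amount <= 0 or self.serum_volume <= 0:
            raise ValueError("calibrant_amount and serum_volume must be > 0")
        names = {a.name for a in self.attribute_specs}
        if len(names) != len(self.attribute_specs):
            raise ValueError("attribute_specs names must be unique")
        ids = [p.peptide_id for p in self.peptide_panel]
        if len(set(ids)) != len(ids):
            raise ValueError("peptide_panel ids must be unique")
        for p in self.peptide_panel:
            if p.modifies is not None and p.modifies not in names:
                raise ValueError(
                    f"peptide {p.peptide_id!r} modifies unknown attribute {p.modifies!r}"
                )

    @property
    def calibrant_concentration(self) -> float:
        """Calibrant-equivalent serum concentration in ug/mL."""
        return self.calibrant_amount / self.serum_volume * 1000.0


def _default_attributes(dose: float) -> list[AttributeSpec]:
    deam = dataclasses.replace(reference_params("deamidation"), dose=dose, f=0.05)
    man5 = dataclasses.replace(reference_params("man5"), dose=dose, f=0.03)
    # pyroGlu: near-complete cyclization in vivo; equal-clearance archetype
    pyro = dataclasses.replace(deam, k_tr=0.08, f=0.96)
    # Fc Met oxidation: slight preferential clearance of the oxidized form
    metox = AttributeModelParams(
        k_cp=0.17, k_pc=0.093, k_tr=0.0, k_cl0=0.13, k_clmod=0.15, volume=3.34, dose=dose, f=0.085
    )
    return [
        AttributeSpec("deamidation", deam, "deamidation"),
        AttributeSpec("man5", man5, "man5"),
        AttributeSpec("pyroglu", pyro, "deamidation"),
        AttributeSpec("fc_metox", metox, "man5"),
    ]


def _default_panel(attributes: Sequence[AttributeSpec], rng: np.random.Generator) -> list[PeptideSpec]:
    """25 clean reference-eligible peptides, one reporter peptide per
    attribute, one carryover-contaminated peptide and one terminally
    degrading peptide (the light-chain N-terminus analogue)."""
    panel: list[PeptideSpec] = []
    ion = lambda: float(np.exp(rng.uniform(np.log(0.3), np.log(3.0))))
    for i in range(25):
        panel.append(PeptideSpec(f"PEP{i:02d}", ion()))
    for spec in attributes:
        panel.append(PeptideSpec(f"MODPEP_{spec.name}", ion(), modifies=spec.name))
    panel.append(PeptideSpec("PEP_CARRYOVER", ion(), carryover_area=50.0))
    panel.append(PeptideSpec("PEP_LC_NTERM", ion(), extra_decay_rate=0.05))
    return panel


def default_config(seed: int = 0, noise_cv: float = 0.10, n_subjects: int = 3) -> StudyConfig:
    """The study conditions the generator emulates, with a fixed panel drawn
    from a seed-derived substream (so the panel itself is reproducible)."""
    attrs = _default_attributes(dose=700.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    return StudyConfig(
        n_subjects=n_subjects,
        attribute_specs=attrs,
        peptide_panel=_default_panel(attrs, rng),
        noise_cv=noise_cv,
        seed=seed,
    )


@dataclass(frozen=True)
class SyntheticStudy:
    """Peak table plus the noise-free truth it was generated from."""

    peak_table: pd.DataFrame
    trajectories: dict[str, Trajectory]  # per attribute, shared across subjects
    fractions: dict[str, pd.DataFrame]  # attribute -> (time_days, fraction), noise-free
    total_concentration: pd.DataFrame  # (time_days, value) in ug/mL-equivalent units
    config: StudyConfig


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate one study's peak-area table and its ground truth.

    Per attribute, the noise-free truth is the ODE solution of the two-form
    model under the configured parameters. Reporter peptides carry one row
    per form (light area proportional to that form's central concentration);
    clean peptides track the total-drug concentration of the first
    equal-clearance attribute's model (a plain biexponential). Heavy areas
    are the constant calibrant-equivalent concentration through the same
    ionization factor; the calibrant is modelled as fully unmodified, so
    modified-form rows have zero heavy area. The pre-bleed sample has zero
    drug light signal (plus any configured carryover).
    """
    times = np.asarray(config.sample_times, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))

    trajectories: dict[str, Trajectory] = {}
    fractions: dict[str, pd.DataFrame] = {}
    for spec in config.attribute_specs:
        p = dataclasses.replace(spec.params, dose=config.dose_amount)
        traj = simulate(p, times)
        trajectories[spec.name] = traj
        fractions[spec.name] = pd.DataFrame(
            {"time_days": times, "fraction": traj.modified_fraction_central}
        )

    # total-drug truth: the model of the first equal-clearance attribute if
    # present (its total is an exact biexponential), else the first attribute
    total_source = next(
        (s.name for s in config.attribute_specs if s.kind == "deamidation"),
        config.attribute_specs[0].name if config.attribute_specs else None,
    )
    if total_source is None:
        raise ValueError("config must declare at least one attribute")
    c_total_truth = trajectories[total_source].c_total  # mass/L for the configured dose
    total_truth = pd.DataFrame({"time_days": times, "value": c_total_truth})

    post_dose = times > 0
    c_cal = config.calibrant_concentration
    rows: list[tuple] = []
    for subject in range(1, config.n_subjects + 1):
        sid = f"S{subject}"
        for pep in config.peptide_panel:
            if pep.modifies is None:
                conc = np.where(post_dose, c_total_truth, 0.0)
                if pep.extra_decay_rate:
                    conc = conc * np.exp(-pep.extra_decay_rate * times)
                light = pep.ionization_factor * conc
                if pep.carryover_area:
                    light = light + pep.carryover_area
                heavy = pep.ionization_factor * c_cal * np.ones_like(times)
                for t, lo, he in zip(times, light, heavy):
                    rows.append((sid, t, pep.peptide_id, "none", lo, he))
            else:
                traj = trajectories[pep.modifies]
                c0 = np.where(post_dose, traj.c0, 0.0)
                cmod = np.where(post_dose, traj.cmod, 0.0)
                heavy = pep.ionization_factor * c_cal * np.ones_like(times)
                for t, a, he in zip(times, pep.ionization_factor * c0, heavy):
                    rows.append((sid, t, pep.peptide_id, "none", a, he))
                for t, a in zip(times, pep.ionization_factor * cmod):
                    rows.append((sid, t, pep.peptide_id, pep.modifies, a, 0.0))

    table = pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)
    noisy = _lognormal_factors(rng, config.noise_cv, (len(table), 2))
    table["light_area"] = table["light_area"].to_numpy() * noisy[:, 0]
    table["heavy_area"] = table["heavy_area"].to_numpy() * noisy[:, 1]
    return SyntheticStudy(
        peak_table=table,
        trajectories=trajectories,
        fractions=fractions,
        total_concentration=total_truth,
        config=config,
    )


def generate_standard_curve(levels: Sequence[float], config: StudyConfig) -> pd.DataFrame:
    """Spike-in standard series: drug at each ``level`` (ug/mL) in blank
    serum with the constant heavy calibrant. Returns a tidy table
    (concentration, peptide_id, light_area, heavy_area); the light/heavy
    ratio is proportional to level, with slope 1/calibrant-concentration
    when noise-free.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("levels must be non-empty")
    if np.any(levels <= 0):
        raise ValueError("standard-curve levels must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x57D]))
    c_cal = config.calibrant_concentration
    peptides = [p for p in config.peptide_panel if p.modifies is None and p.carryover_area == 0]
    if not peptides:
        raise ValueError("peptide_panel has no clean peptide for the standard series")
    rows = []
    for level in levels:
        for pep in peptides:
            rows.append((level, pep.peptide_id, pep.ionization_factor * level,
                         pep.ionization_factor * c_cal))
    curve = pd.DataFrame(rows, columns=["concentration", "peptide_id", "light_area", "heavy_area"])
    noisy = _lognormal_factors(rng, config.noise_cv, (len(curve), 2))
    curve["light_area"] = curve["light_area"].to_numpy() * noisy[:, 0]
    curve["heavy_area"] = curve["heavy_area"].to_numpy() * noisy[:, 1]
    return curve


# ---------------------------------------------------------------------------
# serialization

def write_peak_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=PEAK_TABLE_COLUMNS)


def read_peak_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(PEAK_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"peak table {path} is missing columns {sorted(missing)}")
    return table


def _params_to_dict(p: AttributeModelParams) -> dict:
    return {
        "k_cp": p.k_cp, "k_pc": p.k_pc, "k_tr": p.k_tr, "k_cl0": p.k_cl0,
        "k_clmod": p.k_clmod, "volume": p.volume, "dose": p.dose, "f": p.f,
    }


def save_config(config: StudyConfig, path: str | Path) -> None:
    doc = {
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "dose_amount": config.dose_amount,
        "sample_times": list(map(float, config.sample_times)),
        "calibrant_amount": config.calibrant_amount,
        "serum_volume": config.serum_volume,
        "noise_cv": config.noise_cv,
        "attributes": [
            {"name": a.name, "kind": a.kind, "params": _params_to_dict(a.params)}
            for a in config.attribute_specs
        ],
        "peptides": [
            {
                "peptide_id": p.peptide_id,
                "ionization_factor": p.ionization_factor,
                "modifies": p.modifies,
                "carryover_area": p.carryover_area,
                "extra_decay_rate": p.extra_decay_rate,
            }
            for p in config.peptide_panel
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> StudyConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if "seed" not in doc:
        raise ValueError("config must state a seed")
    attrs = [
        AttributeSpec(a["name"], AttributeModelParams(**a["params"]), a["kind"])
        for a in doc.get("attributes", [])
    ]
    peps = [PeptideSpec(**p) for p in doc.get("peptides", [])]
    return StudyConfig(
        n_subjects=doc.get("n_subjects", 3),
        dose_amount=doc.get("dose_amount", 1.0),
        sample_times=doc.get("sample_times", default_sample_times()),
        attribute_specs=attrs,
        peptide_panel=peps,
        calibrant_amount=doc.get("calibrant_amount", 2.5),
        serum_volume=doc.get("serum_volume", 12.5),
        noise_cv=doc.get("noise_cv", 0.10),
        seed=doc["seed"],
    )
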