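"""Synthetic urine Raman cohort generator.

Builds seeded cohorts with known ground truth: biomarker panels drawn
from the study groups' concentration distributions (healthy controls vs
diabetic & hypertensive patients), and spectra assembled by a linear
Beer-Lambert-style forward model — per-analyte component spectra built
from literature band positions, scaled by concentration, plus a broad
water band, a smooth fluorescence baseline, white noise, and occasional
one-channel cosmic-ray spikes.

Component band positions (cm^-1): urea 516, 587, 1002 (strongest), 1157;
creatinine 678, 846, 910; phosphate 880, 979, 1080; glucose 446, 516
(overlapping urea), 910 (overlapping creatinine), 1080 (overlapping
phosphate), 1127; proteins as broad bands between 1250 and 1700.
Narrow bands are Lorentzian (FWHM 12 cm^-1), protein and water bands
Gaussian.

The diseased group's glucose is a 75/25 mixture: three quarters of
patients near-normoglycosuric (0.3 +/- 0.1 mmol/L), one quarter frankly
glycosuric (lognormal, mean 68 mmol/L) — the minimal model reproducing
both the group's heavy-tailed mean (about 17 +/- 39 mmol/L) and a 25%
above-reference fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    ANALYTES,
    BiomarkerPanel,
    Group,
    Sex,
    SpectraSet,
    Spectrum,
    SpectrumMeta,
    WavenumberAxis,
    default_grid,
)

__all__ = [
    "Peak",
    "PeakTable",
    "DistributionSpec",
    "CohortConfig",
    "DEFAULT_PEAK_TABLES",
    "DEFAULT_GROUP_DISTRIBUTIONS",
    "component_spectrum",
    "sample_biomarker_panel",
    "synthesize_spectrum",
    "generate_cohort",
    "null_group_distributions",
    "LatentComponent",
    "DEFAULT_LATENT_COMPONENTS",
    "null_latent_components",
    "null_cohort_config",
]


@dataclass(frozen=True)
class Peak:
    """One vibrational band: center (cm^-1), relative height, FWHM, shape."""

    center: float
    relative_height: float
    fwhm: float
    shape: str = "lorentzian"  # or "gaussian"

    def __post_init__(self) -> None:
        if not 400.0 <= self.center <= 1800.0:
            raise ValueError(f"peak center {self.center} outside 400-1800 cm^-1")
        if self.relative_height <= 0:
            raise ValueError("peak height must be > 0")
        if not 4.0 <= self.fwhm <= 200.0:
            raise ValueError("FWHM must be within [4, 200] cm^-1")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.shape == "lorentzian":
            g = self.fwhm / 2.0
            return self.relative_height * g**2 / ((x - self.center) ** 2 + g**2)
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return self.relative_height * np.exp(-0.5 * ((x - self.center) / sigma) ** 2)


PeakTable = tuple[Peak, ...]

_L = 12.0  # default narrow-band FWHM (cm^-1)

DEFAULT_PEAK_TABLES: dict[str, PeakTable] = {
    "urea": (
        Peak(516.0, 0.25, _L),
        Peak(587.0, 0.30, _L),
        Peak(1002.0, 1.00, _L),
        Peak(1157.0, 0.25, _L),
    ),
    "creatinine": (
        Peak(678.0, 1.00, _L),
        Peak(846.0, 0.50, _L),
        Peak(910.0, 0.60, _L),
    ),
    "phosphate": (
        Peak(880.0, 0.50, _L),
        Peak(979.0, 1.00, _L),
        Peak(1080.0, 0.60, _L),
    ),
    "glucose": (
        Peak(446.0, 0.80, _L),
        Peak(516.0, 0.60, _L),
        Peak(910.0, 0.40, _L),
        Peak(1080.0, 0.50, _L),
        Peak(1127.0, 1.00, _L),
    ),
    "total_protein": (
        Peak(1270.0, 0.50, 40.0, "gaussian"),
        Peak(1342.0, 0.60, 40.0, "gaussian"),
        Peak(1449.0, 1.00, 40.0, "gaussian"),
        Peak(1555.0, 0.40, 40.0, "gaussian"),
        Peak(1659.0, 0.90, 40.0, "gaussian"),
    ),
}


@dataclass(frozen=True)
class DistributionSpec:
    """Concentration distribution for one analyte in one group.

    Families: ``normal_truncated0`` (params mean, sd; renormalized at 0),
    ``lognormal`` (params mean, sd on the natural scale), and ``mixture``
    (params components: list of (weight, DistributionSpec)).
    """

    family: str
    params: dict

    def draw(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        n = 1 if size is None else size
        if self.family == "normal_truncated0":
            mu, sd = self.params["mean"], self.params["sd"]
            if sd == 0:
                out = np.full(n, float(mu))
            else:
                a = (0.0 - mu) / sd
                out = stats.truncnorm.rvs(
                    a, np.inf, loc=mu, scale=sd, size=n, random_state=rng
                )
        elif self.family == "lognormal":
            m, sd = self.params["mean"], self.params["sd"]
            sigma2 = np.log(1.0 + (sd / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            out = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
        elif self.family == "mixture":
            comps = self.params["components"]
            weights = np.array([w for w, _ in comps], dtype=float)
            if not np.isclose(weights.sum(), 1.0):
                raise ValueError("mixture weights must sum to 1")
            which = rng.choice(len(comps), size=n, p=weights)
            out = np.empty(n)
            for j, (_, spec) in enumerate(comps):
                mask = which == j
                if mask.any():
                    out[mask] = spec.draw(rng, int(mask.sum()))
        else:
            raise ValueError(f"unknown distribution family {self.family!r}")
        return float(out[0]) if size is None else out


def _tn(mean: float, sd: float) -> DistributionSpec:
    return DistributionSpec("normal_truncated0", {"mean": mean, "sd": sd})


#: Group concentration distributions (units as in BiomarkerPanel).
DEFAULT_GROUP_DISTRIBUTIONS: dict[Group, dict[str, DistributionSpec]] = {
    Group.CT: {
        "urea": _tn(271.0, 89.0),
        "creatinine": _tn(12.5, 5.5),
        "glucose": _tn(0.23, 0.04),
        "phosphate": _tn(23.4, 14.1),
        "total_protein": _tn(14.7, 5.5),
    },
    Group.DMHBP: {
        "urea": _tn(249.0, 68.0),
        "creatinine": _tn(9.3, 4.0),
        "glucose": DistributionSpec(
            "mixture",
            {
                "components": [
                    (0.75, _tn(0.3, 0.1)),
                    (0.25, DistributionSpec("lognormal", {"mean": 68.0, "sd": 50.0})),
                ]
            },
        ),
        "phosphate": _tn(17.2, 9.9),
        "total_protein": _tn(15.6, 7.2),
    },
}


def null_group_distributions() -> dict[Group, dict[str, DistributionSpec]]:
    """Both groups drawn from the control distributions (no group effect)."""
    ct = DEFAULT_GROUP_DISTRIBUTIONS[Group.CT]
    return {Group.CT: dict(ct), Group.DMHBP: dict(ct)}


@dataclass(frozen=True)
class LatentComponent:
    """An unassayed spectral component with a group-dependent level.

    Urine carries many metabolites beyond the five assayed biomarkers;
    disease shifts some of them.  One such aggregate "metabolic profile"
    component is what lets full-spectrum classification genuinely exceed
    classification on the five assayed concentrations, as observed on
    real cohorts.  The level is in arbitrary concentration-like units.
    """

    peaks: PeakTable
    coefficient: float  # counts per unit level
    distributions: dict  # Group -> DistributionSpec


#: Aggregate amino-acid/metabolite bands (positions echo protein/amino-acid
#: features reported in urine spectra), elevated in the diseased group.
DEFAULT_LATENT_COMPONENTS: dict[str, LatentComponent] = {
    "metabolic_profile": LatentComponent(
        peaks=(
            Peak(622.0, 0.5, _L),
            Peak(788.0, 0.6, _L),
            Peak(868.0, 0.4, _L),
            Peak(1006.0, 0.3, _L),
            Peak(1360.0, 0.7, _L),
            Peak(1408.0, 0.5, _L),
            Peak(1635.0, 1.0, _L),
        ),
        coefficient=30.0,
        distributions={
            Group.CT: _tn(1.0, 0.33),
            Group.DMHBP: _tn(2.0, 0.33),
        },
    )
}


def null_latent_components() -> dict[str, LatentComponent]:
    """Latent components with the control distribution in both groups."""
    out = {}
    for name, lc in DEFAULT_LATENT_COMPONENTS.items():
        ct = lc.distributions[Group.CT]
        out[name] = LatentComponent(
            peaks=lc.peaks,
            coefficient=lc.coefficient,
            distributions={Group.CT: ct, Group.DMHBP: ct},
        )
    return out


@dataclass
class CohortConfig:
    """Study-design and forward-model parameters of a synthetic cohort.

    Defaults emulate the study conditions: 20 samples per group, 6
    replicate spectra per sample (240 spectra), the 400-1800 cm^-1 grid at
    2 cm^-1, group concentration distributions as published, and signal
    scales giving urea-dominated spectra with band heights of tens to a
    couple hundred counts over a noise SD of 1.5.
    """

    n_per_group: int = 20
    replicates_per_sample: int = 6
    grid: WavenumberAxis = field(default_factory=default_grid)
    group_distributions: dict = field(
        default_factory=lambda: {
            g: dict(d) for g, d in DEFAULT_GROUP_DISTRIBUTIONS.items()
        }
    )
    peak_tables: dict = field(default_factory=lambda: dict(DEFAULT_PEAK_TABLES))
    # counts of signal per concentration unit (mmol/L; mg/dL for protein)
    response_coefficients: dict = field(
        default_factory=lambda: {
            "urea": 0.5,
            "creatinine": 4.0,
            "glucose": 6.0,
            "phosphate": 3.0,
            "total_protein": 7.0,
        }
    )
    latent_components: dict = field(
        default_factory=lambda: dict(DEFAULT_LATENT_COMPONENTS)
    )
    # fluorescence baseline: fixed 6-coefficient polynomial shape on the
    # unit interval across the grid, times a per-spectrum random scale
    baseline_coefficients: tuple = (1.0, -1.2, 0.8, -0.3, 0.1, 0.05)
    baseline_scale: float = 300.0
    noise_sd: float = 1.5
    spike_rate: float = 0.2  # expected cosmic-ray spikes per spectrum
    water_band: Peak = field(default=Peak(1660.0, 120.0, 90.0, "gaussian"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")


def component_spectrum(
    analyte: str,
    grid: WavenumberAxis | None = None,
    peaks: PeakTable | None = None,
) -> Spectrum:
    """Unit component spectrum of one analyte (max height normalized to 1)."""
    if peaks is None:
        if analyte not in DEFAULT_PEAK_TABLES:
            raise ValueError(f"unknown analyte {analyte!r}")
        peaks = DEFAULT_PEAK_TABLES[analyte]
    if len(peaks) == 0:
        raise ValueError(f"empty peak table for {analyte!r}")
    grid = grid or default_grid()
    x = grid.values
    y = np.zeros_like(x)
    for p in peaks:
        y += p.evaluate(x)
    y /= np.max(y)
    return Spectrum(grid, y, SpectrumMeta(spectrum_id=f"component_{analyte}"))


def sample_biomarker_panel(
    group: Group,
    cfg: CohortConfig,
    rng: np.random.Generator,
    sample_id: str = "",
) -> BiomarkerPanel:
    """Draw one sample's five concentrations from its group distributions."""
    dists = cfg.group_distributions[group]
    missing = [a for a in ANALYTES if a not in dists]
    if missing:
        raise ValueError(f"no distribution configured for {missing}")
    values = {a: float(dists[a].draw(rng)) for a in ANALYTES}
    return BiomarkerPanel(sample_id=sample_id, **values)


def _baseline_profile(cfg: CohortConfig) -> np.ndarray:
    x = cfg.grid.values
    t = (x - x[0]) / (x[-1] - x[0])
    prof = np.polynomial.polynomial.polyval(t, np.asarray(cfg.baseline_coefficients))
    return np.clip(prof, 0.0, None)


def synthesize_spectrum(
    panel: BiomarkerPanel,
    cfg: CohortConfig,
    rng: np.random.Generator,
    spectrum_id: str = "synthetic",
    meta: SpectrumMeta | None = None,
    latent_levels: dict | None = None,
) -> Spectrum:
    """Forward-model one spectrum from a biomarker panel.

    intensity = sum_a coefficient_a * concentration_a * component_a
    + water band + baseline_scale * U(0.5, 1.5) * baseline profile
    + N(0, noise_sd) per channel + Poisson(spike_rate) one-channel spikes
    of 20-100x the noise SD.  With ``latent_levels`` given (as
    :func:`generate_cohort` does), unassayed latent components are added
    on the same linear terms.  The ground-truth panel is attached to the
    spectrum metadata (``meta.extras["panel"]``).
    """
    x = cfg.grid.values
    y = np.zeros_like(x)
    for a in ANALYTES:
        comp = component_spectrum(a, cfg.grid, cfg.peak_tables.get(a))
        y += cfg.response_coefficients[a] * panel[a] * comp.intensity
    if latent_levels:
        for name, level in latent_levels.items():
            lc = cfg.latent_components[name]
            comp = component_spectrum(name, cfg.grid, lc.peaks)
            y += lc.coefficient * level * comp.intensity
    y += cfg.water_band.evaluate(x)
    if cfg.baseline_scale != 0.0:
        y += rng.uniform(0.5, 1.5) * cfg.baseline_scale * _baseline_profile(cfg)
    if cfg.noise_sd > 0:
        y += rng.normal(0.0, cfg.noise_sd, size=x.size)
    n_spikes = rng.poisson(cfg.spike_rate) if cfg.spike_rate > 0 else 0
    for _ in range(n_spikes):
        ch = rng.integers(0, x.size)
        y[ch] += rng.uniform(20.0, 100.0) * max(cfg.noise_sd, 1.0)
    m = meta or SpectrumMeta(spectrum_id=spectrum_id, sample_id=panel.sample_id)
    m.extras["panel"] = panel
    m.extras["n_spikes_injected"] = int(n_spikes)
    return Spectrum(cfg.grid, y, m)


def generate_cohort(cfg: CohortConfig) -> tuple[SpectraSet, list[BiomarkerPanel]]:
    """Generate the full two-group cohort: panels plus replicate spectra.

    One seeded generator drives every draw, in a fixed order (per group,
    per sample: the panel, then each replicate's baseline scale, noise and
    spikes), so identical configs give bit-identical cohorts.  Sex is
    assigned alternately M/W within each group.
    """
    rng = np.random.default_rng(cfg.seed)
    panels: list[BiomarkerPanel] = []
    spectra: list[Spectrum] = []
    for group, prefix in ((Group.CT, "CT"), (Group.DMHBP, "DM")):
        for i in range(cfg.n_per_group):
            sample_id = f"{prefix}{i + 1:02d}"
            panel = sample_biomarker_panel(group, cfg, rng, sample_id=sample_id)
            panels.append(panel)
            latent = {
                name: float(lc.distributions[group].draw(rng))
                for name, lc in cfg.latent_components.items()
            }
            sex = Sex.M if i % 2 == 0 else Sex.W
            for r in range(1, cfg.replicates_per_sample + 1):
                meta = SpectrumMeta(
                    spectrum_id=f"{sample_id}_r{r}",
                    sample_id=sample_id,
                    group=group,
                    sex=sex,
                    replicate_index=r,
                )
                meta.extras["latent_levels"] = dict(latent)
                spectra.append(
                    synthesize_spectrum(
                        panel, cfg, rng, meta=meta, latent_levels=latent
                    )
                )
    return SpectraSet(cfg.grid, spectra), panels


def null_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Cohort config with the group difference disabled: both groups use
    the control concentration and latent-component distributions."""
    return CohortConfig(
        group_distributions=null_group_distributions(),
        latent_components=null_latent_components(),
        seed=seed,
        **overrides,
    )
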