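"""Synthetic study generator with known ground truth.

Emulates the sampling design and statistical structure of a comparative
lipidomic survey: locale-specific depth-temperature water columns (a
near-isothermal polar column versus temperate/tropical thermoclines),
species-level compositional baselines evolving on a phylogeny under a
stationary Ornstein-Uhlenbeck process, linear environmental effects on
latent (log-ratio) composition coordinates, individual-level noise, and
GC-MS external-standard calibration series and single-ion peak tables
consistent with the known mole fractions.

The latent model for individual i of species s with compound panel k:

    z_ik = m_k + u_sk + beta_depth_k * depth_km_i + beta_temp_k * T_i + e_ik

with u_s ~ MVN(0, sigma^2 exp(-alpha * D)) over species tips and
e ~ N(0, noise_sd); mole fractions are softmax(z_i).  Softmax keeps every
profile on the simplex while the environmental effects stay linear in the
latent space the regression model assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lipids import CompositionProfile, parse_lipid_label
from .phylo import Phylogeny, _Node
from .pipeline import SpecimenRecord
from .quant import MassSpectrum, on_column_fraction, select_quant_ion

__all__ = [
    "Locale",
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_environment",
    "simulate_compositions",
    "simulate_gcms",
    "simulate_study",
    "DEFAULT_PANEL",
    "DEFAULT_SPLIT_RATIOS",
]

#: default compound panel: the six major FAMEs plus the abundant odd-chain
#: acids and the dominant long-chain fatty alcohol
DEFAULT_PANEL: tuple[str, ...] = (
    "C14:0", "C15:0", "C16:0", "C17:0", "C17:1",
    "C18:0", "C18:1", "C20:5", "C22:6", "C22:1(n-9) alcohol",
)

#: typical mean mole fractions for a gelatinous zooplankton lipidome,
#: expressed as softmax logits (log fractions up to an additive constant)
DEFAULT_BASELINE_LOGITS: dict[str, float] = {
    "C14:0": math.log(0.050),
    "C15:0": math.log(0.019),
    "C16:0": math.log(0.350),
    "C17:0": math.log(0.021),
    "C17:1": math.log(0.0075),
    "C18:0": math.log(0.080),
    "C18:1": math.log(0.120),
    "C20:5": math.log(0.140),
    "C22:6": math.log(0.180),
    "C22:1(n-9) alcohol": math.log(0.020),
}

#: latent effects per km of depth: unsaturation (C18:1 and, more weakly, the
#: long-chain PUFAs) rises with depth at the expense of saturated chains;
#: fatty alcohols decline with depth
DEFAULT_BETA_DEPTH: dict[str, float] = {
    "C18:1": 0.45,
    "C20:5": 0.2,
    "C22:6": 0.2,
    "C16:0": -0.3,
    "C18:0": -0.3,
    "C14:0": -0.1,
    "C22:1(n-9) alcohol": -0.3,
}

#: latent effects per degC: warm water favors longer saturated chains
#: (C18:0 up, C14:0 down), monounsaturation declines, alcohols are polar
DEFAULT_BETA_TEMP: dict[str, float] = {
    "C18:0": 0.08,
    "C14:0": -0.128,
    "C18:1": -0.02,
    "C17:0": 0.03,
    "C17:1": -0.03,
    "C22:1(n-9) alcohol": -0.08,
}

DEFAULT_SPLIT_RATIOS: tuple[float, ...] = (1, 2, 5, 10, 20, 25, 50, 100)

#: compounds integrated on a shared base peak must resolve on another ion
DEFAULT_COELUTION_GROUPS: tuple[tuple[str, ...], ...] = (("C20:5", "C22:6"),)


@dataclass(frozen=True)
class Locale:
    """A collection locale with a piecewise-exponential water column.

    T(z) = deep_temp + (surface_temp - deep_temp) * exp(-z / z_scale):
    monotone non-increasing in depth, surface_temp at the surface, tending
    to deep_temp at depth.
    """

    name: str
    surface_temp: float
    deep_temp: float
    z_scale: float
    max_depth: float

    def temperature_at(self, depth_m: float) -> float:
        if depth_m < 0:
            raise ValueError("depth must be >= 0")
        return self.deep_temp + (self.surface_temp - self.deep_temp) * math.exp(
            -depth_m / self.z_scale
        )


DEFAULT_LOCALES: tuple[Locale, ...] = (
    Locale("arctic", surface_temp=5.0, deep_temp=-1.0, z_scale=150.0, max_depth=3000.0),
    Locale("temperate", surface_temp=15.0, deep_temp=1.5, z_scale=300.0, max_depth=4000.0),
    Locale("tropical", surface_temp=28.0, deep_temp=1.5, z_scale=300.0, max_depth=4000.0),
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic survey.

    Defaults mirror a ~105-specimen, 21-species survey spanning polar,
    temperate and tropical water columns.  Environmental effect sizes are
    latent-scale, per km of depth and per degC; they are configuration, not
    constants, because no field measurement pins them down.
    """

    n_taxa: int = 21
    individuals_per_taxon: int = 5
    locales: tuple[Locale, ...] = DEFAULT_LOCALES
    ou_alpha: float = 2.0      # selection strength per unit tree height
    ou_sigma: float = 0.5      # stationary SD of species latent coordinates
    beta_depth: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_DEPTH)
    )
    beta_temp: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_TEMP)
    )
    noise_sd: float = 0.1      # individual-level latent SD
    temp_center_C: float = 14.0   # reference temperature of the baselines
    depth_center_km: float = 1.5  # reference depth of the baselines
    seed: int = 0
    compounds: tuple[str, ...] = DEFAULT_PANEL
    baseline_logits: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_LOGITS)
    )

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.individuals_per_taxon < 1:
            raise ValueError("need at least 1 individual per taxon")
        if not self.locales:
            raise ValueError("locale list is empty")
        for name, value in (
            ("ou_alpha", self.ou_alpha),
            ("ou_sigma", self.ou_sigma),
            ("noise_sd", self.noise_sd),
        ):
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        for beta in (self.beta_depth, self.beta_temp):
            for k, v in beta.items():
                if not math.isfinite(v):
                    raise ValueError(f"non-finite effect for {k}")
                parse_lipid_label(k)
        for label in self.compounds:
            parse_lipid_label(label)


@dataclass
class GroundTruth:
    """Everything the generator knew before instrument noise was added."""

    tree: Phylogeny
    species_baselines: pd.DataFrame          # taxon x compound latent coords
    true_betas: dict                         # {"depth": {...}, "temp": {...}}
    true_mole_fractions: pd.DataFrame        # sample x compound, rows sum to 1
    true_ionization: dict[str, float]        # compound -> molar coefficient


def simulate_tree(n_taxa: int, seed: int) -> Phylogeny:
    """Random binary ultrametric species tree, height normalized to 1.

    Coalescent-style construction: lineages merge pairwise at strictly
    increasing heights, so the tree is binary with positive branch lengths
    and all tips at equal depth.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_taxa)))
    lineages: list[tuple[_Node, float]] = [
        (_Node(f"sp{i + 1:0{width}d}"), 0.0) for i in range(n_taxa)
    ]
    height = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        height += float(rng.exponential(scale=2.0 / (k * (k - 1))))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha), (b, hb) = lineages[i], lineages[j]
        parent = _Node()
        a.length = height - ha
        b.length = height - hb
        parent.children = [a, b]
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((parent, height))
    root, root_height = lineages[0]
    root.length = None
    tree = Phylogeny(root)
    return tree.scaled(1.0 / root_height)


def simulate_environment(config: SimulationConfig) -> list[SpecimenRecord]:
    """Assign taxa to locales and draw collection depths/temperatures.

    Locales rotate across taxa; within each taxon, half the individuals are
    collected shallow (<= 200 m or the locale maximum) and half deep, so the
    shallow-warm, shallow-cold and deep-cold strata are all populated and
    both analysis slices are guaranteed non-empty.  Temperature follows the
    locale profile deterministically given depth.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    width = max(2, len(str(config.n_taxa)))
    records: list[SpecimenRecord] = []
    for t in range(config.n_taxa):
        taxon = f"sp{t + 1:0{width}d}"
        locale = config.locales[t % len(config.locales)]
        for i in range(config.individuals_per_taxon):
            shallow = i % 2 == 0
            if shallow:
                depth = float(rng.uniform(0.0, min(200.0, locale.max_depth)))
                method = "SCUBA"
            else:
                depth = float(rng.uniform(min(200.0, locale.max_depth), locale.max_depth))
                method = "ROV"
            records.append(
                SpecimenRecord(
                    sample_id=f"{taxon}-{i + 1:02d}",
                    taxon=taxon,
                    depth_m=round(depth, 1),
                    temp_C=round(locale.temperature_at(round(depth, 1)), 3),
                    locale=locale.name,
                    method=method,
                )
            )
    return records


def _latent_matrix(
    tree: Phylogeny,
    records: Sequence[SpecimenRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent coordinates per individual and species baselines."""
    taxa = {r.taxon for r in records}
    tips, D = tree.distance_matrix()
    missing = taxa - set(tips)
    if missing:
        raise ValueError(f"record taxa absent from tree: {sorted(missing)}")
    labels = list(config.compounds)
    m = np.array([config.baseline_logits.get(lab, math.log(1e-3)) for lab in labels])

    # species effects: one stationary OU draw per compound over the tree
    cov = config.ou_sigma**2 * np.exp(-config.ou_alpha * D)
    if config.ou_sigma > 0:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(tips)))
        u = L @ rng.standard_normal((len(tips), len(labels)))
    else:
        u = np.zeros((len(tips), len(labels)))
    baselines = pd.DataFrame(u + m, index=tips, columns=labels)

    bd = np.array([config.beta_depth.get(lab, 0.0) for lab in labels])
    bt = np.array([config.beta_temp.get(lab, 0.0) for lab in labels])
    rows = []
    for r in records:
        z = (
            baselines.loc[r.taxon].to_numpy()
            + bd * (r.depth_m / 1000.0 - config.depth_center_km)
            + bt * (r.temp_C - config.temp_center_C)
            + rng.standard_normal(len(labels)) * config.noise_sd
        )
        rows.append(z)
    latent = pd.DataFrame(rows, index=[r.sample_id for r in records], columns=labels)
    return latent, baselines


def simulate_compositions(
    tree: Phylogeny,
    records: Sequence[SpecimenRecord],
    config: SimulationConfig,
) -> tuple[GroundTruth, list[CompositionProfile]]:
    """Draw per-individual mole-fraction profiles from the latent model."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    latent, baselines = _latent_matrix(tree, records, config, rng)

    z = latent.to_numpy()
    z = z - z.max(axis=1, keepdims=True)
    fractions = np.exp(z)
    fractions /= fractions.sum(axis=1, keepdims=True)
    frac_df = pd.DataFrame(fractions, index=latent.index, columns=latent.columns)

    # molar ionization coefficients: similar mass response across compounds,
    # so the molar coefficient scales inversely with molar mass
    ion_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    true_ionization = {}
    for lab in config.compounds:
        mass_coef = 1e6 * float(ion_rng.uniform(0.8, 1.2))
        true_ionization[lab] = mass_coef / parse_lipid_label(lab).molar_mass

    truth = GroundTruth(
        tree=tree,
        species_baselines=baselines,
        true_betas={"depth": dict(config.beta_depth), "temp": dict(config.beta_temp)},
        true_mole_fractions=frac_df,
        true_ionization=true_ionization,
    )
    profiles = [
        CompositionProfile(sid, dict(zip(frac_df.columns, row)))
        for sid, row in zip(frac_df.index, frac_df.to_numpy())
    ]
    return truth, profiles


def _reference_spectrum(label: str, group: tuple[str, ...] | None) -> MassSpectrum:
    """Synthetic electron-impact spectrum for one compound.

    Saturated FAMEs anchor on the McLafferty ion m/z 74, monounsaturates on
    55, polyunsaturates on 79, and fatty alcohols on 83; the molecular ion
    is retained as a weaker high-mass fragment.  Members of a coelution
    group share their base peak (and a mid-mass fragment), so quantitation
    must fall back to the molecular ion.
    """
    sp = parse_lipid_label(label)
    mw = int(round(sp.molar_mass))
    if sp.is_alcohol:
        base = 83
    elif sp.double_bonds == 0:
        base = 74
    elif sp.double_bonds == 1:
        base = 55
    else:
        base = 79
    intens = {base: 1.0, mw: 0.30, mw - 31: 0.15}
    if group is not None:
        intens[91] = 0.50  # shared aromatic-like fragment within the group
    return MassSpectrum(label, intens)


def simulate_gcms(
    profiles: Sequence[CompositionProfile],
    true_ionization: Mapping[str, float],
    split_ratios: Sequence[float] = DEFAULT_SPLIT_RATIOS,
    seed: int = 0,
    rel_noise: float = 0.0,
    coelution_groups: Sequence[tuple[str, ...]] = DEFAULT_COELUTION_GROUPS,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, MassSpectrum]]:
    """Standards, sample peak table and reference spectra for known profiles.

    Standards: one integral per (compound, split ratio), on a line through
    the origin in on-column fraction with optional relative Gaussian noise.
    Peaks: one single-ion integral per (sample, compound), equal to true
    moles x molar ionization coefficient x a per-sample injection scale.
    """
    if len(set(split_ratios)) < 2:
        raise ValueError("need >=2 distinct split ratios to define a slope")
    if any(k <= 0 for k in true_ionization.values()):
        raise ValueError("ionization coefficients must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))

    compounds = sorted(true_ionization)
    group_of = {}
    for group in coelution_groups:
        for lab in group:
            group_of[lab] = tuple(group)
    spectra = {lab: _reference_spectrum(lab, group_of.get(lab)) for lab in compounds}

    std_rows = []
    for lab in compounds:
        molar_mass = parse_lipid_label(lab).molar_mass
        mass_coef = true_ionization[lab] * molar_mass
        for sr in split_ratios:
            noise = 1.0 + rel_noise * float(rng.standard_normal()) if rel_noise else 1.0
            std_rows.append(
                {
                    "compound": lab,
                    "molar_mass_g_mol": molar_mass,
                    "split_ratio": float(sr),
                    "integral": mass_coef * on_column_fraction(sr) * noise,
                }
            )
    standards = pd.DataFrame(std_rows)

    peak_rows = []
    for prof in profiles:
        scale = float(rng.uniform(500.0, 2000.0))
        for sp in sorted(prof.species, key=lambda s: s.label):
            lab = sp.label
            if lab not in true_ionization:
                continue
            coeluters = [
                spectra[o] for o in group_of.get(lab, ()) if o != lab and o in spectra
            ]
            mz = select_quant_ion(spectra[lab], coeluters)
            noise = 1.0 + rel_noise * float(rng.standard_normal()) if rel_noise else 1.0
            peak_rows.append(
                {
                    "sample_id": prof.sample_id,
                    "compound": lab,
                    "mz": mz,
                    "integral": prof[lab] * scale * true_ionization[lab] * noise,
                }
            )
    peaks = pd.DataFrame(peak_rows)
    return standards, peaks, spectra


def simulate_study(config: SimulationConfig, rel_noise: float = 0.0):
    """Full synthetic survey: tree, specimens, profiles and GC-MS tables."""
    tree = simulate_tree(config.n_taxa, config.seed)
    records = simulate_environment(config)
    truth, profiles = simulate_compositions(tree, records, config)
    standards, peaks, spectra = simulate_gcms(
        profiles, truth.true_ionization, seed=config.seed, rel_noise=rel_noise
    )
    return tree, records, truth, profiles, standards, peaks, spectra
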