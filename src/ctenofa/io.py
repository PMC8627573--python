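"""Plain-text readers and writers for the pipeline's table formats.

All tables are CSV/TSV with fixed column schemas:

- specimens.csv: sample_id, taxon, locale, depth_m, temp_C, method
- composition.csv (long): sample_id, compound, mole_fraction
- standards.csv: compound, molar_mass_g_mol, split_ratio, integral
- peaks.csv: sample_id, compound, mz, integral
- spectra.csv: compound, mz, rel_intensity
- metrics.tsv: sample_id + one column per summary metric
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .lipids import CompositionProfile
from .phylo import Phylogeny, parse_newick
from .pipeline import SpecimenRecord
from .quant import MassSpectrum, PeakObservation, StandardSeries

_FLOAT = "%.12g"

__all__ = [
    "read_tree", "write_tree",
    "read_specimens", "write_specimens",
    "read_composition", "write_composition",
    "read_standards", "write_standards",
    "read_peaks", "write_peaks",
    "read_spectra", "write_spectra",
    "read_metrics", "write_metrics",
    "write_truth",
]


def read_tree(path) -> Phylogeny:
    return parse_newick(Path(path).read_text())


def write_tree(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_specimens(path) -> list[SpecimenRecord]:
    df = pd.read_csv(path)
    return [
        SpecimenRecord(
            sample_id=str(r.sample_id),
            taxon=str(r.taxon),
            depth_m=float(r.depth_m),
            temp_C=float(r.temp_C),
            locale=str(getattr(r, "locale", "")),
            method=str(getattr(r, "method", "")),
        )
        for r in df.itertuples(index=False)
    ]


def write_specimens(records: Sequence[SpecimenRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        path, index=False, float_format=_FLOAT
    )


def read_composition(path) -> list[CompositionProfile]:
    """Long-form composition table -> one profile per sample."""
    df = pd.read_csv(path)
    profiles = []
    for sid, group in df.groupby("sample_id", sort=True):
        profiles.append(
            CompositionProfile(
                str(sid), dict(zip(group["compound"], group["mole_fraction"]))
            )
        )
    return profiles


def write_composition(profiles: Iterable[CompositionProfile], path) -> None:
    rows = [
        {"sample_id": p.sample_id, "compound": sp.label, "mole_fraction": x}
        for p in profiles
        for sp, x in sorted(p.entries.items(), key=lambda kv: kv[0].label)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT)


def composition_wide(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """Samples x compounds mole-fraction matrix (absent compounds = 0)."""
    rows = {p.sample_id: {sp.label: x for sp, x in p.entries.items()} for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()


def read_standards(path) -> list[StandardSeries]:
    df = pd.read_csv(path)
    out = []
    for (compound, mm), group in df.groupby(["compound", "molar_mass_g_mol"], sort=True):
        points = tuple(zip(group["split_ratio"].astype(float), group["integral"].astype(float)))
        out.append(StandardSeries(str(compound), float(mm), points))
    return out


def write_standards(standards: pd.DataFrame, path) -> None:
    standards.to_csv(path, index=False, float_format=_FLOAT)


def read_peaks(path) -> dict[str, list[PeakObservation]]:
    """Peak table grouped by sample id."""
    df = pd.read_csv(path)
    out: dict[str, list[PeakObservation]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.sample_id), []).append(
            PeakObservation(str(r.sample_id), str(r.compound), int(r.mz), float(r.integral))
        )
    return out


def write_peaks(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False, float_format=_FLOAT)


def read_spectra(path) -> dict[str, MassSpectrum]:
    df = pd.read_csv(path)
    out = {}
    for compound, group in df.groupby("compound", sort=True):
        out[str(compound)] = MassSpectrum(
            str(compound), dict(zip(group["mz"].astype(int), group["rel_intensity"]))
        )
    return out


def write_spectra(spectra: Mapping[str, MassSpectrum], path) -> None:
    rows = [
        {"compound": lab, "mz": mz, "rel_intensity": inten}
        for lab in sorted(spectra)
        for mz, inten in sorted(spectra[lab].intensities.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_metrics(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, sep="\t", float_format=_FLOAT)


def write_truth(truth, path) -> None:
    """Ground-truth parameters as JSON (tree as Newick)."""
    blob = {
        "tree_newick": truth.tree.to_newick(),
        "species_baselines": truth.species_baselines.round(12).to_dict(),
        "true_betas": truth.true_betas,
        "true_ionization": truth.true_ionization,
        "true_mole_fractions": truth.true_mole_fractions.round(15).to_dict(),
    }
    Path(path).write_text(json.dumps(blob, indent=1, sort_keys=True))
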