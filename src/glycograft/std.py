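"""Theoretical STD-NMR intensity profiles via the isolated spin-pair
approximation (ISPA).

Saturation transfer from an irradiated protein to a bound ligand falls off as
the inverse sixth power of the inter-proton distance, so for ligand proton *j*
the predicted enhancement is taken proportional to Σ_i R_ij⁻⁶ over protein
protons *i*.  Methyl groups tumble as a unit and are observed as one signal:
the three proton sums are pooled into a single entry.  Profiles are normalized
to the strongest entry = 100, which permits direct comparison with normalized
experimental STD intensities and hence ranking of candidate bound poses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .structure import StructureModel, select_atoms


class STDError(ValueError):
    pass


@dataclass
class STDProfile:
    """Per-proton (or per-methyl) theoretical STD intensities."""

    entries: list[tuple[str, float, float]]  # (label, raw Σ R⁻⁶ in Å⁻⁶, normalized %)

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.entries]

    def normalized(self) -> dict[str, float]:
        return {label: norm for label, _, norm in self.entries}

    def raw(self) -> dict[str, float]:
        return {label: raw for label, raw, _ in self.entries}


def predict_std(
    complex_model: StructureModel,
    ligand_selection: str,
    methyl_groups: dict[str, list[str]] | None = None,
    cutoff: float | None = None,
) -> STDProfile:
    """Predict the STD profile of the ligand in a protonated complex.

    ``methyl_groups`` maps a pooled label (e.g. ``"NAc-Me"``) to the ligand
    proton atom names it absorbs.  ``cutoff`` optionally restricts the protein
    proton sum to a distance shell (Å); by default every protein proton
    contributes (R⁻⁶ decays fast enough that this is cheap and assumption-free).
    Hydrogen-free inputs are refused: ISPA is defined on proton positions.
    """
    ligand = select_atoms(complex_model, ligand_selection)
    if not ligand.atoms:
        raise STDError(f"ligand selection {ligand_selection!r} selects no atoms")
    ligand_serials = {a.serial for a in ligand.atoms}
    ligand_h = [a for a in ligand.atoms if a.is_hydrogen]
    protein_h = [
        a
        for a in complex_model.atoms
        if a.is_hydrogen and a.serial not in ligand_serials
    ]
    if not ligand_h:
        raise STDError("ligand has no hydrogens; STD prediction requires a protonated ligand")
    if not protein_h:
        raise STDError("protein has no hydrogens; protonate the complex first")

    lp = np.array([a.coords for a in ligand_h])
    pp = np.array([a.coords for a in protein_h])
    d = np.linalg.norm(lp[:, None, :] - pp[None, :, :], axis=-1)
    if np.any(d < 1e-6):
        raise STDError("coincident ligand and protein protons")
    contrib = d**-6.0
    if cutoff is not None:
        contrib[d > cutoff] = 0.0
    raw_per_h = contrib.sum(axis=1)

    methyl_groups = methyl_groups or {}
    name_to_group = {
        name: label for label, names in methyl_groups.items() for name in names
    }
    sums: dict[str, float] = {}
    order: list[str] = []
    for atom, raw in zip(ligand_h, raw_per_h):
        label = name_to_group.get(atom.name, atom.name)
        if label not in sums:
            sums[label] = 0.0
            order.append(label)
        sums[label] += float(raw)

    peak = max(sums.values())
    if peak <= 0:
        raise STDError("all R^-6 sums are zero (empty protein shell?)")
    entries = [(label, sums[label], 100.0 * sums[label] / peak) for label in order]
    return STDProfile(entries)


@dataclass
class STDAgreement:
    """Agreement between a theoretical and an experimental profile."""

    spearman_rho: float
    mean_abs_deviation: float  # over normalized intensities, percent points
    n_shared: int
    unmatched_theoretical: list[str]
    unmatched_experimental: list[str]


def compare_std(theoretical: STDProfile, experimental: dict[str, float] | list) -> STDAgreement:
    """Rank-correlate a predicted profile with experimental intensities.

    The experimental table is label → intensity (any common scale; it is
    renormalized to max = 100 before the deviation is computed, and rank
    correlation is scale-free).  At least three shared labels are required.
    """
    if not isinstance(experimental, dict):
        experimental = dict(experimental)
    theo = theoretical.normalized()
    shared = [label for label in theoretical.labels if label in experimental]
    if len(shared) < 3:
        raise STDError(
            f"only {len(shared)} shared proton labels; need at least 3 for comparison"
        )
    exp_max = max(abs(v) for v in experimental.values())
    if exp_max == 0:
        raise STDError("experimental intensities are all zero")
    exp_norm = {k: 100.0 * v / exp_max for k, v in experimental.items()}
    t = np.array([theo[label] for label in shared])
    e = np.array([exp_norm[label] for label in shared])
    rho = float(spearmanr(t, e).statistic)
    mad = float(np.mean(np.abs(t - e)))
    return STDAgreement(
        spearman_rho=rho,
        mean_abs_deviation=mad,
        n_shared=len(shared),
        unmatched_theoretical=[x for x in theoretical.labels if x not in experimental],
        unmatched_experimental=[x for x in experimental if x not in theo],
    )


def rank_poses(
    poses: list[tuple[str, StructureModel]],
    ligand_selection: str,
    experimental: dict[str, float] | list,
    methyl_groups: dict[str, list[str]] | None = None,
    cutoff: float | None = None,
) -> list[tuple[str, STDAgreement]]:
    """Order candidate poses by agreement with the experimental STD profile.

    Sorted by Spearman rank correlation (descending), ties broken by mean
    absolute deviation (ascending); equal statistics preserve input order.
    """
    if len(poses) < 2:
        raise STDError("pose ranking needs at least 2 poses")
    scored = []
    for name, model in poses:
        profile = predict_std(model, ligand_selection, methyl_groups, cutoff)
        scored.append((name, compare_std(profile, experimental)))
    return sorted(
        scored,
        key=lambda item: (-item[1].spearman_rho, item[1].mean_abs_deviation),
    )


def read_experimental_table(path) -> dict[str, float]:
    """Read a two-column (label, intensity) plain-text table; '#' comments."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise STDError(f"malformed experimental table line: {line!r}")
            table[parts[0]] = float(parts[1])
    if not table:
        raise STDError(f"no entries in experimental table {path}")
    return table
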