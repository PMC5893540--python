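"""Geometry reports: minimal inter-residue distances and ion contact
fractions over multi-model coordinate series.

Contact fractions follow the convention: for each residue and cutoff, the
fraction of (frame, ion) observations in which the ion lies within the
cutoff of any atom of the residue.  An alternative normalization (mean ion
count per frame) is available via ``normalization="count_per_frame"``.
Cutoffs are supplied in nm to match the figure convention; coordinates are
Å internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .structure_io import Structure

__all__ = ["min_residue_distance", "ContactProfile", "contact_fractions"]


def min_residue_distance(
    structure: Structure,
    res_a: int,
    res_b: int,
    frame: int = 0,
    heavy_only: bool = True,
) -> float:
    """Minimum distance (Å) between any atom pair of two residues.

    Heavy atoms only by default (crystal structures usually lack H);
    set ``heavy_only=False`` to include hydrogens.
    """
    atoms = structure.frames[frame]

    def coords_of(resnum):
        sel = [
            a.pos
            for a in atoms
            if a.resnum == resnum and not a.het and (not heavy_only or a.element != "H")
        ]
        if not sel:
            raise KeyError(f"residue {resnum} not present in structure")
        return np.array(sel)

    ca, cb = coords_of(res_a), coords_of(res_b)
    diff = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


@dataclass
class ContactProfile:
    """Per-residue ion contact fractions at each cutoff."""

    fractions: pd.DataFrame  # index residue, one column per cutoff (nm)
    ion_species: Tuple[str, ...]
    n_frames: int
    n_ions: int
    normalization: str

    def fraction(self, residue: int, cutoff_nm: float) -> float:
        return float(self.fractions.loc[residue, cutoff_nm])


def contact_fractions(
    trajectory: Structure,
    residues: Optional[Sequence[int]] = None,
    ion_species: Sequence[str] = ("NA", "MG", "CA", "K", "ZN"),
    cutoffs_nm: Sequence[float] = (0.3, 0.6),
    normalization: str = "fraction",
) -> ContactProfile:
    """Ion-residue contact statistics over a multi-model series.

    For every frame and every ion of the requested species, an (ion,
    residue) observation is a contact at a cutoff when the ion sits within
    that distance of any atom of the residue.  ``fraction`` divides contact
    counts by n_frames × n_ions; ``count_per_frame`` divides by n_frames
    only (mean number of ions in contact per frame).
    """
    if trajectory.n_frames < 1:
        raise ValueError("trajectory must contain at least one frame")
    if normalization not in ("fraction", "count_per_frame"):
        raise ValueError("normalization must be fraction or count_per_frame")
    species = tuple(s.upper() for s in ion_species)
    cutoffs = sorted(float(c) for c in cutoffs_nm)
    if residues is None:
        residues = trajectory.residue_numbers()
    residues = list(residues)

    counts = {c: {r: 0 for r in residues} for c in cutoffs}
    n_ions_seen = None
    for frame_atoms in trajectory.frames:
        ions = [a for a in frame_atoms if a.het and a.element in species]
        if n_ions_seen is None:
            n_ions_seen = len(ions)
        if not ions:
            raise ValueError("no ions of the requested species in frame")
        ion_pos = np.array([a.pos for a in ions])
        for r in residues:
            res_pos = np.array(
                [a.pos for a in frame_atoms if a.resnum == r and not a.het]
            )
            if res_pos.size == 0:
                raise KeyError(f"residue {r} not present")
            d = np.sqrt(
                ((ion_pos[:, None, :] - res_pos[None, :, :]) ** 2).sum(axis=2)
            ).min(axis=1)  # per-ion min distance to residue, Å
            for c in cutoffs:
                counts[c][r] += int(np.sum(d <= c * 10.0))

    denom = trajectory.n_frames * (n_ions_seen if normalization == "fraction" else 1)
    table = pd.DataFrame(
        {c: [counts[c][r] / denom for r in residues] for c in cutoffs},
        index=pd.Index(residues, name="residue"),
    )
    return ContactProfile(
        fractions=table,
        ion_species=species,
        n_frames=trajectory.n_frames,
        n_ions=n_ions_seen or 0,
        normalization=normalization,
    )
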