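"""Rigidity-transmission allostery (RTA).

For two disjoint sites A and B in a body-bar constraint network, the number
of degrees of freedom transmittable between them is

    DOF_AB = A_max + B_max − AB_max − 6

where A_max, B_max and AB_max are the conformational degrees of freedom
available to A, B and A∪B (pebble-game counts) and the subtracted 6 removes
the trivial rigid-body motions.  Positive DOF_AB means motions of A and B
are mechanically coupled beyond a shared rigid motion — rigidity-based
allosteric transmission.

Scanning proceeds by sweeping the hydrogen-bond energy cutoff (weak bonds
dropped first), computing DOF_AB at each cutoff, and integrating the
clamped curve (rectangle rule) into a transmission intensity.  A sliding
three-residue window walks the scanned range; each residue's intensity is
the mean over the (up to three) windows containing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import pebble
from .structure_io import ConstraintNetwork, add_cation_bridge, filter_by_cutoff

__all__ = [
    "TransmissionPoint",
    "TransmissionProfile",
    "transmitted_dof",
    "transmission_curve",
    "intensity",
    "window_scan",
    "BridgeSpec",
    "bridge_comparison",
]

DEFAULT_SWEEP = (0.0, -6.0, 0.01)
DEFAULT_SINK = (208, 230, 291)  # helix 5/6/7 intracellular tips in the receptor


@dataclass(frozen=True)
class TransmissionPoint:
    e_cut: float
    a_max: int
    b_max: int
    ab_max: int

    @property
    def dof_ab_raw(self) -> int:
        return self.a_max + self.b_max - self.ab_max - 6

    @property
    def dof_ab(self) -> int:
        return max(0, self.dof_ab_raw)


@dataclass
class TransmissionProfile:
    """DOF_AB versus hydrogen-bond energy cutoff, descending in E_cut."""

    points: List[TransmissionPoint]
    step: float

    @property
    def intensity(self) -> float:
        return intensity(self)

    def as_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        return (
            np.array([p.e_cut for p in self.points]),
            np.array([p.dof_ab for p in self.points]),
        )


def transmitted_dof(
    network, site_a: Sequence[int], site_b: Sequence[int]
) -> TransmissionPoint:
    """Single-cutoff DOF_AB between two disjoint body sets."""
    sa, sb = sorted(set(site_a)), sorted(set(site_b))
    if not sa or not sb:
        raise ValueError("sites must be non-empty")
    if set(sa) & set(sb):
        raise ValueError("sites A and B overlap")
    game = pebble.build_game(network)
    a_max = game.copy().collect_on(sa)
    b_max = game.copy().collect_on(sb)
    ab_max = game.copy().collect_on(sa + sb)
    return TransmissionPoint(e_cut=0.0, a_max=a_max, b_max=b_max, ab_max=ab_max)


def _sweep_grid(sweep: Tuple[float, float, float]) -> np.ndarray:
    start, stop, step = sweep
    if step <= 0:
        raise ValueError("sweep step must be positive")
    if start < stop:
        raise ValueError("sweep must descend (start >= stop)")
    n = int(round((start - stop) / step)) + 1
    if n < 1:
        raise ValueError("empty sweep")
    return start - step * np.arange(n)


def transmission_curve(
    network: ConstraintNetwork,
    site_a: Sequence[int],
    site_b: Sequence[int],
    sweep: Tuple[float, float, float] = DEFAULT_SWEEP,
) -> TransmissionProfile:
    """DOF_AB across an energy-cutoff sweep.

    The curve is piecewise constant, changing only where a hydrogen bond's
    energy crosses the cutoff, so pebble games are built once per distinct
    retained-bond set and re-read for every grid point in between.
    """
    grid = _sweep_grid(sweep)
    cache: Dict[int, TransmissionPoint] = {}
    energies = np.array(network.hbond_energies())
    points = []
    for e_cut in grid:
        n_retained = int(np.sum(energies <= e_cut + 1e-12))
        if n_retained not in cache:
            sub = filter_by_cutoff(network, float(e_cut))
            tp = transmitted_dof(sub, site_a, site_b)
            cache[n_retained] = tp
        tp = cache[n_retained]
        points.append(
            TransmissionPoint(
                e_cut=float(e_cut), a_max=tp.a_max, b_max=tp.b_max, ab_max=tp.ab_max
            )
        )
    return TransmissionProfile(points=points, step=sweep[2])


def intensity(profile: TransmissionProfile) -> float:
    """Area under the clamped transmission curve (rectangle rule)."""
    if len(profile.points) < 2:
        raise ValueError("profile needs at least 2 points")
    return float(sum(p.dof_ab for p in profile.points) * profile.step)


@dataclass
class WindowScanResult:
    windows: List[Tuple[int, int, int]]
    profiles: List[TransmissionProfile]
    window_intensity: Dict[Tuple[int, int, int], float]
    residue_intensity: Dict[int, float]


def window_scan(
    network: ConstraintNetwork,
    residue_range: Tuple[int, int],
    sink_residues: Sequence[int] = DEFAULT_SINK,
    sweep: Tuple[float, float, float] = DEFAULT_SWEEP,
) -> WindowScanResult:
    """Slide a three-consecutive-residue window over `residue_range` and
    compute the transmission profile of each window against the sink.

    Residue intensity is the mean of the intensities of the (up to three)
    windows containing the residue; terminal residues use whatever windows
    exist.  The sink must not overlap the scanned range.
    """
    lo, hi = residue_range
    residues = list(range(lo, hi + 1))
    if len(residues) < 3:
        raise ValueError("residue range must cover at least 3 residues")
    if set(residues) & set(sink_residues):
        raise ValueError("scan range overlaps the sink")
    sink_site = network.site_atoms(sink_residues)

    windows = [(r, r + 1, r + 2) for r in residues[:-2]]
    profiles = []
    w_int: Dict[Tuple[int, int, int], float] = {}
    for w in windows:
        site = network.site_atoms(w)
        prof = transmission_curve(network, site, sink_site, sweep)
        profiles.append(prof)
        w_int[w] = prof.intensity
    r_int: Dict[int, float] = {}
    for r in residues:
        containing = [w for w in windows if r in w]
        r_int[r] = float(np.mean([w_int[w] for w in containing])) if containing else 0.0
    return WindowScanResult(
        windows=windows, profiles=profiles, window_intensity=w_int,
        residue_intensity=r_int,
    )


@dataclass(frozen=True)
class BridgeSpec:
    """A cation bridge: the coordinating atoms (body indices) and the mode
    used to rigidify it."""

    atoms: Tuple[int, ...]
    mode: str = "explicit_ion"
    label: str = ""


@dataclass
class BridgeComparison:
    base: WindowScanResult
    bridged: WindowScanResult
    delta: Dict[int, float]  # bridged − base per residue


def bridge_comparison(
    network: ConstraintNetwork,
    bridges: Sequence[BridgeSpec],
    residue_range: Tuple[int, int],
    sink_residues: Sequence[int] = DEFAULT_SINK,
    sweep: Tuple[float, float, float] = DEFAULT_SWEEP,
) -> BridgeComparison:
    """Window-scan the unmodified network and the cation-bridged network and
    report per-residue intensity deltas."""
    base = window_scan(network, residue_range, sink_residues, sweep)
    bridged_net = network
    for b in bridges:
        bridged_net = add_cation_bridge(bridged_net, list(b.atoms), b.mode)
    bridged = window_scan(bridged_net, residue_range, sink_residues, sweep)
    delta = {
        r: bridged.residue_intensity[r] - base.residue_intensity[r]
        for r in base.residue_intensity
    }
    return BridgeComparison(base=base, bridged=bridged, delta=delta)
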