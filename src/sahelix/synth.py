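"""Synthetic data generators for testing the survey and trajectory analyses.

The analyses in this package were designed against two kinds of input that
cannot be shipped: a large culled set of crystal-structure helices, and
multi-hundred-nanosecond explicit-solvent MD trajectories.  The generators
here emulate the *statistical structure* those inputs present to the
analysis code — not their physics — so that every downstream statistic can
be checked against planted ground truth:

* :func:`gen_two_state_series` draws a discrete two-state (formed/broken)
  process with geometric dwell times, the memoryless picture of salt-bridge
  formation and breakage kinetics;
* :func:`gen_distance_series` decorates a state series with distances whose
  formed-state distribution is a two-component mixture (peaks near 2.8 and
  3.7 A, the two bridge geometries seen in simulation), plus an optional
  "indirect", water-separated component at 5.6-6.0 A assigned to broken
  frames;
* :func:`gen_planted_ensemble` builds ideal-helix structure sets in which a
  chosen fraction of charge pairings is posed at salt-bridge-capable
  rotamer combinations, the rest at combinations that cannot bridge;
* :func:`gen_dynamic_trajectory` animates a rigid ideal helix by switching
  pair side chains between a capable and a non-capable combination
  according to independent two-state processes.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .sequences import PolypeptideSequence, ChargePairing, enumerate_pairings, parse_mode
from .helixgeom import (
    HelixStructure,
    RotamerCombination,
    build_ideal_helix,
    rotamer_combination_scan,
    set_chi,
    SALT_BRIDGE_CUTOFF,
)
from .trajstats import Trajectory, DEFAULT_FRAME_INTERVAL

logger = logging.getLogger(__name__)

#: distance (A) every arrangement of a combination must exceed for the
#: combination to serve as a planted "off" (non-bridged) pose
OFF_DISTANCE_MIN = 4.5


# -- two-state dwell process -----------------------------------------------


@dataclass(frozen=True)
class DwellProcessParams:
    """Two-state process with geometric dwell times.

    ``mean_on`` / ``mean_off`` are the mean dwell lengths in frames (>= 1);
    the stationary occupancy is mean_on / (mean_on + mean_off).
    """

    mean_on: float
    mean_off: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_on < 1 or self.mean_off < 1:
            raise ValueError("dwell means must be >= 1 frame")
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")

    @property
    def stationary_occupancy(self) -> float:
        return self.mean_on / (self.mean_on + self.mean_off)


def gen_two_state_series(params: DwellProcessParams):
    """Draw one boolean formed/broken series with geometric dwells.

    Returns ``(states, truth)`` where truth records the configured
    stationary occupancy and the realized empirical occupancy and event
    count.  Deterministic in (params, seed).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    states = np.empty(n, dtype=bool)
    if n == 0:
        return states, {
            "stationary_occupancy": params.stationary_occupancy,
            "empirical_occupancy": float("nan"),
            "n_events": 0,
        }
    state = bool(rng.random() < params.stationary_occupancy)
    pos = 0
    while pos < n:
        mean = params.mean_on if state else params.mean_off
        run = int(rng.geometric(1.0 / mean))
        states[pos: pos + run] = state
        pos += run
        state = not state
    padded = np.concatenate([[False], states, [False]]).astype(int)
    n_events = int((np.diff(padded) == 1).sum())
    truth = {
        "stationary_occupancy": params.stationary_occupancy,
        "empirical_occupancy": float(states.mean()),
        "n_events": n_events,
    }
    return states, truth


# -- distance emissions ----------------------------------------------------


@dataclass(frozen=True)
class DistanceEmissionParams:
    """Distance distributions conditioned on the bridge state.

    Formed frames draw from a two-Gaussian mixture below the 4 A cutoff
    (defaults: weights 0.6/0.4 at 2.8/3.7 A, sigma 0.15 A — the two direct
    salt-bridge geometries).  Broken frames draw, with probability
    ``indirect_weight``, from a narrow "indirect" component centred between
    5.6 and 6.0 A (a bridge separated by one water molecule) and otherwise
    from a broad separated-state distribution; all broken-state emissions
    exceed 4.5 A.
    """

    on_centres: tuple[float, float] = (2.8, 3.7)
    on_weights: tuple[float, float] = (0.6, 0.4)
    on_sigma: float = 0.15
    indirect_centre: float = 5.8
    indirect_sigma: float = 0.12
    indirect_weight: float = 0.2
    off_min: float = 4.5

    def __post_init__(self) -> None:
        if abs(sum(self.on_weights) - 1.0) > 1e-9:
            raise ValueError("on-state component weights must sum to 1")
        if not 0.0 <= self.indirect_weight <= 1.0:
            raise ValueError("indirect_weight must be in [0, 1]")


def gen_distance_series(states: np.ndarray,
                        emission: DistanceEmissionParams | None = None,
                        seed: int = 0) -> np.ndarray:
    """Distances consistent with a boolean state series.

    Formed frames emit strictly below the 4 A bridge cutoff, broken frames
    strictly above ``emission.off_min``, so thresholding the output at 4 A
    reproduces ``states`` exactly.
    """
    emission = emission or DistanceEmissionParams()
    states = np.asarray(states, dtype=bool)
    rng = np.random.default_rng(seed)
    n = states.size
    d = np.empty(n, dtype=float)

    n_on = int(states.sum())
    comp = rng.random(n_on) < emission.on_weights[0]
    centres = np.where(comp, emission.on_centres[0], emission.on_centres[1])
    on = rng.normal(centres, emission.on_sigma)
    # keep formed-state emissions strictly below the cutoff
    on = np.clip(on, 2.0, SALT_BRIDGE_CUTOFF - 0.01)
    d[states] = on

    n_off = n - n_on
    indirect = rng.random(n_off) < emission.indirect_weight
    off = 4.6 + rng.gamma(shape=3.0, scale=0.8, size=n_off)
    ind = rng.normal(emission.indirect_centre, emission.indirect_sigma,
                     size=n_off)
    off = np.where(indirect, np.clip(ind, emission.off_min + 0.01, None), off)
    d[~states] = off
    return d


# -- rotamer palettes ------------------------------------------------------


def _mode_palettes(mode: str) -> tuple[list[RotamerCombination],
                                       list[RotamerCombination]]:
    """(capable combinations, clearly-non-bridging combinations) per mode."""
    rows = rotamer_combination_scan(mode)
    on = [r for r in rows if r.capable]
    off = [r for r in rows if (not r.capable) and r.distance > OFF_DISTANCE_MIN]
    if not on:
        raise ValueError(f"no salt-bridge-capable rotamer combination for {mode}")
    if not off:
        raise ValueError(f"no non-bridging rotamer combination for {mode}")
    return on, off


_PALETTE_CACHE: dict[str, tuple[list, list]] = {}


def mode_palettes(mode: str):
    if mode not in _PALETTE_CACHE:
        _PALETTE_CACHE[mode] = _mode_palettes(mode)
    return _PALETTE_CACHE[mode]


def _apply_combination(structure: HelixStructure, pairing: ChargePairing,
                       combo: RotamerCombination) -> None:
    """Pose both residues of a pairing at a scanned combination's chis."""
    first, _, _ = parse_mode(pairing.mode)
    if first == "E":
        e_res, x_res = pairing.donor_index, pairing.partner_index
    else:
        e_res, x_res = pairing.partner_index, pairing.donor_index
    for k, val in enumerate(combo.e_chi):
        set_chi(structure, e_res, k + 1, val)
    for k, val in enumerate(combo.x_chi):
        set_chi(structure, x_res, k + 1, val)


def _check_disjoint(pairings: list[ChargePairing]) -> None:
    used: set[int] = set()
    for p in pairings:
        for r in (p.donor_index, p.partner_index):
            if r in used:
                raise ValueError(
                    f"pairings share residue {r}; planted pairs must use "
                    "disjoint residues")
            used.add(r)


# -- planted structure ensembles -------------------------------------------

#: default planting sequence: isolated E->K(+3) and E->R(+3) pairs (four of
#: each) spaced by alanines so that no two pairings share a residue
DEFAULT_ENSEMBLE_SEQUENCE = ("AAEAAKAA" + "AAEAARAA") * 4


@dataclass(frozen=True)
class PlantedEnsembleSpec:
    """Specification of a planted-salt-bridge helix ensemble.

    ``planting_rates`` maps pairing mode -> fraction of that mode's
    pairings posed at a salt-bridge-capable rotamer combination (the exact
    count ``round(rate x n_pairs)`` is planted per structure; which pairs
    are planted is drawn per structure).  Remaining pairings are posed at
    combinations that place the charges beyond 4.5 A.  ``jitter`` is the
    s.d. (A) of isotropic Gaussian coordinate noise.
    """

    n_structures: int = 20
    sequence: str = DEFAULT_ENSEMBLE_SEQUENCE
    planting_rates: tuple[tuple[str, float], ...] = (
        ("E->K(+3)", 0.5), ("E->R(+3)", 0.5),
    )
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for mode, rate in self.planting_rates:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"planting rate for {mode} outside [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def gen_planted_ensemble(spec: PlantedEnsembleSpec):
    """Build an ideal-helix ensemble with planted salt bridges.

    Returns ``(structures, truth)``: a list of (structure id,
    :class:`HelixStructure`) and a ground-truth dict with, per mode, the
    pairing count per structure, the planted count, and the planted
    fraction.  Raises if the sequence gives pairings sharing residues (the
    planted poses would conflict) or a mode has no capable combination.
    """
    seq = PolypeptideSequence(id="planted", residues=spec.sequence)
    modes = [m for m, _ in spec.planting_rates]
    rates = dict(spec.planting_rates)
    pairings = enumerate_pairings(seq, modes=modes)
    _check_disjoint(pairings)
    by_mode: dict[str, list[ChargePairing]] = {}
    for p in pairings:
        by_mode.setdefault(p.mode, []).append(p)

    rng = np.random.default_rng(spec.seed)
    base = build_ideal_helix(seq)
    structures = []
    planted_total = {m: 0 for m in by_mode}
    for s_idx in range(spec.n_structures):
        st = base.copy()
        for mode, plist in by_mode.items():
            on_pal, off_pal = mode_palettes(mode)
            n_plant = int(round(rates[mode] * len(plist)))
            chosen = set(rng.choice(len(plist), size=n_plant, replace=False))
            for k, pairing in enumerate(plist):
                if k in chosen:
                    combo = on_pal[rng.integers(len(on_pal))]
                    planted_total[mode] += 1
                else:
                    combo = off_pal[rng.integers(len(off_pal))]
                _apply_combination(st, pairing, combo)
        if spec.jitter > 0:
            st.atoms.coord += rng.normal(0.0, spec.jitter,
                                         size=st.atoms.coord.shape)
        structures.append((f"planted_{s_idx:03d}", st))

    truth = {
        "sequence": spec.sequence,
        "modes": {
            mode: {
                "pairs_per_structure": len(plist),
                "planted_per_structure": int(round(rates[mode] * len(plist))),
                "planted_fraction": (int(round(rates[mode] * len(plist)))
                                     / len(plist)) if plist else float("nan"),
                "planted_total": planted_total[mode],
            }
            for mode, plist in by_mode.items()
        },
    }
    return structures, truth


# -- dynamic trajectories --------------------------------------------------


def gen_dynamic_trajectory(
    sequence: str | PolypeptideSequence,
    pair_params: dict[tuple[int, int, str], DwellProcessParams] | None = None,
    seed: int = 0,
    n_frames: int | None = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    modes: tuple[str, ...] | None = None,
    default_params: DwellProcessParams | None = None,
):
    """Animate a rigid ideal helix with switching salt bridges.

    Each pairing follows its own independent two-state dwell process; at
    formed frames the pair's side chains are posed at a fixed
    salt-bridge-capable rotamer combination, at broken frames at a fixed
    far-separated combination.  The backbone never moves.

    ``pair_params`` keys are (donor_index, partner_index, mode); when
    omitted, every pairing of ``modes`` (default: all eight) present in the
    sequence receives ``default_params`` (which must then be given, its
    ``n_frames`` defining the trajectory length).  Pairings must use
    disjoint residues.

    Returns ``(trajectory, truth)`` with per-pair ground-truth state
    series, occupancies and event counts.
    """
    if isinstance(sequence, str):
        sequence = PolypeptideSequence(id="dyn", residues=sequence)
    if pair_params is None:
        if default_params is None:
            raise ValueError("give pair_params or default_params")
        from .sequences import PAIRING_MODES
        use_modes = modes if modes is not None else PAIRING_MODES
        pair_params = {
            (p.donor_index, p.partner_index, p.mode): default_params
            for p in enumerate_pairings(sequence, modes=use_modes)
        }
    pairings = [ChargePairing(donor_index=i, partner_index=j, mode=m)
                for (i, j, m) in pair_params]
    if not pairings:
        raise ValueError("no pairings to animate")
    _check_disjoint(pairings)
    lengths = {p.n_frames for p in pair_params.values()}
    if n_frames is None:
        if len(lengths) != 1:
            raise ValueError("pair_params disagree on n_frames; pass n_frames")
        n_frames = lengths.pop()

    rng = np.random.default_rng(seed)
    base = build_ideal_helix(sequence)
    coords0 = base.atoms.coord

    # two poses per pairing: residue coordinate blocks for on and off
    pose_blocks = []
    truth_series = {}
    for pairing, params in zip(pairings, pair_params.values()):
        on_pal, off_pal = mode_palettes(pairing.mode)
        on_combo = on_pal[int(rng.integers(len(on_pal)))]
        off_combo = off_pal[int(rng.integers(len(off_pal)))]
        sub_seed = int(rng.integers(2**31 - 1))
        states, s_truth = gen_two_state_series(
            DwellProcessParams(params.mean_on, params.mean_off,
                               n_frames, seed=sub_seed))
        mask = (base.residue_mask(pairing.donor_index)
                | base.residue_mask(pairing.partner_index))
        on_st = base.copy()
        _apply_combination(on_st, pairing, on_combo)
        off_st = base.copy()
        _apply_combination(off_st, pairing, off_combo)
        pose_blocks.append((mask, on_st.atoms.coord[mask],
                            off_st.atoms.coord[mask], states))
        key = f"{pairing.mode}@{pairing.donor_index}-{pairing.partner_index}"
        truth_series[key] = {
            "states": states,
            "occupancy": s_truth["empirical_occupancy"],
            "stationary_occupancy": s_truth["stationary_occupancy"],
            "n_events": s_truth["n_events"],
            "mean_on": params.mean_on,
            "mean_off": params.mean_off,
        }

    frames = np.repeat(coords0[np.newaxis, :, :], n_frames, axis=0)
    for mask, on_block, off_block, states in pose_blocks:
        frames[:, mask, :] = np.where(states[:, None, None],
                                      on_block[None, :, :],
                                      off_block[None, :, :])
    import biotite.structure as struc
    stack = struc.from_template(base.atoms, frames)
    traj = Trajectory(frames=stack, frame_interval=frame_interval)
    truth = {"pairs": truth_series, "n_frames": n_frames,
             "frame_interval": frame_interval}
    return traj, truth
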