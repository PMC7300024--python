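"""Interdomain contact counting, per-residue-pair contact frequencies with the
significance rule, and hydrogen-bond number / lifetime / formation-energy
estimates.

Two contact notions are used, both configurable:

* total contacts — heavy-atom pairs across two groups within 3.5 Å;
* residue-level contact — any heavy-atom pair of the residue pair within
  4.5 Å (minimum-distance criterion).

A residue pair is *significant* between two ensembles when the larger of the
two frequencies is ≥ ``freq_min`` (default 0.5) and the absolute frequency
change exceeds ``delta_min`` (default 0.10).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import InsufficientDataError, NonUniformSpacingError, TmrepackError
from .structure_io import AtomRecord, Frame, Trajectory

#: gas constant, kcal/(mol·K)
R_KCAL = 1.9872e-3
#: analysis temperature, K
T_DEFAULT = 303.0
#: reference lifetime for the ΔG estimate, ps
TAU0_PS = 1.0

ResidueKey = tuple[str, int, str]  # (chain, residue_seq, residue_name)


def _heavy(topology: Sequence[AtomRecord], indices: np.ndarray) -> np.ndarray:
    return np.array(
        [i for i in np.asarray(indices, dtype=int) if topology[i].element != "H"],
        dtype=int,
    )


def count_contacts(
    frame: Frame,
    topology: Sequence[AtomRecord],
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 3.5,
) -> int:
    """Number of heavy-atom pairs (a ∈ A, b ∈ B) within ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = _heavy(topology, group_a)
    b = _heavy(topology, group_b)
    if np.intersect1d(a, b).size:
        raise TmrepackError("contact groups overlap")
    if len(a) == 0 or len(b) == 0:
        return 0
    tree_a = cKDTree(frame.positions[a])
    tree_b = cKDTree(frame.positions[b])
    return int(tree_a.count_neighbors(tree_b, cutoff))


@dataclass
class ContactSeries:
    """Boolean contact time series for one residue pair."""

    residue_pair: tuple[ResidueKey, ResidueKey]
    present: np.ndarray

    @property
    def frequency(self) -> float:
        return float(np.mean(self.present))


def contact_frequencies(
    trajectory: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    residue_cutoff: float = 4.5,
) -> list[ContactSeries]:
    """Per-residue-pair contact series over the trajectory.

    A pair is in contact in a frame when its minimum heavy-atom distance is
    ≤ ``residue_cutoff``; pairs never in contact are absent from the output.
    Output is sorted by residue key for determinism.
    """
    if residue_cutoff <= 0:
        raise ValueError("residue_cutoff must be positive")
    topo = trajectory.topology
    a = _heavy(topo, group_a)
    b = _heavy(topo, group_b)
    key_a = [(topo[i].chain_id, topo[i].residue_seq, topo[i].residue_name) for i in a]
    key_b = [(topo[i].chain_id, topo[i].residue_seq, topo[i].residue_name) for i in b]

    n_frames = trajectory.n_frames
    series: dict[tuple[ResidueKey, ResidueKey], np.ndarray] = {}
    for f, fr in enumerate(trajectory.frames):
        tree_a = cKDTree(fr.positions[a])
        tree_b = cKDTree(fr.positions[b])
        pairs = tree_a.sparse_distance_matrix(tree_b, residue_cutoff, output_type="coo_matrix")
        seen = set()
        for ia, ib in zip(pairs.row, pairs.col):
            key = (key_a[ia], key_b[ib])
            if key in seen:
                continue
            seen.add(key)
            if key not in series:
                series[key] = np.zeros(n_frames, dtype=bool)
            series[key][f] = True
    return [
        ContactSeries(residue_pair=k, present=v)
        for k, v in sorted(series.items())
    ]


@dataclass
class SignificancePair:
    """Frequency change for one residue pair under the significance rule."""

    residue_pair: tuple[ResidueKey, ResidueKey]
    freq_wt: float
    freq_variant: float

    @property
    def delta(self) -> float:
        return self.freq_variant - self.freq_wt

    def passes(self, freq_min: float = 0.5, delta_min: float = 0.10) -> bool:
        return max(self.freq_wt, self.freq_variant) >= freq_min and abs(self.delta) > delta_min


def significant_pairs(
    freq_wt: dict[tuple[ResidueKey, ResidueKey], float],
    freq_variant: dict[tuple[ResidueKey, ResidueKey], float],
    freq_min: float = 0.5,
    delta_min: float = 0.10,
) -> list[SignificancePair]:
    """Pairs passing the rule, sorted by |Δfrequency| descending.

    A pair missing from one table has frequency 0 there (covers gained and
    lost contacts).
    """
    out = []
    for key in set(freq_wt) | set(freq_variant):
        pair = SignificancePair(
            residue_pair=key,
            freq_wt=float(freq_wt.get(key, 0.0)),
            freq_variant=float(freq_variant.get(key, 0.0)),
        )
        if pair.passes(freq_min, delta_min):
            out.append(pair)
    out.sort(key=lambda p: (-abs(p.delta), p.residue_pair))
    return out


def frequency_table(series: list[ContactSeries]) -> dict:
    """Map residue pair → frequency, for feeding :func:`significant_pairs`."""
    return {s.residue_pair: s.frequency for s in series}


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

_DONOR_ELEMENTS = frozenset({"N", "O", "S"})
_H_BOND_MAX = 1.25  # Å, covalent D–H recognition distance


def find_donor_hydrogens(
    frame: Frame,
    topology: Sequence[AtomRecord],
    donor_indices: np.ndarray,
) -> list[tuple[int, int]]:
    """(donor, hydrogen) pairs: H within 1.25 Å of an N/O/S donor, same residue.

    Donors with no bonded hydrogen are skipped with a warning.
    """
    pairs = []
    h_by_res: dict[tuple[str, int], list[int]] = {}
    for i, atom in enumerate(topology):
        if atom.element == "H":
            h_by_res.setdefault((atom.chain_id, atom.residue_seq), []).append(i)
    for d in np.asarray(donor_indices, dtype=int):
        atom = topology[d]
        if atom.element not in _DONOR_ELEMENTS:
            continue
        found = False
        for h in h_by_res.get((atom.chain_id, atom.residue_seq), []):
            if np.linalg.norm(frame.positions[h] - frame.positions[d]) <= _H_BOND_MAX:
                pairs.append((int(d), int(h)))
                found = True
        if not found:
            warnings.warn(
                f"donor {atom.chain_id}/{atom.residue_name}{atom.residue_seq}:"
                f"{atom.atom_name} has no bonded hydrogen; skipped"
            )
    return pairs


def hbond_detect(
    frame: Frame,
    topology: Sequence[AtomRecord],
    donors: np.ndarray,
    acceptors: np.ndarray,
    d_max: float = 3.5,
    angle_max: float = 30.0,
) -> list[tuple[int, int, int]]:
    """(donor, hydrogen, acceptor) triples with D–A ≤ d_max and ∠(H–D–A) ≤ angle_max.

    Donor atoms must carry explicit hydrogens; CA-only fixtures are rejected
    by the warning path in :func:`find_donor_hydrogens` (no silent geometry
    invention).
    """
    dh = find_donor_hydrogens(frame, topology, donors)
    acc = np.asarray(acceptors, dtype=int)
    acc = np.array([i for i in acc if topology[i].element in _DONOR_ELEMENTS], dtype=int)
    if not dh or len(acc) == 0:
        return []
    tree = cKDTree(frame.positions[acc])
    triples = []
    for d, h in dh:
        for j in tree.query_ball_point(frame.positions[d], d_max):
            a = int(acc[j])
            if a == d:
                continue
            v_da = frame.positions[a] - frame.positions[d]
            v_dh = frame.positions[h] - frame.positions[d]
            cosang = float(
                np.dot(v_da, v_dh) / (np.linalg.norm(v_da) * np.linalg.norm(v_dh))
            )
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle <= angle_max:
                triples.append((d, h, a))
    return sorted(triples)


def mean_dwell_length(present: np.ndarray) -> float:
    """Mean length (frames) of maximal runs of consecutive True values."""
    runs = []
    count = 0
    for v in np.asarray(present, dtype=bool):
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return float(np.mean(runs)) if runs else 0.0


def hbond_free_energy(tau_ps: float, temperature: float = T_DEFAULT) -> float:
    """ΔG of H-bond formation: −RT ln(τ/τ₀), τ₀ = 1 ps."""
    if tau_ps <= 0:
        raise ValueError("lifetime must be positive")
    return -R_KCAL * temperature * math.log(tau_ps / TAU0_PS)


@dataclass
class HBondStats:
    """Per-triple occupancy with lifetime and formation-energy estimate."""

    triple: tuple[int, int, int]
    present: np.ndarray
    tau_ps: float
    dg_kcal_mol: float

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.present))


@dataclass
class HBondSummary:
    """Group-pair summary across all observed triples."""

    mean_count: float     # average H-bonds per frame
    mean_tau_ps: float
    mean_dg_kcal_mol: float
    n_triples: int


def hbond_stats(
    trajectory: Trajectory,
    donors: np.ndarray,
    acceptors: np.ndarray,
    dt_ps: float | None = None,
    d_max: float = 3.5,
    angle_max: float = 30.0,
    temperature: float = T_DEFAULT,
) -> tuple[list[HBondStats], HBondSummary]:
    """Occupancy, lifetime τ (mean continuous dwell × dt) and ΔG per triple.

    Frame times must be uniformly spaced; pass ``dt_ps`` explicitly when the
    trajectory has no time stamps. Triples never bonded are absent.
    """
    if trajectory.n_frames < 2:
        raise InsufficientDataError("need ≥ 2 frames for lifetime statistics")
    times = [fr.time for fr in trajectory.frames]
    if dt_ps is None:
        if any(t is None for t in times):
            raise NonUniformSpacingError("no frame times; pass dt_ps explicitly")
        diffs = np.diff(np.array(times, dtype=float))
        if np.ptp(diffs) > 1e-9:
            raise NonUniformSpacingError("frame times are not uniformly spaced")
        dt_ps = float(diffs[0])

    occupancy: dict[tuple[int, int, int], np.ndarray] = {}
    per_frame_counts = np.zeros(trajectory.n_frames)
    for f, fr in enumerate(trajectory.frames):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-frame donor warnings repeat
            triples = hbond_detect(
                fr, trajectory.topology, donors, acceptors, d_max, angle_max
            )
        per_frame_counts[f] = len(triples)
        for t in triples:
            if t not in occupancy:
                occupancy[t] = np.zeros(trajectory.n_frames, dtype=bool)
            occupancy[t][f] = True

    stats_list = []
    for t, present in sorted(occupancy.items()):
        tau = mean_dwell_length(present) * dt_ps
        stats_list.append(
            HBondStats(
                triple=t,
                present=present,
                tau_ps=tau,
                dg_kcal_mol=hbond_free_energy(tau, temperature),
            )
        )
    summary = HBondSummary(
        mean_count=float(per_frame_counts.mean()),
        mean_tau_ps=float(np.mean([s.tau_ps for s in stats_list])) if stats_list else 0.0,
        mean_dg_kcal_mol=float(np.mean([s.dg_kcal_mol for s in stats_list]))
        if stats_list
        else float("nan"),
        n_triples=len(stats_list),
    )
    return stats_list, summary
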