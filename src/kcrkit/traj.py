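"""MD-trajectory selectivity observables.

Operates on a minimal trajectory container (atom table + coordinate
frames) and computes the observables used to characterize K+ selectivity
in channelrhodopsin simulations: inter-selection distances and their
histograms (e.g. the Y222 side chain relative to its tryptophan partner),
hysteresis-based tight/loose conformational occupancy, first-shell
hydration numbers of a permeant ion, salt-bridge/contact occupancy
(e.g. R244-D116), and transient site-binding events near the intracellular
constriction.

Coordinates are treated as unwrapped; periodic imaging is unsupported and
a sanity check warns when frame-to-frame jumps look like wrapping
artifacts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist

__all__ = [
    "TrajectoryBundle", "Selection", "StateSeries", "BindingEvent",
    "BindingEvents", "EmptySelectionError",
    "distance_series", "distance_histogram", "classify_two_state",
    "auto_thresholds", "hydration_number", "contact_occupancy",
    "detect_binding_events",
]

TIGHT, LOOSE, UNDEFINED = "tight", "loose", "undefined"

ATOM_COLUMNS = ("index", "name", "resname", "resnum", "chain", "element")


class EmptySelectionError(ValueError):
    """A selection predicate resolved to zero atoms."""


@dataclass
class TrajectoryBundle:
    """Atom table plus per-frame coordinates in Angstrom.

    ``atoms`` is a DataFrame with columns index/name/resname/resnum/chain/
    element (1-based residue numbers, PDB convention); ``coords`` has shape
    (n_frames, n_atoms, 3). ``frame_interval_ps`` is optional metadata.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    frame_interval_ps: float | None = None
    check_wrapping: bool = True

    def __post_init__(self):
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"{self.coords.shape[1]} coordinate columns vs "
                f"{len(self.atoms)} atoms in the table"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        if self.check_wrapping:
            self._warn_if_wrapped()

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def _warn_if_wrapped(self):
        if self.n_frames < 2:
            return
        extent = np.ptp(self.coords.reshape(-1, 3), axis=0)
        jumps = np.abs(np.diff(self.coords, axis=0)).max(axis=(0, 1))
        big = (extent > 0) & (jumps > 0.5 * extent)
        if np.any(big):
            warnings.warn(
                "frame-to-frame atom jumps exceed half the coordinate extent "
                "on axis " + ",".join("xyz"[i] for i in np.flatnonzero(big))
                + "; coordinates may be periodically wrapped, which this "
                "module does not support"
            )


_FIELD_MAP = {"resi": "resnum", "resn": "resname", "name": "name",
              "chain": "chain", "element": "element", "index": "index"}


@dataclass(frozen=True)
class Selection:
    """Conjunction of equality predicates over atom-table columns.

    Built from a PyMOL-flavoured string of `and`-joined clauses, e.g.
    ``"resi 222 and name OH"`` or ``"resn HOH and element O"``. Each clause
    may list alternatives separated by ``+`` (``"name OD1+OD2"``).
    """

    clauses: tuple[tuple[str, tuple[str, ...]], ...]
    text: str = ""

    @classmethod
    def parse(cls, text: str) -> "Selection":
        clauses = []
        for part in re.split(r"\s+and\s+", text.strip()):
            tokens = part.split()
            if len(tokens) != 2:
                raise ValueError(f"cannot parse selection clause {part!r}")
            key, value = tokens
            if key not in _FIELD_MAP:
                raise ValueError(
                    f"unknown selection field {key!r}; "
                    f"known fields: {sorted(_FIELD_MAP)}"
                )
            clauses.append((_FIELD_MAP[key], tuple(value.split("+"))))
        return cls(tuple(clauses), text=text)

    def resolve(self, atoms: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(atoms), dtype=bool)
        for column, values in self.clauses:
            col = atoms[column]
            if column in ("resnum", "index"):
                vals = [int(v) for v in values]
            else:
                vals = list(values)
            mask &= col.isin(vals).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise EmptySelectionError(
                f"selection {self.text or self.clauses!r} matches no atoms")
        return idx


def _as_selection(sel: "Selection | str") -> Selection:
    return Selection.parse(sel) if isinstance(sel, str) else sel


@dataclass
class StateSeries:
    labels: list[str]
    occupancy: dict[str, float]
    transitions: int


@dataclass(frozen=True)
class BindingEvent:
    start_frame: int
    end_frame: int  # inclusive
    mean_distance_A: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class BindingEvents:
    events: list[BindingEvent]
    bound_fraction: float


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_series(traj: TrajectoryBundle, sel_a: Selection | str,
                    sel_b: Selection | str, mode: str = "centroid") -> np.ndarray:
    """Per-frame distance (Angstrom) between two selections.

    ``centroid`` uses unweighted selection centroids; ``min-pair`` the
    minimum inter-atom distance.
    """
    if mode not in ("centroid", "min-pair"):
        raise ValueError(f"mode must be 'centroid' or 'min-pair', got {mode!r}")
    ia = _as_selection(sel_a).resolve(traj.atoms)
    ib = _as_selection(sel_b).resolve(traj.atoms)
    if mode == "centroid":
        ca = traj.coords[:, ia].mean(axis=1)
        cb = traj.coords[:, ib].mean(axis=1)
        return np.linalg.norm(ca - cb, axis=1)
    return np.array([
        cdist(traj.coords[f, ia], traj.coords[f, ib]).min()
        for f in range(traj.n_frames)
    ])


def distance_histogram(distances: np.ndarray, bin_width_A: float = 0.1
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin edges) with fixed-width bins."""
    d = np.asarray(distances, dtype=float)
    lo = np.floor(d.min() / bin_width_A) * bin_width_A
    hi = np.ceil(d.max() / bin_width_A) * bin_width_A
    nbins = max(int(round((hi - lo) / bin_width_A)), 1)
    return np.histogram(d, bins=nbins, range=(lo, hi))


# ---------------------------------------------------------------------------
# two-state occupancy
# ---------------------------------------------------------------------------

def classify_two_state(distances: np.ndarray, low_threshold: float,
                       high_threshold: float) -> StateSeries:
    """Hysteresis classifier for tight/loose conformational states.

    Enter ``tight`` when d < low_threshold, ``loose`` when
    d > high_threshold, otherwise keep the previous label; frames before
    the first crossing are ``undefined``. Hysteresis prevents a signal
    chattering inside the dead band from registering spurious transitions.
    Occupancies are computed over defined frames only.
    """
    if not low_threshold < high_threshold:
        raise ValueError(
            f"low_threshold ({low_threshold}) must be below "
            f"high_threshold ({high_threshold})"
        )
    labels: list[str] = []
    state = UNDEFINED
    transitions = 0
    for d in np.asarray(distances, dtype=float):
        new = state
        if d < low_threshold:
            new = TIGHT
        elif d > high_threshold:
            new = LOOSE
        if new != state and state != UNDEFINED:
            transitions += 1
        state = new
        labels.append(state)
    arr = np.array(labels)
    defined = arr != UNDEFINED
    n_def = int(defined.sum())
    occ = {TIGHT: 0.0, LOOSE: 0.0}
    if n_def:
        occ[TIGHT] = float((arr == TIGHT).sum()) / n_def
        occ[LOOSE] = float((arr == LOOSE).sum()) / n_def
    return StateSeries(labels=labels, occupancy=occ, transitions=transitions)


def auto_thresholds(distances: np.ndarray, *, bin_width_A: float = 0.1,
                    margin_A: float = 0.5) -> tuple[float, float]:
    """Hysteresis thresholds from the two largest histogram modes.

    Returns (tight_mode + margin, loose_mode - margin). Manual thresholds
    always take precedence over this heuristic; it raises when the
    histogram is unimodal or the modes are closer than 2*margin.
    """
    counts, edges = distance_histogram(distances, bin_width_A)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, props = find_peaks(np.concatenate([[0], counts, [0]]),
                              height=0.05 * counts.max())
    peaks = peaks - 1
    if peaks.size < 2:
        raise ValueError("distance histogram is not bimodal; "
                         "supply thresholds manually")
    top2 = peaks[np.argsort(props["peak_heights"])[-2:]]
    m_lo, m_hi = np.sort(centers[top2])
    if m_hi - m_lo <= 2 * margin_A:
        raise ValueError(
            f"histogram modes at {m_lo:.2f} and {m_hi:.2f} A are too close "
            f"for a {margin_A} A hysteresis margin"
        )
    return float(m_lo + margin_A), float(m_hi - margin_A)


# ---------------------------------------------------------------------------
# hydration, contacts, binding
# ---------------------------------------------------------------------------

def hydration_number(traj: TrajectoryBundle, ion: Selection | str,
                     waters: Selection | str, cutoff_A: float = 3.5
                     ) -> tuple[np.ndarray, float]:
    """First-shell water count around a single ion, per frame, plus mean.

    Counts water (oxygen) atoms with distance <= cutoff (inclusive). The
    ion selection must resolve to exactly one atom.
    """
    ion_sel = _as_selection(ion)
    ii = ion_sel.resolve(traj.atoms)
    if ii.size != 1:
        raise ValueError(
            f"ion selection {ion_sel.text!r} resolves to {ii.size} atoms; "
            "need exactly 1"
        )
    iw = _as_selection(waters).resolve(traj.atoms)
    d = np.linalg.norm(traj.coords[:, iw] - traj.coords[:, ii], axis=2)
    counts = (d <= cutoff_A).sum(axis=1)
    return counts, float(counts.mean())


def contact_occupancy(traj: TrajectoryBundle, sel_a: Selection | str,
                      sel_b: Selection | str, cutoff_A: float = 4.0
                      ) -> tuple[float, np.ndarray]:
    """Fraction of frames with min-pair distance <= cutoff, plus the series."""
    d = distance_series(traj, sel_a, sel_b, mode="min-pair")
    in_contact = d <= cutoff_A
    return float(in_contact.mean()), in_contact


def detect_binding_events(distances: np.ndarray, cutoff_A: float = 5.0,
                          min_dwell_frames: int = 1) -> BindingEvents:
    """Maximal runs of frames within cutoff, discarding sub-dwell runs.

    The bound fraction counts only frames inside retained events, so with
    ``min_dwell_frames = 1`` it equals the plain contact occupancy.
    """
    if min_dwell_frames < 1:
        raise ValueError("min_dwell_frames must be >= 1")
    d = np.asarray(distances, dtype=float)
    bound = d <= cutoff_A
    padded = np.concatenate([[False], bound, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    events = [
        BindingEvent(int(s), int(e), float(d[s:e + 1].mean()))
        for s, e in zip(starts, ends)
        if e - s + 1 >= min_dwell_frames
    ]
    n_bound = sum(ev.n_frames for ev in events)
    return BindingEvents(events=events,
                         bound_fraction=n_bound / d.size if d.size else 0.0)
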