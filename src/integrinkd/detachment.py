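"""Micropipette detachment-assay analysis.

A computer-controlled micropipette probes adhered cells with stepwise
increasing negative-pressure pulses; after each round the cells still
attached are re-counted.  This module turns those per-round counts into
detachment curves (averaged or pooled across replicates), detachment
pressure histograms, the weighted-average adhesion statistic W, a
weak/moderate/strong subpopulation decomposition, and a condition-by-bin
adhesion heat map.

Conventions
-----------
* Round 0 is the state before any pressure is applied: the remaining
  fraction there is 1 by definition.
* A cell detached in round n has a critical pressure in the half-open bin
  (p_{n-1}, p_n] with p_0 = 0 atm; its detachment pressure is represented
  by the bin midpoint.
* Cells never detached occupy a terminal bin whose midpoint extrapolates
  the last step: p_N + (p_N - p_{N-1})/2 (with p_0 = 0 when N = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InvalidDataError, InvalidParameterError

#: Pressure schedule used by the assay design: six rounds, 0.07 to 0.22 atm
#: in steps of 0.03 atm, 25 ms pulses.
DEFAULT_PRESSURES = (0.07, 0.10, 0.13, 0.16, 0.19, 0.22)
DEFAULT_PULSE_MS = 25.0


@dataclass(frozen=True)
class PressureSchedule:
    """Ascending magnitudes of the applied negative-pressure rounds, atm."""

    pressures: tuple[float, ...] = DEFAULT_PRESSURES
    pulse_ms: float = DEFAULT_PULSE_MS

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        if p.size < 1:
            raise InvalidParameterError("schedule needs at least one pressure")
        if not np.all(p > 0):
            raise InvalidParameterError("pressures must be positive")
        if p.size > 1 and not np.all(np.diff(p) > 0):
            raise InvalidParameterError("pressures must be strictly increasing")
        if not self.pulse_ms > 0:
            raise InvalidParameterError("pulse_ms must be positive")
        object.__setattr__(self, "pressures", tuple(float(x) for x in p))

    @property
    def n_rounds(self) -> int:
        return len(self.pressures)

    def bin_edges(self) -> np.ndarray:
        """Histogram bin edges [0, p_1, ..., p_N, terminal_edge].

        The terminal edge extends the last step symmetrically so that the
        terminal bin midpoint is p_N + (p_N - p_{N-1})/2; for a single-round
        schedule the previous edge is p_0 = 0 and the midpoint is 1.5 p_1.
        """
        p = np.asarray(self.pressures, dtype=float)
        prev = p[-2] if p.size > 1 else 0.0
        terminal_edge = p[-1] + (p[-1] - prev)
        return np.concatenate([[0.0], p, [terminal_edge]])

    def bin_midpoints(self) -> np.ndarray:
        edges = self.bin_edges()
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class ReplicateCounts:
    """Cell counts for one replicate: initial count and remaining after each round."""

    initial: int
    remaining: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = (self.initial, *self.remaining)
        if any(int(c) != c or c < 0 for c in counts):
            raise InvalidDataError("cell counts must be non-negative integers")
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise InvalidDataError("remaining counts must be non-increasing across rounds")
        object.__setattr__(self, "initial", int(self.initial))
        object.__setattr__(self, "remaining", tuple(int(c) for c in self.remaining))


@dataclass(frozen=True)
class ConditionDataset:
    """All replicates measured for one coating condition (one Q value)."""

    q: float
    schedule: PressureSchedule
    replicates: tuple[ReplicateCounts, ...]

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise InvalidDataError("a condition needs at least one replicate")
        n = self.schedule.n_rounds
        for rep in self.replicates:
            if len(rep.remaining) != n:
                raise InvalidDataError(
                    "replicate round count does not match the pressure schedule"
                )
        object.__setattr__(self, "replicates", tuple(self.replicates))


@dataclass(frozen=True)
class DetachmentCurve:
    """Remaining cell fraction after each round.

    ``fractions[n-1]`` is the fraction still attached after round n; the
    implied round-0 point is 1.  ``stderr`` is present only for averaged
    curves built from at least two replicates.
    """

    fractions: np.ndarray
    mode: str  # "averaged" | "pooled"
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size < 1 or np.any(f < 0) or np.any(f > 1):
            raise InvalidDataError("fractions must lie in [0, 1]")
        if np.any(np.diff(np.concatenate([[1.0], f])) > 1e-12):
            raise InvalidDataError("detachment curve must be non-increasing")
        object.__setattr__(self, "fractions", f)
        if self.stderr is not None:
            object.__setattr__(self, "stderr", np.asarray(self.stderr, dtype=float))


@dataclass(frozen=True)
class DetachmentHistogram:
    """Fraction of the population detached in each pressure bin.

    ``masses[n-1]`` is the fraction detached in round n; ``terminal_mass``
    is the fraction never detached.  Masses plus terminal mass sum to 1.
    """

    bin_edges: np.ndarray
    masses: np.ndarray
    terminal_mass: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        total = float(self.masses.sum() + self.terminal_mass)
        if np.any(self.masses < -1e-12) or self.terminal_mass < -1e-12:
            raise InvalidDataError("histogram masses must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise InvalidDataError(f"histogram masses must sum to 1, got {total}")

    def all_masses(self) -> np.ndarray:
        """Round-bin masses with the terminal bin appended."""
        return np.concatenate([self.masses, [self.terminal_mass]])

    def midpoints(self) -> np.ndarray:
        edges = self.bin_edges
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class SubpopulationSummary:
    """Adhesion-phenotype decomposition: weak / moderate / strong fractions."""

    weak: float
    moderate: float
    strong: float

    def __post_init__(self) -> None:
        if abs(self.weak + self.moderate + self.strong - 1.0) > 1e-9:
            raise InvalidDataError("subpopulation fractions must partition unity")


@dataclass(frozen=True)
class AdhesionHeatMap:
    """Bin masses per condition, rows ordered by ascending ligand density."""

    rho_numbers: np.ndarray  # 1/um^2, ascending
    bin_edges: np.ndarray
    values: np.ndarray  # shape (n_conditions, n_bins); each row sums to 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(np.abs(v.sum(axis=1) - 1.0) > 1e-9):
            raise InvalidDataError("each heat-map row must sum to 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "rho_numbers", np.asarray(self.rho_numbers, dtype=float))
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))


#: Columns of a per-cell table.
CELL_TABLE_COLUMNS = ("cell_id", "x_um", "y_um", "round_detached")


def proximity_filter(cells: pd.DataFrame, min_separation: float = 70.0) -> pd.DataFrame:
    """Drop every cell that has a neighbour closer than ``min_separation`` um.

    The micropipette probes one cell at a time; two cells closer than the
    pipette diameter would be probed together, so both members of any close
    pair are excluded.  Exclusion is mutual and transitive chains are NOT
    followed: a cell is removed iff some other cell lies at Euclidean
    distance strictly below the threshold.  Ties at exactly
    ``min_separation`` are kept.  Input row order is preserved.
    """
    if not min_separation > 0:
        raise InvalidParameterError("min_separation must be positive")
    if len(cells) == 0:
        return cells.copy()
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise InvalidDataError("cell coordinates must be finite")
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=min_separation, output_type="ndarray")
    if pairs.size:
        # query_pairs uses distance <= r; enforce the strict inequality.
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        pairs = pairs[d < min_separation]
    keep = np.ones(len(cells), dtype=bool)
    keep[np.unique(pairs)] = False
    return cells.iloc[keep].copy()


def remaining_fraction_averaged(dataset: ConditionDataset) -> DetachmentCurve:
    """Average the per-replicate remaining fractions at each round.

    R_a(n) = mean over replicates of x_n / x_0.  The standard error is the
    sample (n-1) standard deviation across replicates divided by the square
    root of the replicate count; omitted for a single replicate.
    """
    ratios = _replicate_ratios(dataset)
    k = ratios.shape[0]
    fractions = ratios.mean(axis=0)
    stderr = ratios.std(axis=0, ddof=1) / np.sqrt(k) if k >= 2 else None
    return DetachmentCurve(fractions=fractions, mode="averaged", stderr=stderr)


def remaining_fraction_pooled(dataset: ConditionDataset) -> DetachmentCurve:
    """Pool replicates into one population: R_p(n) = sum x_n / sum x_0."""
    _replicate_ratios(dataset)  # validates initial counts
    totals0 = sum(r.initial for r in dataset.replicates)
    remaining = np.sum([r.remaining for r in dataset.replicates], axis=0)
    return DetachmentCurve(fractions=remaining / totals0, mode="pooled")


def _replicate_ratios(dataset: ConditionDataset) -> np.ndarray:
    if any(r.initial == 0 for r in dataset.replicates):
        raise InvalidDataError("every replicate must start with at least one cell")
    return np.array(
        [np.asarray(r.remaining, dtype=float) / r.initial for r in dataset.replicates]
    )


def build_histogram(curve: DetachmentCurve, schedule: PressureSchedule) -> DetachmentHistogram:
    """Difference the detachment curve into per-bin detachment masses.

    The fraction detached in round n is fraction_{n-1} - fraction_n (with
    the implied fraction_0 = 1); the never-detached fraction is the last
    curve value.
    """
    f = curve.fractions
    if f.size != schedule.n_rounds:
        raise InvalidDataError("curve length does not match the pressure schedule")
    padded = np.concatenate([[1.0], f])
    masses = -np.diff(padded)
    if np.any(masses < -1e-12):
        raise InvalidDataError("detachment curve increases between rounds")
    masses = np.clip(masses, 0.0, None)
    return DetachmentHistogram(
        bin_edges=schedule.bin_edges(), masses=masses, terminal_mass=float(f[-1])
    )


def weighted_average(hist: DetachmentHistogram) -> float:
    """Weighted average detachment pressure W, atm.

    W = sum over bins of (bin mass) x (bin midpoint), the terminal
    (never-detached) bin included at its extrapolated midpoint.  Equals the
    population mean of per-cell bin midpoints.
    """
    return float(np.dot(hist.all_masses(), hist.midpoints()))


def subpopulations(hist: DetachmentHistogram) -> SubpopulationSummary:
    """Partition the population into weak / moderate / strong adherers.

    Weak cells detach in round 1, strong cells survive every round, and the
    moderate fraction is the remainder.
    """
    weak = float(hist.masses[0])
    strong = float(hist.terminal_mass)
    return SubpopulationSummary(weak=weak, moderate=1.0 - weak - strong, strong=strong)


def heatmap(
    histograms: Sequence[tuple[float, DetachmentHistogram]],
) -> AdhesionHeatMap:
    """Stack per-condition histograms into a density-ordered heat map."""
    if len(histograms) < 1:
        raise InvalidDataError("heat map needs at least one condition")
    edges0 = histograms[0][1].bin_edges
    for _, h in histograms[1:]:
        if h.bin_edges.shape != edges0.shape or not np.allclose(h.bin_edges, edges0):
            raise InvalidDataError("all conditions must share the pressure schedule")
    order = np.argsort([rho for rho, _ in histograms], kind="stable")
    rhos = np.array([histograms[i][0] for i in order], dtype=float)
    values = np.vstack([histograms[i][1].all_masses() for i in order])
    return AdhesionHeatMap(rho_numbers=rhos, bin_edges=edges0, values=values)
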