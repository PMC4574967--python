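"""Windowed transcript-density traces and spatiotemporal registration.

Because meiotic induction sweeps the fetal ovary from anterior to posterior,
position along the AP axis is a proxy for developmental time.  A *trace* is
the windowed mean (+/- SD) transcript density of one gene along the axis of
one genotype/age group: 100 evenly spaced sliding windows, each 0.2 of the
ovary length wide.  Traces from consecutive embryonic days are *registered*
onto a single spatiotemporal coordinate by shifting each day's trace along
the axis to maximize overlap of the reference gene (Stra8), and the same
shifts are then applied to every other gene.  Induction timing is read off a
joined trace as the coordinate of half-maximal expression on the rising phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import density

__all__ = [
    "Trace",
    "SpatiotemporalAxis",
    "JoinedTrace",
    "HalfMax",
    "windowed_trace",
    "register_traces",
    "build_joined_trace",
    "half_max_time",
]


@dataclass
class Trace:
    """Windowed mean/SD transcript density along the AP axis."""

    gene: str
    genotype: str
    age: float
    window_centers: np.ndarray  # positions in [0, 1], evenly spaced
    mean_density: np.ndarray  # NaN where the window is empty
    sd_density: np.ndarray
    n_cells: np.ndarray
    window_frac: float = 0.2  # window width as a fraction of the axis

    def __post_init__(self) -> None:
        lens = {len(self.window_centers), len(self.mean_density),
                len(self.sd_density), len(self.n_cells)}
        if len(lens) != 1:
            raise ValueError("trace arrays must have equal length")

    @property
    def empty_windows(self) -> np.ndarray:
        return self.n_cells < 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene, "genotype": self.genotype, "age": self.age,
            "window_center": self.window_centers, "mean_density": self.mean_density,
            "sd_density": self.sd_density, "n_cells": self.n_cells,
        })


@dataclass
class SpatiotemporalAxis:
    """Per-age offsets placing each day's trace on one pseudotime coordinate.

    ``shifts[i]`` is the axis coordinate of age ``ages[i]``'s posterior pole
    (trace origin); the first age is anchored at 0 and shifts are
    non-decreasing.  ``ambiguous`` flags age pairs where the reference trace
    was too flat to register (the pair is then abutted with zero overlap).
    """

    ages: tuple[float, ...]
    shifts: np.ndarray
    reference_gene: str = "Stra8"
    ambiguous: tuple[bool, ...] = ()
    objectives: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if list(self.ages) != sorted(self.ages):
            raise ValueError("ages must be ordered")
        if np.any(np.diff(self.shifts) < 0):
            raise ValueError("shifts must be non-decreasing with age")
        if abs(self.shifts[0]) > 1e-12:
            raise ValueError("first age must be anchored at offset 0")

    def shift_of(self, age: float) -> float:
        for a, s in zip(self.ages, self.shifts):
            if a == age:
                return float(s)
        raise KeyError(f"age {age} not on axis")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.ages)
        return pd.DataFrame({
            "age": self.ages,
            "shift": np.asarray(self.shifts, dtype=float),
            "ambiguous": list(self.ambiguous) if self.ambiguous else [False] * n,
            "objective": list(self.objectives) if self.objectives else [np.nan] * n,
            "reference_gene": self.reference_gene,
        })


@dataclass
class JoinedTrace:
    """One gene's trace on the joined spatiotemporal coordinate."""

    gene: str
    genotype: str
    coordinates: np.ndarray  # strictly increasing
    mean_density: np.ndarray
    sd_density: np.ndarray
    n_cells: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if len(self.coordinates) and np.any(np.diff(self.coordinates) <= 0):
            raise ValueError("joined coordinates must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene, "genotype": self.genotype,
            "coordinate": self.coordinates, "mean_density": self.mean_density,
            "sd_density": self.sd_density,
            "n_cells": self.n_cells if self.n_cells is not None else np.nan,
        })


def windowed_trace(
    cells: pd.DataFrame,
    gene: str,
    n_windows: int = 100,
    window_frac: float = 0.2,
) -> Trace:
    """Sliding-window mean/SD of transcript density along the AP axis.

    Window centers are evenly spaced on [0, 1]; each window is the closed
    interval ``center +/- window_frac/2``, slid inward at the poles so every
    window keeps its full width inside [0, 1] (a window is a fixed fraction
    of the ovary's length; the degenerate ``window_frac = 1`` therefore makes
    every window the whole axis).  Windows overlap, which is what smooths the
    trace.
    """
    if len(cells) == 0:
        raise ValueError("empty cell selection")
    if not (0 < window_frac <= 1):
        raise ValueError("window_frac must lie in (0, 1]")
    for col in ("genotype", "age"):
        if cells[col].nunique() > 1:
            raise ValueError(f"cells must share a single {col}")

    pos = cells["ap_position"].to_numpy(dtype=float)
    dens = density(cells, gene).to_numpy(dtype=float)
    centers = np.linspace(0.0, 1.0, n_windows)
    half = window_frac / 2.0

    means = np.full(n_windows, np.nan)
    sds = np.full(n_windows, np.nan)
    ns = np.zeros(n_windows, dtype=int)
    for i, c in enumerate(centers):
        lo = min(max(0.0, c - half), 1.0 - 2 * half)
        hi = lo + 2 * half
        sel = (pos >= lo) & (pos <= hi)
        n = int(sel.sum())
        ns[i] = n
        if n >= 1:
            means[i] = dens[sel].mean()
            sds[i] = dens[sel].std(ddof=0)
    return Trace(
        gene=gene,
        genotype=str(cells["genotype"].iloc[0]),
        age=float(cells["age"].iloc[0]),
        window_centers=centers,
        mean_density=means,
        sd_density=sds,
        n_cells=ns,
        window_frac=window_frac,
    )


def _pair_shift(
    earlier: Trace,
    later: Trace,
    grid_step: float,
    min_overlap: float,
    flat_tol: float,
) -> tuple[float, float, bool]:
    """Displacement of ``later`` relative to ``earlier`` on the common axis.

    Scans displacements ``d`` on a grid; at displacement ``d`` the later
    trace's window at position u sits at axis coordinate ``u + d``, so its
    values are compared against the earlier trace interpolated at ``u + d``.
    Mean squared difference over the overlap is minimized; ties break toward
    the smaller shift.  Only full-width interior windows enter the objective
    (edge windows are truncated at the poles and are not translation
    equivariant).  Returns ``(d, objective, ambiguous)``; a pair whose
    reference traces have near-zero dynamic range (10th-90th percentile
    spread relative to the pair's peak, robust to baseline noise) is flagged
    ambiguous and abutted end-to-end (d = 1, no overlap).
    """
    e_ok = ~np.isnan(earlier.mean_density)
    l_ok = ~np.isnan(later.mean_density)
    if not e_ok.any() or not l_ok.any():
        raise ValueError("reference trace is empty")
    peak = float(np.nanmax([np.nanmax(earlier.mean_density),
                            np.nanmax(later.mean_density)]))
    rng_e = np.diff(np.nanquantile(earlier.mean_density, [0.1, 0.9]))[0]
    rng_l = np.diff(np.nanquantile(later.mean_density, [0.1, 0.9]))[0]
    if peak <= 0 or min(rng_e, rng_l) < flat_tol * peak:
        return 1.0, np.nan, True

    half_e = earlier.window_frac / 2.0
    half_l = later.window_frac / 2.0
    e_in = e_ok & (earlier.window_centers >= half_e) \
        & (earlier.window_centers <= 1.0 - half_e)
    l_in = l_ok & (later.window_centers >= half_l) \
        & (later.window_centers <= 1.0 - half_l)
    if not e_in.any() or not l_in.any():  # degenerate window_frac = 1
        e_in, l_in = e_ok, l_ok
    ex = earlier.window_centers[e_in]
    ey = earlier.mean_density[e_in]
    lx = later.window_centers[l_in]
    ly = later.mean_density[l_in]

    best_d, best_obj = None, np.inf
    n_steps = int(round((1.0 - min_overlap) / grid_step))
    for k in range(n_steps + 1):
        d = k * grid_step
        tgt = lx + d
        inside = (tgt >= ex[0]) & (tgt <= ex[-1])
        if inside.sum() < min_overlap * len(later.window_centers):
            continue
        pred = np.interp(tgt[inside], ex, ey)
        obj = float(np.mean((pred - ly[inside]) ** 2))
        if obj < best_obj - 1e-15:
            best_d, best_obj = d, obj
    if best_d is None:
        raise ValueError("no admissible overlap between consecutive traces")
    return best_d, best_obj, False


def register_traces(
    traces_by_age: dict[float, Trace],
    grid_step: float = 0.01,
    min_overlap: float = 0.25,
    flat_tol: float = 0.2,
) -> SpatiotemporalAxis:
    """Register reference-gene traces from consecutive ages onto one axis.

    Shifts accumulate: each age's offset is the previous age's offset plus the
    pairwise displacement.  Two identical traces register at displacement 0.
    """
    ages = sorted(traces_by_age)
    if len(ages) < 2:
        raise ValueError("need at least two ages to register")
    genes = {traces_by_age[a].gene for a in ages}
    if len(genes) != 1:
        raise ValueError("all reference traces must be of the same gene")

    shifts = [0.0]
    flags = [False]
    objs = [np.nan]
    for prev, nxt in zip(ages, ages[1:]):
        d, obj, amb = _pair_shift(traces_by_age[prev], traces_by_age[nxt],
                                  grid_step, min_overlap, flat_tol)
        shifts.append(shifts[-1] + d)
        flags.append(amb)
        objs.append(obj)
    return SpatiotemporalAxis(
        ages=tuple(ages),
        shifts=np.asarray(shifts, dtype=float),
        reference_gene=genes.pop(),
        ambiguous=tuple(flags),
        objectives=tuple(objs),
    )


def build_joined_trace(
    traces_by_age: dict[float, Trace],
    axis: SpatiotemporalAxis,
    bin_width: float = 0.01,
) -> JoinedTrace:
    """Place each age's trace at its registered shift and merge overlaps.

    Where ages overlap, window values landing in the same coordinate bin are
    averaged weighted by the number of cells behind each window.  A single age
    reproduces the input trace.
    """
    ages = sorted(traces_by_age)
    if set(ages) - set(axis.ages):
        raise KeyError("trace age missing from axis")
    genes = {traces_by_age[a].gene for a in ages}
    genotypes = {traces_by_age[a].genotype for a in ages}
    if len(genes) != 1 or len(genotypes) != 1:
        raise ValueError("traces must share one gene and genotype")

    coords, means, sds, ns = [], [], [], []
    for age in ages:
        t = traces_by_age[age]
        ok = t.n_cells >= 1
        coords.append(t.window_centers[ok] + axis.shift_of(age))
        means.append(t.mean_density[ok])
        sds.append(t.sd_density[ok])
        ns.append(t.n_cells[ok])
    coords = np.concatenate(coords)
    means = np.concatenate(means)
    sds = np.concatenate(sds)
    ns = np.concatenate(ns).astype(float)
    if len(coords) == 0:
        raise ValueError("all traces are empty")

    bins = np.round(coords / bin_width).astype(int)
    order = np.argsort(bins, kind="stable")
    bins, coords, means, sds, ns = (a[order] for a in (bins, coords, means, sds, ns))
    uniq, start = np.unique(bins, return_index=True)
    out_c, out_m, out_s, out_n = [], [], [], []
    edges = list(start) + [len(bins)]
    for i in range(len(uniq)):
        sl = slice(edges[i], edges[i + 1])
        w = ns[sl]
        wsum = w.sum()
        if wsum <= 0:
            w = np.ones_like(w)
            wsum = w.sum()
        out_c.append(np.average(coords[sl], weights=w))
        out_m.append(np.average(means[sl], weights=w))
        out_s.append(np.average(sds[sl], weights=w))
        out_n.append(wsum)
    return JoinedTrace(
        gene=genes.pop(),
        genotype=genotypes.pop(),
        coordinates=np.asarray(out_c),
        mean_density=np.asarray(out_m),
        sd_density=np.asarray(out_s),
        n_cells=np.asarray(out_n),
    )


@dataclass(frozen=True)
class HalfMax:
    """Coordinate of half-maximal expression; undefined for flat traces."""

    coordinate: float
    defined: bool


def half_max_time(trace: JoinedTrace, baseline_tol: float = 1e-9) -> HalfMax:
    """First coordinate where the trace reaches 50% of its own maximum.

    Computed on the rising phase only: the earliest crossing from below, with
    linear interpolation between windows.  A trace whose maximum does not
    exceed ``baseline_tol`` is flagged undefined.
    """
    y = np.asarray(trace.mean_density, dtype=float)
    x = np.asarray(trace.coordinates, dtype=float)
    ok = ~np.isnan(y)
    if not ok.any():
        raise ValueError("all-empty trace")
    x, y = x[ok], y[ok]
    peak = float(y.max())
    if peak <= baseline_tol:
        return HalfMax(np.nan, False)
    target = 0.5 * peak
    if y[0] >= target:
        return HalfMax(float(x[0]), True)
    above = np.nonzero(y >= target)[0]
    i = int(above[0])
    x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
    frac = (target - y0) / (y1 - y0)
    return HalfMax(float(x0 + frac * (x1 - x0)), True)
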