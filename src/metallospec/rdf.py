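"""Radial distribution functions on periodic cubic-box trajectories.

Distances use the minimum-image convention; g(r) is the pair-distance
histogram normalized by the ideal-gas expectation per spherical shell, and
the running coordination number is the cumulative neighbour count per
central atom, N(r) = 4 pi rho_B \\int_0^r g(s) s^2 ds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import UsageError

__all__ = ["TrajectoryFrameSet", "RdfResult", "rdf", "read_xyz", "write_xyz"]


@dataclass
class TrajectoryFrameSet:
    """Frames of element-labelled coordinates in a cubic periodic box (Å)."""

    box_edge: float
    elements: list[str]
    frames: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise UsageError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.elements):
            raise UsageError("element labels do not match the atom count")
        if not self.box_edge > 0:
            raise UsageError("box edge must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def select(self, selection: str | Sequence[int]) -> np.ndarray:
        """Atom indices for an element symbol or an explicit index list."""
        if isinstance(selection, str):
            idx = np.array(
                [i for i, e in enumerate(self.elements) if e == selection], dtype=int
            )
        else:
            idx = np.asarray(selection, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
                raise UsageError("selection index out of range")
        if idx.size == 0:
            raise UsageError(f"selection {selection!r} matches no atoms")
        return idx


@dataclass
class RdfResult:
    """g(r) on bin centres plus the running coordination number."""

    r: np.ndarray
    g: np.ndarray
    coordination: np.ndarray
    bin_width: float
    n_a: int
    n_b: int
    box_edge: float

    def first_shell(self, smooth: int = 5) -> tuple[float, float]:
        """(r at the first minimum after the first maximum, N there).

        The search runs on a ``smooth``-point moving average of g(r).
        """
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        gs = np.convolve(np.pad(self.g, pad, mode="edge"), kernel, mode="valid")
        i = 1
        n = len(gs)
        # first local maximum
        while i < n - 1 and not (gs[i] > gs[i - 1] and gs[i] >= gs[i + 1]):
            i += 1
        # first local minimum after it
        j = i + 1
        while j < n - 1 and not (gs[j] < gs[j - 1] and gs[j] <= gs[j + 1]):
            j += 1
        if j >= n - 1:
            raise UsageError("no first-shell minimum found within r_max")
        return float(self.r[j]), float(self.coordination[j])


def rdf(
    traj: TrajectoryFrameSet,
    selection_a: str | Sequence[int],
    selection_b: str | Sequence[int],
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> RdfResult:
    """Radial distribution function between two selections.

    ``r_max`` defaults to half the box edge and may not exceed it (beyond
    that the minimum-image shell volume is no longer spherical).
    """
    box = traj.box_edge
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-12:
        raise UsageError("r_max must not exceed half the box edge")
    if bin_width <= 0:
        raise UsageError("bin width must be positive")
    ia = traj.select(selection_a)
    ib = traj.select(selection_b)
    edges = np.arange(0.0, r_max + bin_width * 0.999, bin_width)
    if edges[-1] < r_max - 1e-12:
        edges = np.append(edges, r_max)
    hist = np.zeros(edges.size - 1)
    overlap = np.intersect1d(ia, ib).size
    self_mask = ia[:, None] == ib[None, :]
    for frame in traj.frames:
        d = frame[ia][:, None, :] - frame[ib][None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt(np.sum(d * d, axis=-1))
        r = r[~self_mask]
        hist += np.histogram(r, bins=edges)[0]
    n_pairs = ia.size * ib.size - overlap
    if n_pairs <= 0:
        raise UsageError("selections leave no distinct atom pairs")
    volume = box**3
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = traj.n_frames * n_pairs * shell / volume
    g = hist / ideal
    coordination = np.cumsum(hist) / (traj.n_frames * ia.size)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RdfResult(
        r=centers,
        g=g,
        coordination=coordination,
        bin_width=bin_width,
        n_a=int(ia.size),
        n_b=int(ib.size),
        box_edge=box,
    )


# ---------------------------------------------------------------------------
# XYZ interchange (frame-per-block; comment line carries "box=<edge>")


def read_xyz(path: str | Path) -> TrajectoryFrameSet:
    """Read a multi-frame XYZ file whose comment lines carry ``box=<Å>``."""
    frames = []
    elements: list[str] | None = None
    box = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise UsageError(f"bad XYZ atom-count line {i + 1}: {lines[i]!r}") from exc
        comment = lines[i + 1]
        for tok in comment.replace(",", " ").split():
            if tok.startswith("box="):
                box = float(tok[4:])
        elems, coords = [], []
        for k in range(nat):
            parts = lines[i + 2 + k].split()
            elems.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if elements is None:
            elements = elems
        elif elems != elements:
            raise UsageError("inconsistent element labels across frames")
        frames.append(coords)
        i += 2 + nat
    if not frames:
        raise UsageError(f"no frames found in {path}")
    if box is None:
        raise UsageError("no 'box=' entry found on any XYZ comment line")
    return TrajectoryFrameSet(
        box_edge=box, elements=elements, frames=np.array(frames, dtype=float)
    )


def write_xyz(traj: TrajectoryFrameSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"box={float(traj.box_edge)!r}\n")
            for el, (x, y, z) in zip(traj.elements, frame):
                fh.write(f"{el} {float(x)!r} {float(y)!r} {float(z)!r}\n")
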