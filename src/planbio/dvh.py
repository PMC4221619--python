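"""Dose-volume histogram (DVH) data model and queries.

A DVH summarises the dose distribution within a contoured structure as a
histogram over dose bins.  The canonical in-memory representation here is the
*differential* DVH: strictly increasing bin edges (Gy) plus the fraction of
the structure volume falling in each bin, summing to one.  The *cumulative*
form — fraction of volume receiving at least a given dose — is derived on
demand and is also accepted on input (plan-system exports are usually
cumulative).

All radiobiological computation downstream uses bin midpoints as the bin
dose; queries (``dose_at_volume_fraction``, ``volume_fraction_at_dose``)
interpolate linearly on the cumulative curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DVH",
    "DoseGrid",
    "to_cumulative",
    "to_differential",
    "dose_at_volume_fraction",
    "volume_fraction_at_dose",
    "dvh_from_grid",
    "uniform_dvh",
]

#: cumulative values may dip below monotone by this much before we error
_MONOTONE_TOL = 1e-8
#: a cumulative curve whose top deviates from 1 by more than this errors out
_NORMALISE_TOL = 1e-3


class DVHValidationError(ValueError):
    """Raised when DVH data violate the representation invariants."""


@dataclass
class DVH:
    """Per-structure dose-volume histogram.

    Parameters
    ----------
    structure_name : str
        Label of the contoured structure (e.g. ``"PTV70"``, ``"parotid"``).
    bin_edges : ndarray, shape (B+1,)
        Finite, nonnegative, strictly increasing dose values in Gy.
    volume : ndarray
        For ``kind="differential"``: length B, nonnegative volume fractions
        summing to 1.  For ``kind="cumulative"``: length B+1, nonincreasing
        fractions at the bin edges, starting at 1 (fraction receiving at
        least that dose).
    abs_volume_cc : float, optional
        Absolute structure volume in cm^3; needed only for conformity and
        "1 cc" dose-volume rules.
    kind : {"differential", "cumulative"}
        Stored representation.  Analysis always goes through
        :meth:`as_differential`.
    """

    structure_name: str
    bin_edges: np.ndarray
    volume: np.ndarray
    abs_volume_cc: Optional[float] = None
    kind: str = "differential"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        e = self.bin_edges
        if e.ndim != 1 or e.size < 2:
            raise DVHValidationError("bin_edges must be 1-D with at least two entries")
        if not np.all(np.isfinite(e)):
            raise DVHValidationError("bin edges must be finite")
        if e[0] < 0:
            raise DVHValidationError("bin edges must be nonnegative")
        if not np.all(np.diff(e) > 0):
            raise DVHValidationError("bin edges must be strictly increasing")
        if self.abs_volume_cc is not None and not self.abs_volume_cc > 0:
            raise DVHValidationError("abs_volume_cc must be positive")
        if self.kind == "differential":
            if self.volume.shape != (e.size - 1,):
                raise DVHValidationError("differential volume must have one entry per bin")
            if np.any(self.volume < 0):
                raise DVHValidationError("differential volumes must be nonnegative")
            if abs(self.volume.sum() - 1.0) > 1e-9:
                raise DVHValidationError(
                    f"differential volumes must sum to 1 (got {self.volume.sum()!r})"
                )
        elif self.kind == "cumulative":
            if self.volume.shape != (e.size,):
                raise DVHValidationError("cumulative volume must have one entry per edge")
            if np.any(self.volume < -_MONOTONE_TOL) or np.any(self.volume > 1 + _MONOTONE_TOL):
                raise DVHValidationError("cumulative values must lie in [0, 1]")
            if np.any(np.diff(self.volume) > _MONOTONE_TOL):
                raise DVHValidationError("cumulative curve must be nonincreasing")
        else:
            raise DVHValidationError(f"unknown DVH kind {self.kind!r}")

    # -- representation conversions -------------------------------------

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def midpoints(self) -> np.ndarray:
        """Bin midpoint doses (Gy) of the differential representation."""
        d = self.as_differential()
        return 0.5 * (d.bin_edges[:-1] + d.bin_edges[1:])

    def as_differential(self) -> "DVH":
        """Return the canonical differential form (self if already so)."""
        if self.kind == "differential":
            return self
        c = np.clip(self.volume, 0.0, None)
        v = c[:-1] - c[1:]
        # dips within tolerance clip to zero, larger ones were caught above
        v = np.where(v < 0, 0.0, v)
        total = v.sum()
        if abs(total - 1.0) > _NORMALISE_TOL:
            raise DVHValidationError(
                f"cumulative DVH mass {total!r} too far from 1 to renormalise"
            )
        if total <= 0:
            raise DVHValidationError("cumulative DVH carries no volume")
        v = v / total
        return DVH(self.structure_name, self.bin_edges.copy(), v,
                   self.abs_volume_cc, "differential")

    def as_cumulative(self) -> "DVH":
        """Return the cumulative (at-least) form evaluated at the bin edges."""
        if self.kind == "cumulative":
            return self
        v = self.volume
        c = np.concatenate([np.cumsum(v[::-1])[::-1], [0.0]])
        c[0] = 1.0  # exact by normalisation
        return DVH(self.structure_name, self.bin_edges.copy(), c,
                   self.abs_volume_cc, "cumulative")

    def _cumulative_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges and cumulative values, with an implicit (0 Gy, 1) anchor."""
        c = self.as_cumulative()
        e, y = c.bin_edges, np.clip(c.volume, 0.0, 1.0)
        if e[0] > 0:
            e = np.concatenate([[0.0], e])
            y = np.concatenate([[1.0], y])
        return e, y

    # -- queries ---------------------------------------------------------

    def dose_at_volume_fraction(self, q: float) -> float:
        """Smallest dose D with interpolated cumulative fraction q (D_x%).

        ``q=0.02`` gives D2%, the minimum dose received by the hottest 2% of
        the volume.  ``q=0`` returns the top of the occupied dose range (the
        maximum dose); ``q=1`` returns the minimum dose (the highest dose
        still received by the whole volume).  On flat cumulative segments
        ties resolve toward the lower dose, except at ``q=1``.
        """
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"volume fraction q={q!r} outside [0, 1]")
        e, c = self._cumulative_curve()
        if q >= 1.0:
            return float(e[np.nonzero(c >= 1.0 - 1e-12)[0][-1]])
        if q <= 0.0:
            return float(e[np.nonzero(c <= 1e-12)[0][0]])
        j = int(np.nonzero(c <= q)[0][0])  # first edge at or below q; exists (c[-1]=0)
        if c[j] == q:
            return float(e[j])
        # interpolate on the strictly decreasing span (e[j-1], e[j])
        c0, c1 = c[j - 1], c[j]
        return float(e[j - 1] + (c0 - q) / (c0 - c1) * (e[j] - e[j - 1]))

    def volume_fraction_at_dose(self, d: float) -> float:
        """Interpolated fraction of volume receiving at least ``d`` Gy."""
        if d < 0:
            raise ValueError("dose must be nonnegative")
        e, c = self._cumulative_curve()
        if d <= e[0]:
            return 1.0
        if d >= e[-1]:
            return 0.0
        return float(np.interp(d, e, c))

    def mean_dose(self) -> float:
        d = self.as_differential()
        return float(d.volume @ d.midpoints)

    def std_dose(self) -> float:
        d = self.as_differential()
        m = d.midpoints
        mu = float(d.volume @ m)
        var = float(d.volume @ (m - mu) ** 2)
        return float(np.sqrt(max(var, 0.0)))

    def max_dose(self) -> float:
        return self.dose_at_volume_fraction(0.0)

    def min_dose(self) -> float:
        return self.dose_at_volume_fraction(1.0)

    def dose_to_cc(self, cc: float) -> float:
        """Minimum dose to the hottest ``cc`` cm^3 (requires abs_volume_cc)."""
        if self.abs_volume_cc is None:
            raise DVHValidationError(
                f"{self.structure_name}: absolute volume required for cc-based query"
            )
        q = min(cc / self.abs_volume_cc, 1.0)
        return self.dose_at_volume_fraction(q)

    # -- plotting ---------------------------------------------------------

    def plot(self, ax=None, **kwargs):
        """Plot the cumulative DVH (volume % vs dose)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        e, c = self._cumulative_curve()
        kwargs.setdefault("label", self.structure_name)
        ax.plot(e, 100.0 * c, **kwargs)
        ax.set_xlabel("Dose (Gy)")
        ax.set_ylabel("Volume (%)")
        ax.set_ylim(0, 105)
        return ax


@dataclass
class DoseGrid:
    """Toy 3-D dose array with a binary structure mask.

    Exists to regenerate DVH fixtures and as the brute-force (per-voxel)
    oracle path; it is not a clinical dose-calculation container.
    """

    dose: np.ndarray
    mask: np.ndarray
    voxel_volume_cc: float = 0.001

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.dose.shape != self.mask.shape:
            raise ValueError("dose and mask shapes differ")
        if np.any(self.dose < 0):
            raise ValueError("dose values must be nonnegative")
        if not self.voxel_volume_cc > 0:
            raise ValueError("voxel volume must be positive")

    @property
    def masked_doses(self) -> np.ndarray:
        return self.dose[self.mask]


def dvh_from_grid(grid: DoseGrid, bin_width: float = 0.1,
                  structure_name: str = "structure") -> DVH:
    """Histogram the masked voxel doses of a :class:`DoseGrid` into a DVH."""
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    doses = grid.masked_doses
    if doses.size == 0:
        raise ValueError("empty structure mask")
    top = float(doses.max())
    n_bins = max(int(np.ceil(top / bin_width)) + 1, 1)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    counts, _ = np.histogram(doses, bins=edges)
    rel = counts / counts.sum()
    return DVH(structure_name, edges, rel,
               abs_volume_cc=doses.size * grid.voxel_volume_cc)


def uniform_dvh(dose: float, width: float = 0.1,
                structure_name: str = "structure",
                abs_volume_cc: Optional[float] = None) -> DVH:
    """Single-bin DVH with all volume in ``[dose - width/2, dose + width/2]``."""
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    lo = max(dose - width / 2.0, 0.0)
    hi = lo + width
    return DVH(structure_name, np.array([lo, hi]), np.array([1.0]),
               abs_volume_cc=abs_volume_cc)


# Functional aliases matching the operation-level API.

def to_cumulative(dvh: DVH) -> DVH:
    """Cumulative (fraction receiving >= dose) form of a differential DVH."""
    return dvh.as_cumulative()


def to_differential(dvh: DVH) -> DVH:
    """Canonical differential form of a cumulative DVH."""
    return dvh.as_differential()


def dose_at_volume_fraction(dvh: DVH, q: float) -> float:
    return dvh.dose_at_volume_fraction(q)


def volume_fraction_at_dose(dvh: DVH, d: float) -> float:
    return dvh.volume_fraction_at_dose(d)
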