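"""BRET biosensor readout from phasor coordinates.

A BRET sensor's emission is a photon mixture of its luciferase donor and
fluorescent-protein acceptor, so by linearity of the phasor transform the
sensor's phasor slides along the straight trajectory from the donor
reference to the acceptor reference as transfer efficiency changes. The
**BRET efficiency** reported here is the normalized position along that
chord (0 at the donor, 1 at the acceptor, clamped), obtained by orthogonal
projection — i.e. the acceptor photon fraction of the mixture.

Phase/modulation are the polar coordinates of a phasor point: phase
(``atan2(s, g)``) encodes mean emission color, modulation (``sqrt(g^2+s^2)``)
spectral narrowness; they are used to discriminate cell populations whose
spectra overlap too much for band ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .pipeline import PhasorImage
from .unmix import unmix_two

__all__ = [
    "BretAxis",
    "bret_efficiency",
    "phase_modulation",
    "per_cell_stats",
    "series_assemble",
    "CELL_COLUMNS",
]

#: Columns of the per-cell table, in order.
CELL_COLUMNS = [
    "cell_id", "area", "centroid_row", "centroid_col",
    "g", "s", "efficiency", "phase", "modulation",
    "total_intensity", "time", "depth",
]


@dataclass(frozen=True)
class BretAxis:
    """Donor -> acceptor phasor trajectory of a BRET sensor."""

    donor: tuple[float, float]
    acceptor: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (g, s) in (("donor", self.donor), ("acceptor", self.acceptor)):
            if g**2 + s**2 > 1.0 + 1e-9:
                raise ParameterError(f"{name} phasor ({g}, {s}) outside the unit disk")
        d = np.subtract(self.acceptor, self.donor)
        if np.linalg.norm(d) <= 1e-6:
            raise ParameterError("degenerate BRET axis: donor and acceptor coincide")

    @classmethod
    def from_spectra(cls, donor_spectrum, acceptor_spectrum, window=None) -> "BretAxis":
        """Axis endpoints from area-normalized donor/acceptor emission spectra."""
        from .spectra import DEFAULT_WINDOW, spectral_phasor

        w = window or DEFAULT_WINDOW
        return cls(
            donor=spectral_phasor(donor_spectrum, w),
            acceptor=spectral_phasor(acceptor_spectrum, w),
        )


def bret_efficiency(g, s, axis: BretAxis):
    """BRET efficiency of phasor point(s): clamped normalized projection
    onto the donor->acceptor chord (0 = donor, 1 = acceptor).

    Accepts scalars or arrays; NaN inputs propagate.
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    scalar = g.ndim == 0
    pts = np.column_stack([np.atleast_1d(g).ravel(), np.atleast_1d(s).ravel()])
    finite = np.isfinite(pts).all(axis=1)
    eff = np.full(pts.shape[0], np.nan)
    if finite.any():
        # f1 measures position toward ref1; use acceptor as ref1 so 1 = acceptor
        res = unmix_two(pts[finite], ref1=axis.acceptor, ref2=axis.donor)
        eff[finite] = res.f1
    if scalar:
        return float(eff[0])
    return eff.reshape(g.shape)


def phase_modulation(g, s):
    """Polar phasor coordinates: ``phase = atan2(s, g)`` in (-pi, pi],
    ``modulation = sqrt(g^2 + s^2)``; (0, 0) maps to phase 0 by convention.
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    phase = np.arctan2(s, g)
    modulation = np.hypot(g, s)
    return (float(phase), float(modulation)) if g.ndim == 0 else (phase, modulation)


def per_cell_stats(
    phasor: PhasorImage,
    axis: BretAxis | None = None,
    time: float | int | None = None,
    depth: float | int | None = None,
) -> pd.DataFrame:
    """Per-cell summary table from a segmented phasor image.

    For every label, the cell phasor is the **intensity-weighted** mean of
    its pixel phasors (equivalent to pooling the cell's photons, by
    linearity of the transform); efficiency, phase and modulation are then
    computed from that mean. One row per cell; empty labeling gives an
    empty table.
    """
    labels = phasor.labels
    ids = np.unique(labels[labels > 0])
    rows = []
    for cell_id in ids:
        sel = (labels == cell_id) & phasor.mask & np.isfinite(phasor.g)
        if not sel.any():
            continue
        w = phasor.intensity[sel]
        if w.sum() <= 0:
            w = np.ones_like(w)
        g_mean = float(np.average(phasor.g[sel], weights=w))
        s_mean = float(np.average(phasor.s[sel], weights=w))
        rr, cc = np.nonzero(labels == cell_id)
        ph, mod = phase_modulation(g_mean, s_mean)
        rows.append(
            {
                "cell_id": int(cell_id),
                "area": int(rr.size),
                "centroid_row": float(rr.mean()),
                "centroid_col": float(cc.mean()),
                "g": g_mean,
                "s": s_mean,
                "efficiency": bret_efficiency(g_mean, s_mean, axis)
                if axis is not None
                else np.nan,
                "phase": ph,
                "modulation": mod,
                "total_intensity": float(phasor.intensity[labels == cell_id].sum()),
                "time": time,
                "depth": depth,
            }
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def series_assemble(
    tables: list[pd.DataFrame], match_radius: float = 10.0
) -> pd.DataFrame:
    """Concatenate per-cell tables over time/depth into one long-format
    series with persistent track ids.

    Cells are matched across consecutive time points by nearest centroid
    within ``match_radius`` pixels (greedy, closest pair first); unmatched
    cells start new tracks, and a cell absent at a time point simply has no
    row there (no imputation). When two candidates fall within the radius
    the nearest is chosen and the row is flagged ``ambiguous_match``.
    """
    if not tables:
        return pd.DataFrame(columns=CELL_COLUMNS + ["track_id", "ambiguous_match"])
    frames = [t.copy() for t in tables if len(t)]
    if not frames:
        return pd.DataFrame(columns=CELL_COLUMNS + ["track_id", "ambiguous_match"])
    combined = pd.concat(frames, ignore_index=True).sort_values(
        ["time", "cell_id"], kind="stable"
    )
    next_track = 0
    active: dict[int, tuple[float, float]] = {}  # track -> last centroid
    out_rows = []
    for t_val, grp in combined.groupby("time", dropna=False, sort=True):
        track_pos = list(active.items())
        taken: set[int] = set()
        pending = []
        for _, row in grp.iterrows():
            pos = (row["centroid_row"], row["centroid_col"])
            cands = [
                (np.hypot(pos[0] - p[0], pos[1] - p[1]), tr)
                for tr, p in track_pos
                if tr not in taken
            ]
            cands = [c for c in cands if c[0] <= match_radius]
            cands.sort()
            if cands:
                dist, track = cands[0]
                ambiguous = len(cands) > 1
                if ambiguous:
                    warnings.warn(
                        f"ambiguous centroid match at time {t_val!r}: "
                        f"{len(cands)} candidates within {match_radius} px",
                        stacklevel=2,
                    )
                taken.add(track)
            else:
                track = next_track
                next_track += 1
                ambiguous = False
            pending.append((track, pos, row, ambiguous))
        for track, pos, row, ambiguous in pending:
            active[track] = pos
            rec = row.to_dict()
            rec["track_id"] = track
            rec["ambiguous_match"] = ambiguous
            out_rows.append(rec)
    out = pd.DataFrame(out_rows)
    return out.reset_index(drop=True)
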