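"""Phasor-space mixture analysis: chord unmixing, GMM clustering,
nearest-reference assignment.

Because the phasor transform is linear in photon counts, a pixel containing
two emission components with pure-component phasors ``(g1, s1)`` and
``(g2, s2)`` lies at ``(f1*g1 + f2*g2, f1*s1 + f2*s2)`` with ``f1 + f2 = 1``
— on the straight chord between the references, at the position given by
the components' relative *intensity* contributions. Noisy pixels fall off
the chord; they are resolved by orthogonal (least-squares) projection onto
it, with the perpendicular distance reported as a quality metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import IllPosedError, ParameterError
from .pipeline import PhasorImage

__all__ = [
    "ReferencePhasor",
    "ReferenceLibrary",
    "UnmixResult",
    "ClusterResult",
    "unmix_two",
    "gmm_cluster",
    "assign_clusters",
]


@dataclass(frozen=True)
class ReferencePhasor:
    """A pure reporter's phasor centroid, with optional spread and mean
    intensity."""

    g: float
    s: float
    cov: np.ndarray | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.g**2 + self.s**2 > 1.0 + 1e-9:
            raise ParameterError(
                f"reference phasor ({self.g:.4f}, {self.s:.4f}) outside the unit disk"
            )

    @property
    def point(self) -> np.ndarray:
        return np.array([self.g, self.s])


class ReferenceLibrary:
    """Named reporter -> reference phasor mapping.

    Used for unmixing-chord endpoints, cluster assignment, and the BRET
    donor/acceptor axis. Construct from a mapping of names to
    ``ReferencePhasor`` / ``(g, s)`` pairs, from spectra
    (:meth:`from_spectra`), or from CSV (:meth:`from_csv`).
    """

    def __init__(self, entries: Mapping[str, ReferencePhasor | tuple[float, float]]) -> None:
        self.entries: dict[str, ReferencePhasor] = {}
        for name, entry in entries.items():
            if not isinstance(entry, ReferencePhasor):
                entry = ReferencePhasor(float(entry[0]), float(entry[1]))
            self.entries[str(name)] = entry
        if not self.entries:
            raise ParameterError("reference library is empty")

    def __getitem__(self, name: str) -> ReferencePhasor:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_spectra(cls, library, window=None) -> "ReferenceLibrary":
        """Reference phasors of a spectral reporter library."""
        from .spectra import DEFAULT_WINDOW
        from .synth import reference_phasors

        refs = reference_phasors(library, window or DEFAULT_WINDOW)
        return cls(refs)

    @classmethod
    def from_csv(cls, path) -> "ReferenceLibrary":
        """Read a (name, g, s[, cov_gg, cov_gs, cov_ss, intensity]) CSV."""
        df = pd.read_csv(path)
        entries = {}
        for _, row in df.iterrows():
            cov = None
            if {"cov_gg", "cov_gs", "cov_ss"} <= set(df.columns):
                cov = np.array(
                    [[row["cov_gg"], row["cov_gs"]], [row["cov_gs"], row["cov_ss"]]]
                )
            entries[row.iloc[0]] = ReferencePhasor(
                float(row["g"]), float(row["s"]), cov=cov,
                intensity=float(row["intensity"]) if "intensity" in df.columns else None,
            )
        return cls(entries)

    def to_csv(self, path) -> None:
        rows = []
        for name, e in self.entries.items():
            row = {"name": name, "g": e.g, "s": e.s}
            if e.cov is not None:
                row.update(cov_gg=e.cov[0, 0], cov_gs=e.cov[0, 1], cov_ss=e.cov[1, 1])
            if e.intensity is not None:
                row["intensity"] = e.intensity
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class UnmixResult:
    """Two-component unmixing output.

    ``f1``/``f2`` are relative intensity fractions of the two references
    (clamped to [0, 1], summing to 1 wherever defined, NaN off-mask);
    ``off_chord_distance`` is each pixel's perpendicular distance from the
    reference chord before projection.
    """

    f1: np.ndarray
    f2: np.ndarray
    off_chord_distance: np.ndarray
    ref1: tuple[float, float]
    ref2: tuple[float, float]


@dataclass
class ClusterResult:
    """GMM clustering of a phasor point cloud.

    ``labels`` are hard maximum-responsibility assignments (shape of the
    input point set); ``centers`` the (k, 2) cluster means; ``assignment``
    maps cluster index -> reporter name after :func:`assign_clusters`.
    """

    labels: np.ndarray
    centers: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray
    converged: bool
    assignment: dict[int, str] | None = None
    assignment_distance: dict[int, float] | None = None


def _as_points(phasor: PhasorImage | np.ndarray) -> tuple[np.ndarray, PhasorImage | None]:
    if isinstance(phasor, PhasorImage):
        return phasor.points(), phasor
    pts = np.asarray(phasor, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError(f"expected (N, 2) phasor points, got shape {pts.shape}")
    return pts, None


def unmix_two(
    phasor: PhasorImage | np.ndarray,
    ref1: tuple[float, float],
    ref2: tuple[float, float],
) -> UnmixResult:
    """Two-component linear unmixing along the ref1-ref2 chord.

    Each phasor point is orthogonally projected onto the chord; ``f1`` is
    the normalized position from ``ref2`` toward ``ref1`` clamped to
    [0, 1], ``f2 = 1 - f1``. Accepts a :class:`PhasorImage` (operates on
    its mask, returns image-shaped fraction maps) or an ``(N, 2)`` point
    array (returns per-point vectors).
    """
    p1 = np.asarray(ref1, dtype=float)
    p2 = np.asarray(ref2, dtype=float)
    chord = p1 - p2
    length = np.linalg.norm(chord)
    if length <= 1e-6:
        raise ParameterError(f"degenerate chord: references {ref1} and {ref2} coincide")
    pts, image = _as_points(phasor)
    rel = pts - p2
    t = rel @ chord / length**2
    perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / length
    f1_pts = np.clip(t, 0.0, 1.0)
    if image is None:
        return UnmixResult(f1_pts, 1.0 - f1_pts, perp, tuple(p1), tuple(p2))
    f1 = np.full(image.mask.shape, np.nan)
    off = np.full(image.mask.shape, np.nan)
    f1[image.mask] = f1_pts
    off[image.mask] = perp
    return UnmixResult(f1, 1.0 - f1, off, tuple(p1), tuple(p2))


def gmm_cluster(points: np.ndarray | PhasorImage, k: int, seed: int = 0) -> ClusterResult:
    """Gaussian-mixture clustering of (g, s) points.

    Full-covariance EM with deterministic k-means++ initialization from
    ``seed`` and a covariance floor of 1e-8 (degenerate/duplicated point
    clouds are handled rather than crashing). Hard labels are maximum
    responsibility. Identical inputs and seed give identical labels.
    """
    from sklearn.mixture import GaussianMixture

    pts, _ = _as_points(points)
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > pts.shape[0]:
        raise ParameterError(f"k={k} exceeds point count {pts.shape[0]}")
    if pts.shape[0] < 10 * k:
        warnings.warn(
            f"only {pts.shape[0]} points for k={k} clusters; fit may be unstable",
            stacklevel=2,
        )
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=1e-8,
        init_params="k-means++",
        n_init=1,
        max_iter=300,
        random_state=int(seed) % (2**32),
    )
    with warnings.catch_warnings():
        # duplicated-point degeneracy is handled by reg_covar; silence EM chatter
        warnings.filterwarnings("ignore", module="sklearn")
        labels = gmm.fit_predict(pts)
    return ClusterResult(
        labels=labels,
        centers=gmm.means_.copy(),
        covariances=gmm.covariances_.copy(),
        weights=gmm.weights_.copy(),
        converged=bool(gmm.converged_),
    )


def assign_clusters(
    centers: np.ndarray | ClusterResult, library: ReferenceLibrary
) -> dict[int, str]:
    """Assign each cluster center to the closest reference reporter.

    Euclidean distance in (g, s); ties broken by lexicographic reporter
    name. Two clusters may share a reporter (warned). When given a
    :class:`ClusterResult`, the assignment and distances are also stored on
    it.
    """
    result = centers if isinstance(centers, ClusterResult) else None
    pts = result.centers if result is not None else np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError(f"expected (k, 2) centers, got {pts.shape}")
    names = sorted(library.names)  # lexicographic order settles exact ties
    ref_pts = np.array([library[n].point for n in names])
    assignment: dict[int, str] = {}
    distances: dict[int, float] = {}
    for i, center in enumerate(pts):
        d = np.linalg.norm(ref_pts - center, axis=1)
        j = int(np.argmin(d))  # argmin takes the first = lexicographically first on ties
        assignment[i] = names[j]
        distances[i] = float(d[j])
    used = list(assignment.values())
    dupes = {n for n in used if used.count(n) > 1}
    if dupes:
        warnings.warn(
            f"multiple clusters assigned to the same reporter(s): {sorted(dupes)}",
            stacklevel=2,
        )
    if result is not None:
        result.assignment = assignment
        result.assignment_distance = distances
    return assignment
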