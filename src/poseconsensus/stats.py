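"""Similarity statistics: native/reference densities, log ratios, score weight.

The consensus reward compares, for each pairwise feature value s, a density
fitted on *native* pose pairs (both poses < 2 Å from the ground truth) against
a density fitted on *all* pose pairs, via log f(s | Native) / f(s | Reference).
Densities are Gaussian kernel density estimates on a bounded support
([0, 1] for pseudo-Tanimoto similarities with bandwidth 0.03; [0, 6] Å for
MCSS RMSD with bandwidth 0.18, values above 6 Å capped to 6 Å beforehand).
Boundary bias is removed by reflecting the data across both support
endpoints; the density is zero outside the support and normalized exactly
over it.

The pose-score weight C is obtained by binning pooled poses by score
(descending, bins of 100), fitting a line to (mean score, −log fraction
correct) per bin, and taking the magnitude of the slope.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import signal
from scipy.stats import norm

from .featurize import FEATURE_KINDS
from .pose_model import NATIVE_RMSD_THRESHOLD
from .similarity import ALL_PAIR_KINDS, PairFeatureTensor

__all__ = [
    "ReflectedKDE",
    "SimilarityDistributions",
    "CnnWeightFit",
    "fit_distribution",
    "fit_similarity_statistics",
    "log_likelihood_ratio",
    "fit_cnn_weight",
    "MCSS_RMSD_CAP",
    "DENSITY_FLOOR",
]

MCSS_RMSD_CAP = 6.0
DENSITY_FLOOR = 1e-9
SIMILARITY_BANDWIDTH = 0.03
MCSS_BANDWIDTH = 0.18
GRID_SIZE = 4096


class ReflectedKDE:
    """Gaussian KDE with reflected boundaries on a finite support.

    Exact evaluation (:meth:`pdf`) sums the Gaussian kernels of the data and
    of their reflections across both endpoints and divides by the analytic
    mass over the support, so the density integrates to 1 to machine
    precision.  A cached fixed grid (:attr:`grid`, linear interpolation via
    :meth:`grid_pdf`) serves high-volume queries; for large fits the grid is
    built by histogram binning plus kernel convolution.
    """

    def __init__(
        self,
        values: Sequence[float],
        bandwidth: float,
        support: tuple[float, float],
        grid_size: int = GRID_SIZE,
    ):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("cannot fit a density to an empty sample")
        if bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        lo, hi = float(support[0]), float(support[1])
        if not lo < hi:
            raise ValueError("support must be a non-empty interval")
        if np.any(values < lo) or np.any(values > hi):
            raise ValueError("values must lie within the support")
        self.values = values
        self.bandwidth = float(bandwidth)
        self.support = (lo, hi)
        self.grid_size = int(grid_size)
        # data plus reflections across each endpoint
        self._mu = np.concatenate([values, 2 * lo - values, 2 * hi - values])
        # analytic mass of all components over the support
        h = self.bandwidth
        mass = norm.cdf((hi - self._mu) / h) - norm.cdf((lo - self._mu) / h)
        self._norm = float(mass.sum()) / values.size
        self._grid_x: Optional[np.ndarray] = None
        self._grid_y: Optional[np.ndarray] = None

    def pdf(self, x) -> np.ndarray:
        """Exact density at ``x`` (zero outside the support)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.support
        inside = (x >= lo) & (x <= hi)
        out = np.zeros_like(x)
        if np.any(inside):
            xi = x[inside]
            z = (xi[:, None] - self._mu[None, :]) / self.bandwidth
            dens = np.exp(-0.5 * z * z).sum(axis=1) / (
                self.bandwidth * math.sqrt(2 * math.pi) * self.values.size
            )
            out[inside] = dens / self._norm
        return out

    def _build_grid(self) -> None:
        lo, hi = self.support
        h = self.bandwidth
        x = np.linspace(lo, hi, self.grid_size)
        if self.values.size <= 2000:
            y = self.pdf(x)
        else:
            # histogram + kernel convolution on an extended grid
            dx = (hi - lo) / (self.grid_size - 1)
            pad = int(np.ceil(6 * h / dx)) + 1
            edges = np.linspace(
                lo - pad * dx, hi + pad * dx, self.grid_size + 2 * pad + 1
            )
            counts, _ = np.histogram(self._mu, bins=edges)
            kx = np.arange(-pad, pad + 1) * dx
            kernel = np.exp(-0.5 * (kx / h) ** 2) / (h * math.sqrt(2 * math.pi))
            dens = signal.fftconvolve(counts.astype(float), kernel, mode="same")
            dens = dens[pad:-pad] / self.values.size / self._norm
            # renormalize residual binning error over the support
            dens /= np.trapezoid(dens, x)
            y = np.maximum(dens, 0.0)
        self._grid_x, self._grid_y = x, y

    @property
    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        if self._grid_x is None:
            self._build_grid()
        return self._grid_x, self._grid_y

    def grid_pdf(self, x) -> np.ndarray:
        """Density via linear interpolation on the cached grid."""
        gx, gy = self.grid
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.interp(x, gx, gy, left=0.0, right=0.0)
        lo, hi = self.support
        out[(x < lo) | (x > hi)] = 0.0
        return out

    def mean(self) -> float:
        gx, gy = self.grid
        return float(np.trapezoid(gx * gy, gx))

    def integral(self, n: int = 2001) -> float:
        lo, hi = self.support
        x = np.linspace(lo, hi, n)
        return float(np.trapezoid(self.pdf(x), x))


def fit_distribution(
    values: Sequence[float],
    bandwidth: float,
    support: tuple[float, float],
) -> ReflectedKDE:
    """Fit a boundary-reflected Gaussian KDE (see :class:`ReflectedKDE`)."""
    return ReflectedKDE(values, bandwidth, support)


# ---------------------------------------------------------------------------
# Native / reference distributions
# ---------------------------------------------------------------------------

_KIND_PARAMS = {
    "hbond": (SIMILARITY_BANDWIDTH, (0.0, 1.0)),
    "saltbridge": (SIMILARITY_BANDWIDTH, (0.0, 1.0)),
    "hydrophobic": (SIMILARITY_BANDWIDTH, (0.0, 1.0)),
    "mcss": (MCSS_BANDWIDTH, (0.0, MCSS_RMSD_CAP)),
}


@dataclass
class SimilarityDistributions:
    """Fitted native and reference densities per pairwise feature kind."""

    native: dict[str, ReflectedKDE]
    reference: dict[str, ReflectedKDE]
    provenance: dict = field(default_factory=dict)

    @property
    def kinds(self) -> list[str]:
        return list(self.native)

    def to_json(self, path: str | Path) -> None:
        """Serialize as a JSON file (grids included for portability)."""
        payload = {"provenance": self.provenance, "kinds": {}}
        for kind in self.native:
            entry = {}
            for label, dist in (("native", self.native[kind]),
                                ("reference", self.reference[kind])):
                entry[label] = {
                    "bandwidth": dist.bandwidth,
                    "support": list(dist.support),
                    "values": dist.values.tolist(),
                }
            payload["kinds"][kind] = entry
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimilarityDistributions":
        payload = json.loads(Path(path).read_text())
        native, reference = {}, {}
        for kind, entry in payload["kinds"].items():
            for label, store in (("native", native), ("reference", reference)):
                spec = entry[label]
                store[kind] = ReflectedKDE(
                    spec["values"], spec["bandwidth"], tuple(spec["support"])
                )
        return cls(native=native, reference=reference,
                   provenance=payload.get("provenance", {}))


def _collect_pair_values(
    tensor: PairFeatureTensor,
    kind: str,
    native_only: bool,
    keep: Sequence[int],
    threshold: float,
) -> np.ndarray:
    flags = tensor.native_flags(threshold) if native_only else None
    chunks = []
    keep_set = set(keep)
    for (i, j), block in tensor.inter.items():
        if i not in keep_set or j not in keep_set or kind not in block:
            continue
        mat = block[kind]
        if native_only:
            mask = flags[i][:, None] & flags[j][None, :]
            chunks.append(mat[mask])
        else:
            chunks.append(mat.ravel())
    for i, block in tensor.intra.items():
        if i not in keep_set or kind not in block:
            continue
        mat = block[kind]
        iu = np.triu_indices(mat.shape[0], k=1)
        if native_only:
            mask = flags[i][:, None] & flags[i][None, :]
            chunks.append(mat[iu][mask[iu]])
        else:
            chunks.append(mat[iu])
    if not chunks:
        return np.array([])
    return np.concatenate(chunks)


def fit_similarity_statistics(
    tensor: PairFeatureTensor,
    exclude_target: Optional[str] = None,
    native_threshold: float = NATIVE_RMSD_THRESHOLD,
) -> SimilarityDistributions:
    """Fit native and reference densities from a labelled pair tensor.

    A pair is *native* when both of its poses are native (< threshold Å from
    their ground truths).  The reference fit uses all pairs.  MCSS RMSD
    values above the 6 Å cap are set to 6 Å before fitting.  Pairs involving
    any ligand of ``exclude_target`` are omitted from both fits
    (leave-one-target-out evaluation).
    """
    if tensor.targets is None:
        keep = list(range(tensor.n_ligands))
    else:
        keep = [
            i
            for i, t in enumerate(tensor.targets)
            if exclude_target is None or t != exclude_target
        ]
    kinds = set()
    for block in tensor.inter.values():
        kinds.update(block)
    native, reference = {}, {}
    for kind in [k for k in ALL_PAIR_KINDS if k in kinds]:
        bandwidth, support = _KIND_PARAMS[kind]
        ref_vals = _collect_pair_values(tensor, kind, False, keep, native_threshold)
        nat_vals = _collect_pair_values(tensor, kind, True, keep, native_threshold)
        if nat_vals.size == 0:
            raise ValueError(f"no native pairs available for feature '{kind}'")
        if kind == "mcss":
            ref_vals = np.minimum(ref_vals, MCSS_RMSD_CAP)
            nat_vals = np.minimum(nat_vals, MCSS_RMSD_CAP)
        native[kind] = ReflectedKDE(nat_vals, bandwidth, support)
        reference[kind] = ReflectedKDE(ref_vals, bandwidth, support)
    return SimilarityDistributions(
        native=native,
        reference=reference,
        provenance={
            "excluded_target": exclude_target,
            "native_threshold": native_threshold,
            "n_ligands": len(keep),
        },
    )


def log_likelihood_ratio(
    dists: SimilarityDistributions,
    kind: str,
    value,
    method: str = "grid",
) -> np.ndarray | float:
    """log(native density / reference density) at ``value``.

    Values are clamped to the support (MCSS RMSD capped at 6 Å); densities
    are floored at 1e-9 to keep the objective finite.  ``method='grid'``
    interpolates the cached evaluation grid; ``'exact'`` evaluates the KDEs
    in closed form.
    """
    if kind not in dists.native:
        raise KeyError(f"unknown feature kind '{kind}'")
    nat = dists.native[kind]
    ref = dists.reference[kind]
    scalar = np.isscalar(value)
    x = np.atleast_1d(np.asarray(value, dtype=float))
    lo, hi = nat.support
    x = np.clip(x, lo, hi)
    if method == "exact":
        fn, fr = nat.pdf(x), ref.pdf(x)
    elif method == "grid":
        fn, fr = nat.grid_pdf(x), ref.grid_pdf(x)
    else:
        raise ValueError(f"unknown method '{method}'")
    out = np.log(np.maximum(fn, DENSITY_FLOOR) / np.maximum(fr, DENSITY_FLOOR))
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Pose-score weight
# ---------------------------------------------------------------------------

@dataclass
class CnnWeightFit:
    """Binned negative-log-likelihood line fit giving the score weight C."""

    bin_size: int
    bin_mean_scores: np.ndarray
    bin_neg_log_frac: np.ndarray
    slope: float
    intercept: float
    C: float

    @classmethod
    def from_bins(
        cls, mean_scores: Sequence[float], neg_log_fracs: Sequence[float],
        bin_size: int = 100,
    ) -> "CnnWeightFit":
        """Fit the line directly from per-bin summaries."""
        x = np.asarray(mean_scores, dtype=float)
        y = np.asarray(neg_log_fracs, dtype=float)
        if x.size < 2:
            raise ValueError("need at least 2 bins to fit a line")
        slope, intercept = np.polyfit(x, y, 1)
        c = abs(float(slope))
        if c < 1e-12:
            c = 0.0
        if c == 0.0:
            warnings.warn("flat NLL fit: score weight C is 0", stacklevel=2)
        return cls(bin_size, x, y, float(slope), float(intercept), c)


def fit_cnn_weight(
    pose_scores: Sequence[float],
    native_flags: Sequence[bool],
    bin_size: int = 100,
) -> CnnWeightFit:
    """Fit the pose-score weight C from pooled labelled poses.

    Poses are sorted by score descending and grouped into consecutive
    disjoint bins of ``bin_size`` (a trailing partial bin is dropped).  Per
    bin, x is the mean score and y = −log(fraction native), with the
    fraction floored at 1/(2·bin_size) so empty bins stay finite.  C is the
    magnitude of the OLS slope of y on x.
    """
    scores = np.asarray(pose_scores, dtype=float)
    flags = np.asarray(native_flags, dtype=bool)
    if scores.shape != flags.shape:
        raise ValueError("scores and native flags must align")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    order = np.argsort(-scores, kind="stable")
    n_bins = scores.size // bin_size
    if n_bins < 2:
        raise ValueError(
            f"need at least 2 full bins of {bin_size}; got {scores.size} poses"
        )
    xs, ys = [], []
    floor = 1.0 / (2.0 * bin_size)
    for b in range(n_bins):
        idx = order[b * bin_size : (b + 1) * bin_size]
        xs.append(scores[idx].mean())
        frac = max(float(flags[idx].mean()), floor)
        ys.append(-math.log(frac))
    return CnnWeightFit.from_bins(xs, ys, bin_size=bin_size)
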