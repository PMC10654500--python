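"""Periodic WHAM: free-energy profiles along phi_I from biased windows.

The estimator is the standard self-consistent weighted-histogram iteration
on a uniform periodic grid, with harmonic biases evaluated on the minimal
periodic image.  Bins never visited by any window are reported as NaN; a
gap *inside* the sampled arc raises a coverage error (the profile there
would be unsupported), while unsampled bins outside a single contiguous
sampled arc are simply left unreported.

The 90-100 degree stretch around the conical intersection is flagged
(annotation only): classical sampling is unreliable there, so consumers
typically exclude flagged bins from quantitative comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConvergenceError, CoverageError, StrandgateError
from .periodic import in_circular_range, periodic_delta, wrap_angle

#: kcal/(mol K)
R_KCAL = 1.98720425864083e-3

__all__ = ["UmbrellaWindow", "PMFProfile", "wham", "barrier_height",
           "compare_pmf", "read_umbrella_csv"]


@dataclass
class UmbrellaWindow:
    """Biased samples from one umbrella window."""

    center: float                 # degrees
    k_bias: float                 # kcal/(mol deg^2)
    samples: np.ndarray           # degrees in (-180, 180]
    temperature: float = 300.0    # K

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise StrandgateError("umbrella window has no samples")
        self.samples = wrap_angle(self.samples)


@dataclass
class PMFProfile:
    """Free energy per periodic bin, anchored so the minimum is zero."""

    bin_centers: np.ndarray       # degrees, uniform over the full circle
    free_energy: np.ndarray       # kcal/mol; NaN where unsampled
    temperature: float
    ci_window: tuple[float, float] = (90.0, 100.0)

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    @property
    def flagged_ci(self) -> np.ndarray:
        lo, hi = self.ci_window
        return in_circular_range(self.bin_centers, lo, hi)

    def value_at(self, phi_deg: float) -> float:
        idx = int(np.argmin(np.abs(periodic_delta(self.bin_centers, phi_deg))))
        return float(self.free_energy[idx])

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"phi_deg": self.bin_centers,
                      "G_kcal_mol": self.free_energy,
                      "flagged_ci": self.flagged_ci}).to_csv(path, index=False)


def _bin_edges(n_bins: int) -> np.ndarray:
    return np.linspace(-180.0, 180.0, n_bins + 1)


def wham(windows: Sequence[UmbrellaWindow], n_bins: int = 72,
         tolerance: float = 1e-4, max_iter: int = 100_000,
         min_bin_count: int = 10) -> PMFProfile:
    """Self-consistent WHAM over periodic bins.

    Converged when the largest change of any window free energy between
    iterations drops below ``tolerance`` (kcal/mol).  Bins holding fewer
    than ``min_bin_count`` samples in total are left unreported (NaN): a
    handful of far-tail samples carries an exp(+beta*u) reweighting factor
    that makes their free-energy estimate meaningless.  Raises
    :class:`CoverageError` when reportable bins form more than one arc on
    the circle and :class:`ConvergenceError` at the iteration budget.
    """
    if len(windows) == 0:
        raise StrandgateError("no umbrella windows")
    temps = {w.temperature for w in windows}
    if len(temps) != 1:
        raise StrandgateError(f"windows at different temperatures: {sorted(temps)}")
    temperature = temps.pop()
    kT = R_KCAL * temperature

    edges = _bin_edges(n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    n_i = counts.sum(axis=1).astype(float)
    total = counts.sum(axis=0).astype(float)

    populated = total >= max(int(min_bin_count), 1)
    _check_coverage(populated)

    # bias factors c_ik = exp(-beta * u_i(bin_k))
    bias = np.stack([0.5 * w.k_bias * periodic_delta(centers, w.center) ** 2
                     for w in windows])
    c = np.exp(-bias / kT)

    f = np.zeros(len(windows))
    for _ in range(int(max_iter)):
        denom = (n_i[:, None] * np.exp(f[:, None] / kT) * c).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(populated, total / denom, 0.0)
        p_sum = p.sum()
        p /= p_sum
        f_new = -kT * np.log(np.maximum((c * p[None, :]).sum(axis=1), 1e-300))
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {delta:.3g})")

    with np.errstate(divide="ignore"):
        g = np.where(populated, -kT * np.log(np.maximum(p, 1e-300)), np.nan)
    g -= np.nanmin(g)
    return PMFProfile(centers, g, temperature)


def _check_coverage(populated: np.ndarray) -> None:
    if populated.all():
        return
    if not populated.any():
        raise CoverageError("no samples in any bin")
    # count populated arcs on the circle
    transitions = np.flatnonzero(populated != np.roll(populated, 1))
    n_arcs = len(transitions) // 2
    if n_arcs > 1:
        gaps = np.flatnonzero(~populated)
        raise CoverageError(
            f"umbrella windows leave interior gaps (empty bins at indices "
            f"{gaps.tolist()}); add overlapping windows")


def barrier_height(pmf: PMFProfile, cis_region: tuple[float, float] = (-30.0, 30.0),
                   trans_region: tuple[float, float] = (150.0, -150.0)
                   ) -> float:
    """Forward barrier: maximum along the lower of the two circular paths
    from the cis-region minimum to the trans-region minimum, minus the cis
    minimum.  Regions are circular arcs (lo -> hi in increasing angle)."""
    return _barrier(pmf, cis_region, trans_region)[0]


def _region_min_bin(pmf: PMFProfile, region: tuple[float, float]) -> int:
    mask = in_circular_range(pmf.bin_centers, *region) & np.isfinite(pmf.free_energy)
    if not mask.any():
        raise StrandgateError(f"no populated bins in region {region}")
    idx = np.flatnonzero(mask)
    return int(idx[np.argmin(pmf.free_energy[idx])])


def _barrier(pmf: PMFProfile, cis_region, trans_region) -> tuple[float, str]:
    i_cis = _region_min_bin(pmf, cis_region)
    i_trans = _region_min_bin(pmf, trans_region)
    n = pmf.n_bins
    g = pmf.free_energy

    def path_max(start: int, stop: int, step: int) -> float:
        idx = [start]
        i = start
        while i != stop:
            i = (i + step) % n
            idx.append(i)
        values = g[idx]
        return np.inf if np.isnan(values).any() else float(values.max())

    up = path_max(i_cis, i_trans, +1)
    down = path_max(i_cis, i_trans, -1)
    if not np.isfinite(min(up, down)):
        raise CoverageError("no fully sampled path between the two regions")
    best, direction = min((up, "increasing"), (down, "decreasing"))
    return best - float(g[i_cis]), direction


def compare_pmf(pmf_a: PMFProfile, pmf_b: PMFProfile,
                cis_region: tuple[float, float] = (-30.0, 30.0),
                trans_region: tuple[float, float] = (150.0, -150.0)) -> float:
    """Barrier difference barrier(a) - barrier(b), kcal/mol."""
    if pmf_a.temperature != pmf_b.temperature:
        raise StrandgateError("profiles at different temperatures are not comparable")
    return (barrier_height(pmf_a, cis_region, trans_region)
            - barrier_height(pmf_b, cis_region, trans_region))


def read_umbrella_csv(paths: Sequence, temperature: float = 300.0) -> list[UmbrellaWindow]:
    """Read per-window CSVs (columns window_center_deg, k_bias, phi_deg)."""
    import pandas as pd

    windows = []
    for path in paths:
        df = pd.read_csv(path)
        windows.append(UmbrellaWindow(
            center=float(df["window_center_deg"].iloc[0]),
            k_bias=float(df["k_bias"].iloc[0]),
            samples=df["phi_deg"].to_numpy(),
            temperature=temperature))
    return windows
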