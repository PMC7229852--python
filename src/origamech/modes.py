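"""Global-fluctuation analysis of coarse-grained trajectories.

Pipeline: rigid superposition of every frame onto the first frame over a
particle selection, mean structure and per-nucleotide RMSF, eigendecomposition
of the 3N x 3N positional covariance C_nm = (1/T) sum_t x_n(t) x_m(t) (x are
deviations from the trajectory mean after alignment), collinearity between
mode sets of different structures, projections of trajectories onto modes,
free-energy profiles by Boltzmann inversion of the projection histogram, and
two-state (metastability) statistics on those profiles.

Eigenvalues are variances in nm^2; the total mean-square fluctuation is their
sum, equal to the covariance trace.  Eigenvector signs are fixed so that each
mode's largest-magnitude component is positive, making projections and
collinearity patterns reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .errors import ArgumentError, DegenerateHistogramError
from .geometry import kabsch_superpose
from .io import Configuration, Trajectory


@dataclass
class ModeSpectrum:
    """Eigenmodes of the positional covariance over a particle selection."""

    selection: np.ndarray  # ordered nucleotide indices (N,)
    mean: np.ndarray  # (3N,) mean structure, nm
    eigenvalues: np.ndarray  # (k,) nm^2, descending
    eigenvectors: np.ndarray  # (3N, k), orthonormal columns
    total_msf: float  # nm^2, = covariance trace = sum of all eigenvalues

    @property
    def n_particles(self) -> int:
        return int(self.selection.size)

    def validate(self) -> None:
        lam = self.eigenvalues
        if (lam < -1e-10).any() or (np.diff(lam) > 1e-10).any():
            raise ArgumentError("eigenvalues must be nonnegative and descending")
        g = self.eigenvectors.T @ self.eigenvectors
        if np.abs(g - np.eye(g.shape[0])).max() >= 1e-8:
            raise ArgumentError("eigenvectors not orthonormal")


@dataclass
class ProjectionSeries:
    """Per-frame scalar projection s_t = <x_t | p> (nm) onto one mode."""

    values: np.ndarray  # (T,)
    timestamps: np.ndarray  # (T,) us
    mode_id: str = "p1"

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class FEProfile:
    """Free energy F(s) = -ln rho(s) (units k_BT), offset so min F = 0."""

    centers: np.ndarray  # (B,) bin centers, nm
    free_energy: np.ndarray  # (B,) k_BT; masked bins hold +inf
    counts: np.ndarray  # (B,) int
    masked: np.ndarray  # (B,) bool, True where count == 0


@dataclass
class TwoStateStats:
    """Metastability bookkeeping along a projection coordinate."""

    n_states: int
    divider: float | None  # nm; None for single-state
    populations: tuple[float, ...]  # fractions, sum to 1
    residence_frames: tuple[float, ...]  # mean run length per state
    transitions: int
    barriers: tuple[float, ...] | None  # k_BT, from each minimum; None if single-state
    minima: tuple[float, ...] | None  # positions of the wells, nm


def _superpose_frame(
    cfg: Configuration, ref_points: np.ndarray, selection: np.ndarray
) -> Configuration:
    tf, _ = kabsch_superpose(cfg.positions[selection], ref_points)
    return cfg.transformed(tf.rotation, tf.translation)


def align_and_average(
    traj: Trajectory, selection: np.ndarray
) -> tuple[Trajectory, np.ndarray, np.ndarray]:
    """Superpose every frame onto the first over *selection*; mean and RMSF.

    Returns (aligned trajectory, mean structure (N_sel, 3), rmsf (N_sel,)).
    rmsf_i = sqrt(<|r_i(t) - <r_i>|^2>), nm.
    """
    selection = np.asarray(selection, dtype=np.intp)
    if selection.size == 0:
        raise ArgumentError("empty selection")
    if len(traj) < 2:
        raise ArgumentError("need at least 2 frames")
    ref = traj[0].positions[selection]
    aligned = [traj[0]] + [_superpose_frame(f, ref, selection) for f in traj.frames[1:]]
    coords = np.stack([f.positions[selection] for f in aligned])  # (T, N, 3)
    mean = coords.mean(0)
    rmsf = np.sqrt(((coords - mean) ** 2).sum(-1).mean(0))
    out = Trajectory(topology=traj.topology, frames=aligned, nm_per_unit=traj.nm_per_unit)
    return out, mean, rmsf


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    idx = np.abs(vecs).argmax(0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def covariance_modes(aligned: Trajectory, selection: np.ndarray) -> ModeSpectrum:
    """Eigenmodes of the covariance of aligned, mean-centered deviations.

    Computed through the thin SVD of the (T, 3N) deviation matrix, which is
    exact for the nonzero part of the spectrum (rank <= T - 1).
    """
    selection = np.asarray(selection, dtype=np.intp)
    if len(aligned) < 2:
        raise ArgumentError("need at least 2 frames")
    coords = np.stack([f.positions[selection] for f in aligned.frames])
    t = coords.shape[0]
    flat = coords.reshape(t, -1)
    mean = flat.mean(0)
    dev = flat - mean
    _, s, vt = np.linalg.svd(dev, full_matrices=False)
    lam = s**2 / t
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vecs = _fix_signs(vt[order].T)
    total = float((dev**2).sum() / t)
    spec = ModeSpectrum(
        selection=selection,
        mean=mean,
        eigenvalues=lam,
        eigenvectors=vecs,
        total_msf=total,
    )
    spec.validate()
    return spec


def collinearity_matrix(a: ModeSpectrum, b: ModeSpectrum, k: int = 10) -> np.ndarray:
    """k x k matrix of |<p_i^A | p_j^B>| between two mode sets."""
    if a.n_particles != b.n_particles or not np.array_equal(
        np.sort(a.selection), np.sort(b.selection)
    ):
        raise ArgumentError("spectra must be over identical selections")
    ka = min(k, a.eigenvectors.shape[1])
    kb = min(k, b.eigenvectors.shape[1])
    m = np.abs(a.eigenvectors[:, :ka].T @ b.eigenvectors[:, :kb])
    return np.clip(m, 0.0, 1.0)


def project_onto_mode(
    aligned: Trajectory,
    selection: np.ndarray,
    mode: np.ndarray,
    center: np.ndarray,
    index_map: np.ndarray | None = None,
    mode_id: str = "p1",
) -> ProjectionSeries:
    """Project aligned frames onto a (possibly foreign) mode.

    When *mode*/*center* come from a different structure's spectrum, the
    caller must supply *index_map*: ``index_map[i]`` is the nucleotide index
    in this trajectory corresponding to the i-th particle of the mode's
    selection.  No automatic matching is attempted.
    """
    selection = np.asarray(selection, dtype=np.intp)
    mode = np.asarray(mode, dtype=float)
    center = np.asarray(center, dtype=float)
    if abs(np.linalg.norm(mode) - 1.0) > 1e-8:
        raise ArgumentError("mode must be unit-norm")
    if mode.size != center.size:
        raise ArgumentError("mode and center dimensions differ")
    if index_map is not None:
        eff = np.asarray(index_map, dtype=np.intp)
    else:
        if 3 * selection.size != mode.size:
            raise ArgumentError(
                "mode dimension does not match selection; supply index_map for "
                "cross-structure projection"
            )
        eff = selection
    if 3 * eff.size != mode.size:
        raise ArgumentError("index_map length does not match mode dimension")
    coords = np.stack([f.positions[eff].ravel() for f in aligned.frames])
    s = (coords - center) @ mode
    return ProjectionSeries(values=s, timestamps=aligned.timestamps, mode_id=mode_id)


def free_energy_profile(series: ProjectionSeries, n_bins: int = 100) -> FEProfile:
    """Boltzmann inversion of the projection histogram: F = -ln(count/total).

    Zero-count bins are masked (F = +inf), never interpolated.
    """
    if n_bins < 5:
        raise ArgumentError("n_bins must be >= 5")
    vals = np.asarray(series.values, dtype=float)
    if vals.size == 0 or np.ptp(vals) == 0:
        raise DegenerateHistogramError("all samples identical; no histogram")
    counts, edges = np.histogram(vals, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    masked = counts == 0
    with np.errstate(divide="ignore"):
        f = -np.log(counts / counts.sum())
    f = f - f[~masked].min()
    f[masked] = np.inf
    return FEProfile(centers=centers, free_energy=f, counts=counts, masked=masked)


def _single_state(series_vals: np.ndarray, minima=None) -> TwoStateStats:
    return TwoStateStats(
        n_states=1,
        divider=None,
        populations=(1.0,),
        residence_frames=(float(series_vals.size),),
        transitions=0,
        barriers=None,
        minima=minima,
    )


def _run_lengths(labels: np.ndarray) -> tuple[float, float]:
    change = np.flatnonzero(np.diff(labels) != 0)
    bounds = np.concatenate([[-1], change, [labels.size - 1]])
    lengths = np.diff(bounds)
    states = labels[bounds[1:]]
    means = []
    for s in (0, 1):
        runs = lengths[states == s]
        means.append(float(runs.mean()) if runs.size else 0.0)
    return means[0], means[1]


def _bookkeeping(
    vals: np.ndarray,
    divider: float,
    barriers: tuple[float, float] | None,
    minima: tuple[float, float] | None,
) -> TwoStateStats:
    labels = (vals > divider).astype(np.int8)
    pops = (float((labels == 0).mean()), float((labels == 1).mean()))
    res = _run_lengths(labels)
    transitions = int((np.diff(labels) != 0).sum())
    return TwoStateStats(
        n_states=2,
        divider=float(divider),
        populations=pops,
        residence_frames=res,
        transitions=transitions,
        barriers=barriers,
        minima=minima,
    )


def two_state_stats(
    series: ProjectionSeries,
    profile: FEProfile | None = None,
    divider: float | None = None,
    min_prominence: float = 0.5,
) -> TwoStateStats:
    """Identify two metastable wells and their populations, barriers, kinetics.

    Wells are detected as minima of the masked free-energy profile with
    prominence >= *min_prominence* (k_BT); if fewer than two qualify, a
    single-state result is returned.  The divider is the highest-F bin
    between the two wells; barriers are F(divider) - F(well).

    An explicit *divider* skips well detection and does the frame
    bookkeeping (populations, residence times, divider crossings) directly;
    barriers are then reported only if a profile with two detectable wells
    is also supplied.
    """
    vals = np.asarray(series.values, dtype=float)
    if divider is not None:
        barriers = minima = None
        if profile is not None:
            detected = two_state_stats(series, profile, min_prominence=min_prominence)
            if detected.n_states == 2:
                barriers, minima = detected.barriers, detected.minima
        return _bookkeeping(vals, divider, barriers, minima)
    if profile is None:
        raise ArgumentError("either a profile or an explicit divider is required")
    ok = ~profile.masked
    f = profile.free_energy[ok]
    x = profile.centers[ok]
    if f.size < 5:
        return _single_state(vals)
    # pad so wells at the profile ends are still detected
    fp = np.concatenate([[np.inf], f, [np.inf]])
    peaks, props = find_peaks(-fp, prominence=min_prominence)
    peaks = peaks - 1
    if peaks.size < 2:
        return _single_state(vals, minima=(float(x[np.argmin(f)]),))
    # two deepest wells, separated by >= 2 bins
    order = peaks[np.argsort(f[peaks])]
    i1 = order[0]
    i2 = next((j for j in order[1:] if abs(j - i1) >= 2), None)
    if i2 is None:
        return _single_state(vals, minima=(float(x[i1]),))
    lo, hi = sorted((i1, i2))
    barrier_idx = lo + int(np.argmax(f[lo : hi + 1]))
    divider = float(x[barrier_idx])
    f_bar = float(f[barrier_idx])
    wells = sorted((float(x[lo]), float(x[hi])))
    barriers = (f_bar - float(f[lo]), f_bar - float(f[hi]))
    if float(x[lo]) > float(x[hi]):  # keep barrier order matching well order
        barriers = (barriers[1], barriers[0])
    labels = (vals > divider).astype(np.int8)
    pops = (float((labels == 0).mean()), float((labels == 1).mean()))
    res = _run_lengths(labels)
    transitions = int((np.diff(labels) != 0).sum())
    return TwoStateStats(
        n_states=2,
        divider=divider,
        populations=pops,
        residence_frames=res,
        transitions=transitions,
        barriers=barriers,
        minima=(wells[0], wells[1]),
    )


def synchronization(
    series_a: ProjectionSeries,
    series_b: ProjectionSeries,
    dividers: tuple[float, float],
) -> tuple[float, float]:
    """State-label agreement fraction and Pearson correlation of two series."""
    a = np.asarray(series_a.values, dtype=float)
    b = np.asarray(series_b.values, dtype=float)
    if a.size != b.size:
        raise ArgumentError("series length mismatch")
    la = a > dividers[0]
    lb = b > dividers[1]
    agreement = float((la == lb).mean())
    corr = float(pearsonr(a, b).statistic)
    return agreement, corr
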