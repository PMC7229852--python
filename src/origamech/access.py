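"""Steric accessibility of a restriction endonuclease at origami sites.

The core method: an ideal 10-bp coarse-grained helix is superposed once onto
the crystallographic enzyme-bound duplex, carrying the enzyme's heavy atoms
into the helix frame (the docking template).  For every trajectory frame and
every recognition site, the template helix is superposed onto the site's
10-bp window -- either with the enzyme's engaged strand on the scaffold
strand, or strand-swapped via the duplex pseudo-dyad for the staple side --
and the enzyme atoms are placed accordingly.

Steric scoring uses two distance maps on a (base pair i, azimuth theta) grid
around the site: ``max[i, theta]`` is the farthest placed enzyme particle in
that cell, ``min[i, theta]`` the nearest particle of adjacent (non-site) DNA.
A frame is accessible from a side iff max < min in every cell: the enzyme
envelope fits strictly inside the empty shell around the site.  The
theoretical site accessibility r is the fraction of frames accessible, the r
of the cleavage scheme E + r T_u -> E + T_c.

Distances are measured from each window base-pair center (not a global axis
line), so the rows stay meaningful when the site helix bends; particles
beyond the 10-bp extent are clamped to the end rows so near-window clashes
are still caught; particles are points, matching the comparison of point
distances in the criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .errors import (
    ArgumentError,
    EmptyStructureError,
    SiteSkip,
    UndefinedCorrelationError,
)
from .geometry import (
    BASE_SITE_OFFSET_NM,
    HelixModel,
    LocalFrame,
    RigidTransform,
    estimate_site_frame,
    kabsch_superpose,
)
from .io import Configuration, ParticleCloud, Topology, Trajectory
from .sites import RecognitionSite

DEFAULT_THETA_BINS = 72
DEFAULT_EXCLUSION_MARGIN_BP = 2


# ---------------------------------------------------------------------------
# docking template
# ---------------------------------------------------------------------------


@dataclass
class DockingTemplate:
    """Enzyme heavy atoms expressed in the frame of an ideal 10-bp helix."""

    protein_local: np.ndarray  # (M, 3) nm, helix frame
    helix: HelixModel
    superposition_rmsd: float  # nm, crystal duplex onto ideal helix
    engaged_strand: str = "A"  # template helix strand the enzyme contacts

    @property
    def n_particles(self) -> int:
        return int(self.protein_local.shape[0])


def duplex_anchors(crystal_dna: ParticleCloud, n_bp: int = 10) -> np.ndarray:
    """One anchor point per nucleotide of a crystal duplex, (2*n_bp, 3).

    Anchors are C1' atoms when present (else P, else the residue centroid).
    The first DNA chain is taken 5'->3' by residue number; the second chain
    is paired antiparallel (descending residue number).  If the duplex is
    longer than *n_bp*, the central *n_bp* base pairs are used.
    """
    crystal_dna.validate()
    by_res: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for pos, (chain, resnum, atom) in zip(crystal_dna.positions, crystal_dna.labels):
        by_res.setdefault((chain, resnum), {})[atom] = pos
    chains: dict[str, list[int]] = {}
    for chain, resnum in by_res:
        chains.setdefault(chain, []).append(resnum)
    if len(chains) != 2:
        raise ArgumentError(f"expected a 2-chain duplex, got chains {sorted(chains)}")
    ca, cb = sorted(chains)
    res_a = sorted(chains[ca])
    res_b = sorted(chains[cb], reverse=True)
    if len(res_a) < n_bp or len(res_b) < n_bp:
        raise ArgumentError(f"crystal duplex has fewer than {n_bp} identifiable bp")
    off_a = (len(res_a) - n_bp) // 2
    off_b = (len(res_b) - n_bp) // 2
    res_a = res_a[off_a : off_a + n_bp]
    res_b = res_b[off_b : off_b + n_bp]

    def anchor(chain: str, resnum: int) -> np.ndarray:
        atoms = by_res[(chain, resnum)]
        for name in ("C1'", "C1*", "P"):
            if name in atoms:
                return atoms[name]
        return np.mean(list(atoms.values()), axis=0)

    pts = [anchor(ca, r) for r in res_a] + [anchor(cb, r) for r in res_b]
    return np.asarray(pts)


def build_docking_template(
    protein: ParticleCloud,
    crystal_dna: ParticleCloud,
    helix: HelixModel,
    rmsd_ceiling: float = 0.5,
) -> DockingTemplate:
    """Superpose the crystal duplex onto the ideal helix; carry the enzyme along."""
    protein.validate()
    if helix.n_bp != 10:
        raise ArgumentError("docking helix must have 10 bp")
    crystal_anchors = duplex_anchors(crystal_dna, n_bp=helix.n_bp)
    tf, rmsd = kabsch_superpose(crystal_anchors, helix.anchors())
    if rmsd > rmsd_ceiling:
        warnings.warn(
            f"crystal-duplex superposition rmsd {rmsd:.3f} nm exceeds "
            f"{rmsd_ceiling} nm; check the duplex assignment",
            stacklevel=2,
        )
    return DockingTemplate(
        protein_local=tf.apply(protein.positions),
        helix=helix,
        superposition_rmsd=rmsd,
    )


def probe_template(
    extent: float,
    n_particles: int = 4000,
    offset: float = 0.0,
    seed: int = 0,
    helix: HelixModel | None = None,
) -> DockingTemplate:
    """Docking template with a synthetic spherical probe instead of an enzyme.

    The probe is a uniform ball of radius *extent* centred *offset* nm from
    the helix axis at the window's axial midpoint.  Used by tests and
    known-answer scenes where the enzyme geometry must be analytic.
    """
    from .synth import make_probe_cloud
    from .geometry import build_ideal_helix

    if helix is None:
        helix = build_ideal_helix(10, "AAAGCGCAAA")
    cloud = make_probe_cloud(extent, n_particles, offset=offset, seed=seed)
    mid = helix.bp_centers().mean(0)
    return DockingTemplate(
        protein_local=cloud.positions + mid,
        helix=helix,
        superposition_rmsd=0.0,
    )


# ---------------------------------------------------------------------------
# docking to a site
# ---------------------------------------------------------------------------


def _window_pairs_or_skip(site: RecognitionSite) -> list[tuple[int, int]]:
    pairs = site.window_pairs()
    if len(pairs) != 10:
        raise SiteSkip(f"site {site.site_id}: window is not 10 bp")
    if any(t < 0 for _, t in pairs):
        raise SiteSkip(f"site {site.site_id}: unpaired nucleotide in window")
    return pairs


def dock_to_site(
    template: DockingTemplate,
    config: Configuration,
    site: RecognitionSite,
    side: str,
) -> tuple[np.ndarray, RigidTransform, float]:
    """Place the template enzyme at *site* in one frame.

    side='scaffold' maps the enzyme's engaged helix strand onto the scaffold
    strand; side='staple' applies the strand-swapped correspondence (the
    pseudo-dyad flip of the duplex).  Returns (placed enzyme positions,
    transform, superposition rmsd).
    """
    if side not in ("scaffold", "staple"):
        raise ArgumentError(f"side must be 'scaffold' or 'staple', got {side!r}")
    pairs = _window_pairs_or_skip(site)
    scaf = np.array([s for s, _ in pairs], dtype=np.intp)
    stap = np.array([t for _, t in pairs], dtype=np.intp)
    if side == "scaffold":
        targets = np.vstack([config.positions[scaf], config.positions[stap]])
    else:
        targets = np.vstack(
            [config.positions[stap[::-1]], config.positions[scaf[::-1]]]
        )
    tf, rmsd = kabsch_superpose(template.helix.anchors(), targets)
    return tf.apply(template.protein_local), tf, rmsd


# ---------------------------------------------------------------------------
# distance maps and classification
# ---------------------------------------------------------------------------


@dataclass
class DistanceMaps:
    """Per-cell farthest-enzyme and nearest-environment distances (nm)."""

    max_map: np.ndarray  # (10, n_theta); -inf where no enzyme particle
    min_map: np.ndarray  # (10, n_theta); +inf where no environment particle

    @property
    def n_theta(self) -> int:
        return int(self.max_map.shape[1])


def _assign_cells(
    points: np.ndarray,
    frame: LocalFrame,
    bp_centers: np.ndarray,
    n_theta: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(row, theta bin, distance-from-row-center) for each point."""
    local = frame.to_local(points)
    z = local[:, 2]
    zc = frame.to_local(bp_centers)[:, 2]
    rows = np.abs(z[:, None] - zc[None, :]).argmin(1)  # clamps beyond ends
    theta = np.arctan2(local[:, 1], local[:, 0])
    tbin = np.clip(
        np.floor((theta + np.pi) / (2 * np.pi / n_theta)).astype(np.intp),
        0,
        n_theta - 1,
    )
    dist = np.linalg.norm(points - bp_centers[rows], axis=1)
    return rows, tbin, dist


def distance_maps(
    placed_protein: np.ndarray,
    frame: LocalFrame,
    bp_centers: np.ndarray,
    environment: np.ndarray,
    n_theta: int = DEFAULT_THETA_BINS,
) -> DistanceMaps:
    """Build the max (enzyme) and min (adjacent DNA) distance maps.

    Each particle lands in cell (i, theta): i is the nearest base-pair center
    along the site axis (clamped to the end rows), theta its azimuth in the
    site frame; the distance is Euclidean from that base-pair center.
    """
    placed_protein = np.atleast_2d(placed_protein)
    if placed_protein.shape[0] == 0:
        raise ArgumentError("empty enzyme particle cloud")
    n_bp = bp_centers.shape[0]
    max_map = np.full((n_bp, n_theta), -np.inf)
    min_map = np.full((n_bp, n_theta), np.inf)
    rows, tbin, dist = _assign_cells(placed_protein, frame, bp_centers, n_theta)
    np.maximum.at(max_map, (rows, tbin), dist)
    environment = np.atleast_2d(environment) if environment is not None else None
    if environment is not None and environment.shape[0] > 0:
        rows, tbin, dist = _assign_cells(environment, frame, bp_centers, n_theta)
        np.minimum.at(min_map, (rows, tbin), dist)
    return DistanceMaps(max_map=max_map, min_map=min_map)


def classify_accessible(maps: DistanceMaps) -> bool:
    """Accessible iff max < min in every cell (empty cells never block)."""
    if maps.max_map.shape != maps.min_map.shape:
        raise ArgumentError("distance maps do not share a grid")
    return bool(np.all(maps.max_map < maps.min_map))


# ---------------------------------------------------------------------------
# per-site aggregation over a trajectory
# ---------------------------------------------------------------------------


@dataclass
class AccessibilityResult:
    """Per-frame accessibility booleans and aggregated fractions for one site."""

    site_id: int
    per_frame: dict[str, np.ndarray]  # side -> (T,) bool over scored frames
    fractions: dict[str, float]  # 'scaffold', 'staple', 'both' as requested
    n_frames: int  # frames scored
    n_skipped: int  # frames skipped (unpaired window etc.)


def window_exclusion(
    site: RecognitionSite, topology: Topology, margin_bp: int = DEFAULT_EXCLUSION_MARGIN_BP
) -> set[int]:
    """Window nucleotides plus a strand-link margin: the site's own duplex
    must not count as blocking environment."""
    core = {int(i) for i in site.window_scaffold_indices if i >= 0}
    core |= {int(i) for i in site.window_staple_indices if i >= 0}
    excluded = set(core)
    shell = set(core)
    for _ in range(margin_bp):
        nxt = set()
        for i in shell:
            for j in (int(topology.neighbor_3p[i]), int(topology.neighbor_5p[i])):
                if j != -1 and j not in excluded:
                    nxt.add(j)
        if topology.pairing is not None:
            for i in list(nxt):
                p = int(topology.pairing[i])
                if p != -1 and p not in excluded:
                    nxt.add(p)
        excluded |= nxt
        shell = nxt
    return excluded


def environment_particles(config: Configuration, excluded: set[int]) -> np.ndarray:
    """All oxDNA interaction centres (backbone + base site) outside *excluded*."""
    keep = np.setdiff1d(
        np.arange(config.n_nucleotides), np.fromiter(excluded, dtype=np.intp)
    )
    backbone = config.positions[keep]
    base = backbone + BASE_SITE_OFFSET_NM * config.a1[keep]
    return np.vstack([backbone, base])


def site_accessibility(
    traj: Trajectory,
    site: RecognitionSite,
    template: DockingTemplate,
    sides: tuple[str, ...] = ("scaffold", "staple"),
    n_theta: int = DEFAULT_THETA_BINS,
    exclusion_margin_bp: int = DEFAULT_EXCLUSION_MARGIN_BP,
    reference_nucleotide: int | None = None,
) -> AccessibilityResult:
    """Dock, map and classify every frame; aggregate accessibility fractions.

    Frames where the window cannot be docked (unpaired nucleotides) are
    skipped and counted, not scored inaccessible; fractions are over scored
    frames.  'both' is the fraction of frames accessible from both sides
    simultaneously.
    """
    if len(traj) == 0:
        raise ArgumentError("empty trajectory")
    ref_nt = (
        int(site.scaffold_indices[0])
        if reference_nucleotide is None
        else reference_nucleotide
    )
    flags: dict[str, list[bool]] = {s: [] for s in sides}
    n_skipped = 0
    excluded = window_exclusion(site, traj.topology, exclusion_margin_bp)
    for cfg in traj:
        try:
            pairs = _window_pairs_or_skip(site)
            frame = estimate_site_frame(cfg, pairs, ref_nt)
            env = environment_particles(cfg, excluded)
            frame_flags = {}
            for side in sides:
                placed, tf, _ = dock_to_site(template, cfg, site, side)
                centers = tf.apply(template.helix.bp_centers())
                maps = distance_maps(placed, frame, centers, env, n_theta)
                frame_flags[side] = classify_accessible(maps)
        except SiteSkip:
            n_skipped += 1
            continue
        for side in sides:
            flags[side].append(frame_flags[side])
    n_scored = len(next(iter(flags.values()))) if flags else 0
    if n_scored == 0:
        raise EmptyStructureError(
            f"site {site.site_id}: all {len(traj)} frames skipped"
        )
    per_frame = {s: np.asarray(v, dtype=bool) for s, v in flags.items()}
    fractions = {s: float(v.mean()) for s, v in per_frame.items()}
    if len(sides) >= 2:
        both = np.logical_and.reduce([per_frame[s] for s in sides])
        fractions["both"] = float(both.mean())
    return AccessibilityResult(
        site_id=site.site_id,
        per_frame=per_frame,
        fractions=fractions,
        n_frames=n_scored,
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# local occupancy (neighbour-helix projections)
# ---------------------------------------------------------------------------


@dataclass
class LocalOccupancy:
    """Neighbour-helix centre-of-mass clouds in the site plane, per frame."""

    site_id: int
    neighbor_xy: dict[str, np.ndarray]  # name -> (T, 2) nm in the site frame
    footprint_xy: dict[str, np.ndarray]  # side -> convex hull vertices (K, 2)


def local_occupancy(
    traj: Trajectory,
    site: RecognitionSite,
    neighbors: dict[str, np.ndarray],
    template: DockingTemplate,
    sides: tuple[str, ...] = ("scaffold", "staple"),
    reference_nucleotide: int | None = None,
) -> LocalOccupancy:
    """Project neighbour-helix centres of mass onto the site-perpendicular plane.

    For each frame the site's local frame is re-estimated, each neighbour's
    centre of mass is expressed in it, and the (x, y) in-plane coordinates
    are collected; the enzyme footprint is the projected convex hull of the
    placed enzyme (constant in the site frame, taken from the first scorable
    frame per side).
    """
    from scipy.spatial import ConvexHull

    if not neighbors:
        raise ArgumentError("empty neighbor set")
    ref_nt = (
        int(site.scaffold_indices[0])
        if reference_nucleotide is None
        else reference_nucleotide
    )
    clouds: dict[str, list[np.ndarray]] = {k: [] for k in neighbors}
    footprints: dict[str, np.ndarray] = {}
    for cfg in traj:
        try:
            pairs = _window_pairs_or_skip(site)
            frame = estimate_site_frame(cfg, pairs, ref_nt)
        except SiteSkip:
            continue
        for name, idx in neighbors.items():
            com = cfg.positions[np.asarray(idx, dtype=np.intp)].mean(0)
            clouds[name].append(frame.to_local(com)[0, :2])
        for side in sides:
            if side in footprints:
                continue
            try:
                placed, _, _ = dock_to_site(template, cfg, site, side)
            except SiteSkip:
                continue
            xy = frame.to_local(placed)[:, :2]
            hull = ConvexHull(xy)
            footprints[side] = xy[hull.vertices]
    if not any(clouds.values()):
        raise EmptyStructureError(f"site {site.site_id}: no scorable frames")
    return LocalOccupancy(
        site_id=site.site_id,
        neighbor_xy={k: np.asarray(v) for k, v in clouds.items()},
        footprint_xy=footprints,
    )


# ---------------------------------------------------------------------------
# theory vs experiment
# ---------------------------------------------------------------------------


def correlate_with_experiment(
    theory: dict[int, float],
    experiment: dict[int, float],
    exclude: set[int] = frozenset(),
) -> tuple[float, list[int]]:
    """Pearson correlation between theoretical and experimental accessibility.

    Sites in *exclude* (crossover-overlapping, hence non-substrates) are
    removed first; sites missing an experimental value are dropped and
    reported in the returned list of used site ids.
    """
    used = sorted((set(theory) & set(experiment)) - set(exclude))
    if len(used) < 3:
        raise ArgumentError(f"need >= 3 paired sites, have {len(used)}")
    x = np.array([theory[i] for i in used], dtype=float)
    y = np.array([experiment[i] for i in used], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    r = float(pearsonr(x, y).statistic)
    return r, used
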