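"""Synthetic scene generators: every input class the pipeline needs, offline.

Generators are deterministic given (parameters, seed) and each scene carries
a ground-truth payload sufficient to score downstream results without
re-deriving anything: planted modes and per-frame displacements, analytic
block/clear labels for raft scenes, known pairing tables for duplexes.

What is emulated -- and what is not: duplex scenes are ideal B-form helices
with isotropic Gaussian jitter (no sequence-dependent structure, no
breathing); raft scenes are rigid parallel helices whose inter-helix gap
follows a prescribed per-frame schedule, standing in for the crossover-tied
helix bundles around an origami recognition site; two-state scenes plant a
single collective coordinate sampled from an overdamped Langevin double well
on top of a static structure.  Real origami fluctuations are anharmonic and
correlated across many modes; these scenes isolate one property at a time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ArgumentError
from .geometry import HelixModel, build_ideal_helix
from .io import (
    Configuration,
    DesignMap,
    ParticleCloud,
    Staple,
    Topology,
    Trajectory,
    complement,
    write_oxdna_topology,
    write_oxdna_trajectory,
    write_tsv,
)

_FRAME_SPACING_US = 7.0  # sampling interval stamped on generated frames


@dataclass
class Scene:
    """A generated input set plus the ground truth needed to score it."""

    name: str
    topology: Topology
    trajectory: Trajectory
    design: DesignMap | None
    ground_truth: dict

    def write(self, outdir: str | Path, prefix: str | None = None) -> dict[str, Path]:
        """Write oxDNA files (+ design JSON, ground-truth TSV); return paths."""
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.name
        paths = {
            "topology": outdir / f"{prefix}.top",
            "trajectory": outdir / f"{prefix}.dat",
        }
        write_oxdna_topology(paths["topology"], self.topology)
        write_oxdna_trajectory(paths["trajectory"], self.trajectory)
        if self.design is not None:
            paths["design"] = outdir / f"{prefix}.design.json"
            paths["design"].write_text(design_to_json(self.design))
        gt_rows = {
            k: v
            for k, v in self.ground_truth.items()
            if isinstance(v, np.ndarray) and v.ndim == 1 and v.size == len(self.trajectory)
        }
        if gt_rows:
            paths["ground_truth"] = outdir / f"{prefix}.truth.tsv"
            write_tsv(
                paths["ground_truth"],
                pd.DataFrame({"frame": np.arange(len(self.trajectory)), **gt_rows}),
                metadata={"scene": self.name},
            )
        return paths


# ---------------------------------------------------------------------------
# duplex building blocks
# ---------------------------------------------------------------------------


def duplex_topology(sequence: str) -> Topology:
    """Two-strand duplex topology with a full pairing table.

    Strand 0 (the 'scaffold' strand) holds *sequence* 5'->3' at indices
    0..n-1; strand 1 holds the reverse complement at n..2n-1, also ordered
    5'->3', with pairing[i] = 2n - 1 - i.
    """
    seq = sequence.upper()
    n = len(seq)
    comp = complement(seq)
    bases = np.array(list(seq) + list(comp[::-1]), dtype="U1")
    strand_ids = np.array([0] * n + [1] * n, dtype=np.intp)
    n3 = np.full(2 * n, -1, dtype=np.intp)
    n5 = np.full(2 * n, -1, dtype=np.intp)
    for s in range(2):
        lo = s * n
        n3[lo : lo + n - 1] = np.arange(lo + 1, lo + n)
        n5[lo + 1 : lo + n] = np.arange(lo, lo + n - 1)
    pairing = (2 * n - 1) - np.arange(2 * n, dtype=np.intp)
    topo = Topology(strand_ids, bases, n3, n5, pairing=pairing,
                    circular=np.zeros(2, dtype=bool))
    topo.validate()
    return topo


def duplex_configuration(helix: HelixModel, time: float = 0.0,
                         box: float = 200.0) -> Configuration:
    """Configuration of one duplex laid out in ``duplex_topology`` order."""
    n = helix.n_bp
    pos = np.empty((2 * n, 3))
    a1 = np.empty((2 * n, 3))
    a3 = np.empty((2 * n, 3))
    pos[:n] = helix.pos_a
    a1[:n] = helix.a1_a
    a3[:n] = helix.a3_a
    # strand B 5'->3' runs antiparallel: topology index n+j holds bp n-1-j
    rev = np.arange(n)[::-1]
    pos[n:] = helix.pos_b[rev]
    a1[n:] = helix.a1_b[rev]
    a3[n:] = helix.a3_b[rev]
    return Configuration(time=time, box=np.full(3, box), positions=pos, a1=a1, a3=a3)


def _duplex_design(sequence: str, helix_num: int = 0) -> DesignMap:
    n = len(sequence)
    path = [(helix_num, i) for i in range(n)]
    return DesignMap(
        scaffold_path=path,
        scaffold_sequence=sequence.upper(),
        staples=[Staple(path=list(path))],
        crossovers=[],
        scaffold_topology_indices=np.arange(n, dtype=np.intp),
        staple_topology_indices=(2 * n - 1) - np.arange(n, dtype=np.intp),
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_duplex_scene(
    sequence: str = "AAAGCGCAAA",
    rise: float | None = None,
    twist: float | None = None,
    jitter: float = 0.0,
    n_frames: int = 3,
    seed: int = 0,
) -> Scene:
    """Isolated ideal duplex with per-frame isotropic Gaussian jitter."""
    if len(sequence) < 10:
        raise ArgumentError("sequence length must be >= 10")
    if jitter < 0:
        raise ArgumentError("jitter sigma must be nonnegative")
    kwargs = {}
    if rise is not None:
        kwargs["rise"] = rise
    if twist is not None:
        kwargs["twist"] = twist
    helix = build_ideal_helix(len(sequence), sequence, **kwargs)
    topo = duplex_topology(sequence)
    base = duplex_configuration(helix)
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(n_frames):
        noise = rng.normal(0.0, jitter, base.positions.shape) if jitter > 0 else 0.0
        frames.append(
            Configuration(
                time=(t + 1) * _FRAME_SPACING_US,
                box=base.box.copy(),
                positions=base.positions + noise,
                a1=base.a1.copy(),
                a3=base.a3.copy(),
            )
        )
    traj = Trajectory(topology=topo, frames=frames)
    return Scene(
        name="duplex",
        topology=topo,
        trajectory=traj,
        design=_duplex_design(sequence),
        ground_truth={
            "jitter_sigma": jitter,
            "base_positions": base.positions.copy(),
            "pairing": topo.pairing.copy(),
            "seed": seed,
        },
    )


def make_raft_scene(
    n_helices: int = 3,
    helix_len_bp: int = 14,
    gap_schedule: Sequence[float] = (10.0,),
    motif: str = "GCGC",
    probe_extent: float = 3.0,
    seed: int = 0,
    helix_radius: float = 1.0,
    env_particle_radius: float = 0.6,
) -> Scene:
    """Planar raft: a motif-bearing central duplex flanked by parallel duplexes.

    The inter-helix gap (surface-to-surface, assuming *helix_radius* nm
    radius) follows *gap_schedule* per frame exactly; helices are rigid rods,
    so for a probe of radial extent *probe_extent* the block/clear label per
    frame is analytic: a frame is clear iff the neighbour axis distance
    (gap + 2*helix_radius) minus the environment-particle radius is at least
    the probe extent.  Labels are stored in the ground truth.

    The central helix defaults to 14 bp so that the 10-bp docking window
    plus the 2-bp exclusion margin covers it completely: a recognition
    site's own duplex must not count as blocking environment.
    """
    if n_helices < 2:
        raise ArgumentError("need at least 2 helices")
    gaps = np.asarray(gap_schedule, dtype=float)
    if (gaps < 0).any():
        raise ArgumentError("gaps must be nonnegative")
    n_frames = gaps.size
    flank = (helix_len_bp - len(motif)) // 2
    seq = ("A" * flank + motif + "A" * (helix_len_bp - len(motif) - flank)).upper()
    neighbor_seq = "T" * helix_len_bp

    helix = build_ideal_helix(helix_len_bp, seq)
    nbr_helix = build_ideal_helix(helix_len_bp, neighbor_seq)

    # topology: central duplex first, then neighbours
    topos = [duplex_topology(seq)] + [
        duplex_topology(neighbor_seq) for _ in range(n_helices - 1)
    ]
    strand_ids = []
    bases = []
    n3 = []
    n5 = []
    pairing = []
    offset = 0
    strand_off = 0
    for tp in topos:
        strand_ids.append(tp.strand_ids + strand_off)
        bases.append(tp.bases)
        shift = np.where(tp.neighbor_3p >= 0, offset, 0)
        n3.append(tp.neighbor_3p + shift)
        shift = np.where(tp.neighbor_5p >= 0, offset, 0)
        n5.append(tp.neighbor_5p + shift)
        pairing.append(tp.pairing + offset)
        offset += tp.n_nucleotides
        strand_off += tp.n_strands
    topo = Topology(
        np.concatenate(strand_ids),
        np.concatenate(bases),
        np.concatenate(n3),
        np.concatenate(n5),
        pairing=np.concatenate(pairing),
        circular=np.zeros(strand_off, dtype=bool),
    )
    topo.validate()

    central = duplex_configuration(helix)
    nbr_base = duplex_configuration(nbr_helix)
    # neighbour slots: +x, -x, +2x, -2x, ...
    slots = []
    for k in range(1, n_helices):
        m = (k + 1) // 2
        slots.append(m if k % 2 == 1 else -m)

    frames = []
    for t, gap in enumerate(gaps):
        axis_sep = gap + 2.0 * helix_radius
        parts_pos = [central.positions]
        parts_a1 = [central.a1]
        parts_a3 = [central.a3]
        for slot in slots:
            shift = np.array([slot * axis_sep, 0.0, 0.0])
            parts_pos.append(nbr_base.positions + shift)
            parts_a1.append(nbr_base.a1)
            parts_a3.append(nbr_base.a3)
        frames.append(
            Configuration(
                time=(t + 1) * _FRAME_SPACING_US,
                box=np.full(3, 500.0),
                positions=np.vstack(parts_pos),
                a1=np.vstack(parts_a1),
                a3=np.vstack(parts_a3),
            )
        )
    traj = Trajectory(topology=topo, frames=frames)
    clear = (gaps + 2.0 * helix_radius - env_particle_radius) >= probe_extent
    n_bp2 = 2 * helix_len_bp
    neighbors = {
        f"neighbor_{i}": np.arange(n_bp2 * (i + 1), n_bp2 * (i + 2))
        for i in range(n_helices - 1)
    }
    return Scene(
        name="raft",
        topology=topo,
        trajectory=traj,
        design=_duplex_design(seq),
        ground_truth={
            "clear": clear,
            "gap_nm": gaps.copy(),
            "probe_extent": probe_extent,
            "neighbor_indices": neighbors,
            "rule": "clear iff gap + 2*helix_radius - env_particle_radius >= probe_extent",
            "seed": seed,
        },
    )


def simulate_double_well(
    n_frames: int,
    barrier: float = 3.0,
    minimum: float = 2.0,
    seed: int = 0,
    dt: float = 0.005,
    stride: int = 30,
    tilt: float = 0.0,
    s0: float | None = None,
) -> np.ndarray:
    """Overdamped Langevin samples from U(s) = B ((s^2-a^2)/a^2)^2 + tilt*s.

    Euler-Maruyama with k_BT = 1; *barrier* B is the height of U at s=0
    relative to the minima (for tilt=0), *minimum* a their position (nm).
    The step dt is small against the stiffest well curvature (8B/a^2) so the
    discretization bias in well populations stays below the percent level;
    one sample is recorded every *stride* steps, about one intra-well
    relaxation time (a^2/8B per unit friction), so recorded frames are
    roughly independent within a well.
    """
    if barrier <= 0:
        raise ArgumentError("barrier must be positive")
    a = float(minimum)
    b = float(barrier)
    rng = np.random.default_rng(seed)
    s = a if s0 is None else float(s0)
    out = np.empty(n_frames)
    sq2dt = np.sqrt(2.0 * dt)
    noise = rng.standard_normal(n_frames * stride)
    k = 0
    for i in range(n_frames):
        for _ in range(stride):
            force = -4.0 * b * s * (s * s - a * a) / a**4 - tilt
            s = s + force * dt + sq2dt * noise[k]
            k += 1
        out[i] = s
    return out


def random_internal_mode(base_positions: np.ndarray, seed: int = 0) -> np.ndarray:
    """Random unit 3N vector orthogonal to the six rigid-body directions.

    Removing net translation and rotation keeps a planted displacement from
    being absorbed by trajectory superposition.
    """
    pos = np.asarray(base_positions, dtype=float)
    n = pos.shape[0]
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(3 * n)
    basis = []
    for ax in range(3):  # translations
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis.append(t.ravel())
    centered = pos - pos.mean(0)
    for ax in range(3):  # infinitesimal rotations about the centroid
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(e, centered).ravel())
    q, _ = np.linalg.qr(np.stack(basis, axis=1))
    v = v - q @ (q.T @ v)
    return v / np.linalg.norm(v)


def make_two_state_trajectory(
    base: Configuration,
    topology: Topology,
    mode: np.ndarray,
    barrier: float = 3.0,
    minimum: float = 2.0,
    noise_sigma: float = 0.0,
    n_frames: int = 1000,
    seed: int = 0,
    dt: float = 0.005,
    stride: int = 30,
) -> tuple[Trajectory, dict]:
    """Trajectory hopping between two states along a planted mode.

    Frames are base + a_t * mode + isotropic Gaussian noise, with a_t from
    :func:`simulate_double_well`.  Ground truth stores a_t, state labels and
    the generating potential.
    """
    mode = np.asarray(mode, dtype=float)
    if abs(np.linalg.norm(mode) - 1.0) > 1e-8:
        raise ArgumentError("mode must be unit-norm")
    if mode.size != base.positions.size:
        raise ArgumentError("mode dimension must be 3N of the base structure")
    a_t = simulate_double_well(
        n_frames, barrier=barrier, minimum=minimum, seed=seed, dt=dt, stride=stride
    )
    rng = np.random.default_rng(seed + 1)
    disp = mode.reshape(-1, 3)
    frames = []
    for t in range(n_frames):
        noise = (
            rng.normal(0.0, noise_sigma, base.positions.shape)
            if noise_sigma > 0
            else 0.0
        )
        frames.append(
            Configuration(
                time=(t + 1) * _FRAME_SPACING_US,
                box=base.box.copy(),
                positions=base.positions + a_t[t] * disp + noise,
                a1=base.a1.copy(),
                a3=base.a3.copy(),
            )
        )
    traj = Trajectory(topology=topology, frames=frames)
    truth = {
        "a": a_t,
        "labels": (a_t > 0).astype(np.int8),
        "barrier": barrier,
        "minima": (-minimum, minimum),
        "mode": mode.copy(),
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return traj, truth


def make_probe_cloud(
    extent: float,
    n_particles: int,
    offset: float = 0.0,
    seed: int = 0,
) -> ParticleCloud:
    """Uniform ball of radius *extent* centred *offset* nm from the origin
    along +x; maximal distance from the axis is extent + offset."""
    if extent <= 0:
        raise ArgumentError("extent must be positive")
    if n_particles < 1:
        raise ArgumentError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n_particles, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = extent * rng.random(n_particles) ** (1.0 / 3.0)
    pos = d * r[:, None] + np.array([offset, 0.0, 0.0])
    labels = [("P", i + 1, "CA") for i in range(n_particles)]
    return ParticleCloud(positions=pos, labels=labels, role="protein")


# ---------------------------------------------------------------------------
# toy file fixtures (cadnano JSON, PDB text)
# ---------------------------------------------------------------------------


def make_toy_cadnano(length: int = 32) -> dict:
    """Minimal valid square-lattice cadnano dict: 2 helices, 2 staples.

    The scaffold enters helix 0 at position 0, runs to position length/2-1,
    crosses to helix 1 and runs back.  Two staples tile the complement, each
    with one crossover; the staple crossover positions are at helix
    positions length/4 and 0.
    """
    if length % 32 != 0:
        raise ArgumentError("square-lattice cadnano length must be a multiple of 32")
    half = length // 2
    empty = [[-1, -1, -1, -1] for _ in range(length)]

    def cell(p5, p3):
        return [p5[0], p5[1], p3[0], p3[1]]

    scaf0 = [list(c) for c in empty]
    scaf1 = [list(c) for c in empty]
    for i in range(half):
        p5 = (-1, -1) if i == 0 else (0, i - 1)
        p3 = (1, half - 1) if i == half - 1 else (0, i + 1)
        scaf0[i] = cell(p5, p3)
    for i in range(half - 1, -1, -1):
        p5 = (0, half - 1) if i == half - 1 else (1, i + 1)
        p3 = (-1, -1) if i == 0 else (1, i - 1)
        scaf1[i] = cell(p5, p3)

    stap0 = [list(c) for c in empty]
    stap1 = [list(c) for c in empty]
    q = half // 2
    # staple 1: helix0 half-1 .. q, cross to helix1 q .. half-1
    for i in range(half - 1, q - 1, -1):
        p5 = (-1, -1) if i == half - 1 else (0, i + 1)
        p3 = (1, q) if i == q else (0, i - 1)
        stap0[i] = cell(p5, p3)
    for i in range(q, half):
        p5 = (0, q) if i == q else (1, i - 1)
        p3 = (-1, -1) if i == half - 1 else (1, i + 1)
        stap1[i] = cell(p5, p3)
    # staple 2: helix0 q-1 .. 0, cross to helix1 0 .. q-1
    for i in range(q - 1, -1, -1):
        p5 = (-1, -1) if i == q - 1 else (0, i + 1)
        p3 = (1, 0) if i == 0 else (0, i - 1)
        stap0[i] = cell(p5, p3)
    for i in range(0, q):
        p5 = (0, 0) if i == 0 else (1, i - 1)
        p3 = (-1, -1) if i == q - 1 else (1, i + 1)
        stap1[i] = cell(p5, p3)

    def vs(num, row, scaf, stap):
        return {
            "num": num,
            "row": row,
            "col": 0,
            "scaf": scaf,
            "stap": stap,
            "skip": [0] * length,
            "loop": [0] * length,
            "stap_colors": [],
        }

    return {"name": "toy", "vstrands": [vs(0, 0, scaf0, stap0), vs(1, 1, scaf1, stap1)]}


def write_synthetic_complex_pdb(
    path: str | Path,
    helix: HelixModel,
    protein_positions: np.ndarray,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> None:
    """Write a synthetic protein-DNA complex PDB (labelled synthetic).

    Chain A carries the 'protein' as ALA CA atoms; chains B and C carry the
    duplex as one C1' pseudo-atom per nucleotide placed at the helix anchor
    points.  An optional rigid motion is applied to everything, emulating an
    arbitrarily oriented crystal structure.  Coordinates are written in
    angstroms (nm * 10).
    """
    r = np.eye(3) if rotation is None else rotation
    t = np.zeros(3) if translation is None else translation
    prot = np.asarray(protein_positions) @ r.T + t
    anch = helix.anchors() @ r.T + t
    n = helix.n_bp
    lines = ["REMARK   1 SYNTHETIC protein-DNA complex fixture"]
    serial = 1

    def atom_line(serial, name, resname, chain, resnum, xyz):
        x, y, z = (c * 10.0 for c in xyz)  # nm -> angstrom
        return (
            f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]}"
        )

    for i, p in enumerate(prot):
        lines.append(atom_line(serial, "CA", "ALA", "A", i + 1, p))
        serial += 1
    comp = {"A": "DT", "T": "DA", "C": "DG", "G": "DC"}
    for i in range(n):  # strand A: chain B, residues 1..n (5'->3')
        resname = "D" + helix.sequence[i]
        lines.append(atom_line(serial, "C1'", resname, "B", i + 1, anch[i]))
        serial += 1
    for j in range(n):  # strand B: chain C, residues 1..n 5'->3' = bp n-1..0
        bp = n - 1 - j
        resname = comp[helix.sequence[bp]]
        lines.append(atom_line(serial, "C1'", resname, "C", j + 1, anch[n + bp]))
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DesignMap (de)serialization -- package-native JSON schema
# ---------------------------------------------------------------------------


def design_to_json(design: DesignMap) -> str:
    return json.dumps(
        {
            "scaffold_path": [list(p) for p in design.scaffold_path],
            "scaffold_sequence": design.scaffold_sequence,
            "staples": [
                {"path": [list(p) for p in s.path], "omitted": s.omitted}
                for s in design.staples
            ],
            "crossovers": [list(c) for c in design.crossovers],
            "omitted_staples": sorted(design.omitted_staples),
            "scaffold_topology_indices": (
                None
                if design.scaffold_topology_indices is None
                else [int(i) for i in design.scaffold_topology_indices]
            ),
            "staple_topology_indices": (
                None
                if design.staple_topology_indices is None
                else [int(i) for i in design.staple_topology_indices]
            ),
        },
        indent=1,
    )


def design_from_json(text: str) -> DesignMap:
    d = json.loads(text)
    idx = d.get("scaffold_topology_indices")
    sidx = d.get("staple_topology_indices")
    return DesignMap(
        scaffold_path=[tuple(p) for p in d["scaffold_path"]],
        scaffold_sequence=d["scaffold_sequence"],
        staples=[
            Staple(path=[tuple(p) for p in s["path"]], omitted=s.get("omitted", False))
            for s in d.get("staples", [])
        ],
        crossovers=[tuple(c) for c in d.get("crossovers", [])],
        omitted_staples=set(d.get("omitted_staples", [])),
        scaffold_topology_indices=None if idx is None else np.asarray(idx, dtype=np.intp),
        staple_topology_indices=None if sidx is None else np.asarray(sidx, dtype=np.intp),
    )
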