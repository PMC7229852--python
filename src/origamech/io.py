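"""Readers and writers for the file formats the pipeline touches.

Covers the plain-text oxDNA topology and configuration/trajectory formats,
PDB structures of protein-DNA complexes (via gemmi), cadnano JSON designs
(square lattice), and tabular TSV outputs.

Units: all coordinates are exposed in nanometres.  oxDNA length units are
converted at read time (1 oxDNA unit = 0.8518 nm) and back at write time;
versors are dimensionless and never scaled.  Configuration timestamps are
exposed in microseconds using the coarse-grained time mapping
(tau_LJ = 0.7 ns per intrinsic unit), stored as metadata only -- no analysis
depends on the time scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    ArgumentError,
    ConsistencyError,
    EmptyStructureError,
    FormatError,
)

#: nanometres per oxDNA length unit
NM_PER_OXDNA_UNIT = 0.8518
#: nanoseconds per intrinsic (Lennard-Jones) time unit
TAU_LJ_NS = 0.7
#: microseconds per oxDNA time unit (metadata only)
US_PER_OXDNA_TIME = TAU_LJ_NS * 1e-3

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PROTEIN_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL "
    "MSE SEC PYL".split()
)
DNA_RESIDUES = frozenset("DA DC DG DT DI DU A C G T U".split())


def complement(seq: str) -> str:
    """Watson-Crick complement of *seq* (same orientation, not reversed)."""
    try:
        return "".join(_COMPLEMENT[b] for b in seq)
    except KeyError as exc:
        raise ArgumentError(f"non-ACGT base in sequence: {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# oxDNA topology
# ---------------------------------------------------------------------------


@dataclass
class Topology:
    """Connectivity of an oxDNA system.

    Per-nucleotide arrays are indexed 0-based.  ``neighbor_3p[i]`` /
    ``neighbor_5p[i]`` give the index of i's 3'- / 5'-neighbour, or -1.
    ``pairing``, when present, maps each nucleotide to its Watson-Crick
    partner (-1 for unpaired); it comes from the design, not the topology
    file, which carries no pairing information.
    """

    strand_ids: np.ndarray  # (N,) int, 0-based
    bases: np.ndarray  # (N,) unicode 'A'|'C'|'G'|'T'
    neighbor_3p: np.ndarray  # (N,) int, -1 = none
    neighbor_5p: np.ndarray  # (N,) int, -1 = none
    pairing: np.ndarray | None = None  # (N,) int, -1 = unpaired
    circular: np.ndarray | None = None  # (n_strands,) bool

    @property
    def n_nucleotides(self) -> int:
        return int(self.strand_ids.size)

    @property
    def n_strands(self) -> int:
        return int(self.strand_ids.max()) + 1 if self.strand_ids.size else 0

    def strand_nucleotides(self, strand: int) -> np.ndarray:
        """Indices of one strand ordered 5' -> 3'."""
        members = np.flatnonzero(self.strand_ids == strand)
        if members.size == 0:
            raise ArgumentError(f"no such strand: {strand}")
        starts = [i for i in members if self.neighbor_5p[i] == -1]
        start = starts[0] if starts else members[0]  # circular: arbitrary start
        order = [start]
        seen = {start}
        while True:
            nxt = int(self.neighbor_3p[order[-1]])
            if nxt == -1 or nxt in seen:
                break
            order.append(nxt)
            seen.add(nxt)
        if len(order) != members.size:
            raise ConsistencyError(
                f"strand {strand} is not contiguous along neighbor links"
            )
        return np.asarray(order, dtype=np.intp)

    def validate(self) -> None:
        n = self.n_nucleotides
        for name, arr in (("3p", self.neighbor_3p), ("5p", self.neighbor_5p)):
            bad = (arr != -1) & ((arr < 0) | (arr >= n))
            if bad.any():
                raise ConsistencyError(
                    f"dangling {name} neighbor index at nucleotide {int(np.flatnonzero(bad)[0])}"
                )
        for i in range(n):
            j = int(self.neighbor_3p[i])
            if j != -1 and int(self.neighbor_5p[j]) != i:
                raise ConsistencyError(f"non-mutual neighbor link {i} -> {j}")
        if self.pairing is not None:
            p = self.pairing
            for i in range(n):
                j = int(p[i])
                if j == -1:
                    continue
                if int(p[j]) != i:
                    raise ConsistencyError(f"pairing not an involution at {i}")
                if _COMPLEMENT[str(self.bases[i])] != str(self.bases[j]):
                    raise ConsistencyError(f"non-complementary pairing {i}-{j}")


def read_oxdna_topology(path: str | Path) -> Topology:
    """Parse a classic oxDNA topology file (``N Nstrands`` header)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty topology file")
    header = lines[0].split()
    if len(header) < 2:
        raise FormatError(f"{path}:1: expected 'N Nstrands' header")
    try:
        n, n_strands = int(header[0]), int(header[1])
    except ValueError:
        raise FormatError(f"{path}:1: non-integer counts in header") from None
    body = [ln for ln in lines[1:] if ln.strip()]
    if len(body) != n:
        raise ConsistencyError(
            f"{path}: header declares {n} nucleotides but file has {len(body)} records"
        )
    strand_ids = np.empty(n, dtype=np.intp)
    bases = np.empty(n, dtype="U1")
    n3 = np.empty(n, dtype=np.intp)
    n5 = np.empty(n, dtype=np.intp)
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{i + 2}: expected 4 fields, got {len(parts)}")
        try:
            strand_ids[i] = int(parts[0]) - 1  # file is 1-based
            n3[i] = int(parts[2])
            n5[i] = int(parts[3])
        except ValueError:
            raise FormatError(f"{path}:{i + 2}: non-integer field") from None
        base = parts[1].upper()
        if base not in _COMPLEMENT:
            raise FormatError(f"{path}:{i + 2}: unknown base {parts[1]!r}")
        bases[i] = base
    topo = Topology(strand_ids, bases, n3, n5)
    if topo.n_strands != n_strands:
        raise ConsistencyError(
            f"{path}: header declares {n_strands} strands, records imply {topo.n_strands}"
        )
    topo.validate()
    # circularity: strand with no 5' terminus
    circ = np.zeros(topo.n_strands, dtype=bool)
    for s in range(topo.n_strands):
        members = np.flatnonzero(strand_ids == s)
        circ[s] = not any(n5[i] == -1 for i in members)
    topo.circular = circ
    return topo


def write_oxdna_topology(path: str | Path, topology: Topology) -> None:
    """Write the classic oxDNA topology dialect (strand lines 3' -> 5')."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{topology.n_nucleotides} {topology.n_strands}\n")
        for i in range(topology.n_nucleotides):
            fh.write(
                f"{int(topology.strand_ids[i]) + 1} {topology.bases[i]} "
                f"{int(topology.neighbor_3p[i])} {int(topology.neighbor_5p[i])}\n"
            )


# ---------------------------------------------------------------------------
# oxDNA configuration / trajectory
# ---------------------------------------------------------------------------


@dataclass
class Configuration:
    """One trajectory frame: positions (nm) and orientation versors."""

    time: float  # microseconds
    box: np.ndarray  # (3,) nm
    positions: np.ndarray  # (N, 3) nm
    a1: np.ndarray  # (N, 3) backbone->base versor
    a3: np.ndarray  # (N, 3) base-normal versor

    @property
    def n_nucleotides(self) -> int:
        return int(self.positions.shape[0])

    def validate(self, topology: Topology | None = None) -> None:
        if topology is not None and self.n_nucleotides != topology.n_nucleotides:
            raise ConsistencyError(
                f"configuration has {self.n_nucleotides} records, topology "
                f"{topology.n_nucleotides}"
            )
        for name, v in (("a1", self.a1), ("a3", self.a3)):
            norms = np.linalg.norm(v, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ConsistencyError(f"{name} versors not unit norm")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Configuration":
        """Return a copy under the rigid motion x -> R x + t (versors rotated)."""
        return Configuration(
            time=self.time,
            box=self.box.copy(),
            positions=self.positions @ rotation.T + translation,
            a1=self.a1 @ rotation.T,
            a3=self.a3 @ rotation.T,
        )


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    topology: Topology
    frames: list[Configuration]
    nm_per_unit: float = NM_PER_OXDNA_UNIT

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Configuration]:
        return iter(self.frames)

    def __getitem__(self, i) -> Configuration:
        return self.frames[i]

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def validate(self) -> None:
        for f in self.frames:
            f.validate(self.topology)
        ts = self.timestamps
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ConsistencyError("timestamps not strictly increasing")


def iter_oxdna_configurations(
    path: str | Path,
    topology: Topology,
    nm_per_unit: float = NM_PER_OXDNA_UNIT,
) -> Iterator[Configuration]:
    """Stream frames from a concatenated oxDNA configuration file.

    Frames are yielded in file order; the whole file is never held resident.
    Positions are multiplied by *nm_per_unit*; versors are left unscaled.
    """
    path = Path(path)
    n = topology.n_nucleotides
    with path.open() as fh:
        ordinal = 0
        while True:
            header = fh.readline()
            if not header:
                return
            if not header.strip():
                continue
            ordinal += 1
            if not header.lstrip().startswith("t"):
                raise FormatError(
                    f"{path}: frame {ordinal}: expected 't = ...' header, got {header.strip()!r}"
                )
            t_raw = float(header.split("=")[1])
            b_line = fh.readline()
            if not b_line.lstrip().startswith("b"):
                raise FormatError(f"{path}: frame {ordinal}: missing box line")
            box = np.array([float(x) for x in b_line.split("=")[1].split()])
            e_line = fh.readline()
            if not e_line.lstrip().startswith("E"):
                raise FormatError(f"{path}: frame {ordinal}: missing energy line")
            pos = np.empty((n, 3))
            a1 = np.empty((n, 3))
            a3 = np.empty((n, 3))
            for i in range(n):
                ln = fh.readline()
                if not ln or ln.lstrip().startswith("t"):
                    raise FormatError(
                        f"{path}: frame {ordinal}: truncated, expected {n} records, got {i}"
                    )
                vals = ln.split()
                if len(vals) < 9:
                    raise FormatError(
                        f"{path}: frame {ordinal}: record {i} has {len(vals)} fields (< 9)"
                    )
                row = [float(v) for v in vals[:9]]
                pos[i] = row[0:3]
                a1[i] = row[3:6]
                a3[i] = row[6:9]
            yield Configuration(
                time=t_raw * US_PER_OXDNA_TIME,
                box=box * nm_per_unit,
                positions=pos * nm_per_unit,
                a1=a1,
                a3=a3,
            )


def read_oxdna_trajectory(
    path: str | Path,
    topology: Topology,
    nm_per_unit: float = NM_PER_OXDNA_UNIT,
) -> Trajectory:
    """Read a whole trajectory into memory (see :func:`iter_oxdna_configurations`)."""
    frames = list(iter_oxdna_configurations(path, topology, nm_per_unit))
    traj = Trajectory(topology=topology, frames=frames, nm_per_unit=nm_per_unit)
    traj.validate()
    return traj


def write_oxdna_trajectory(
    path: str | Path,
    trajectory: Trajectory | Iterable[Configuration],
    nm_per_unit: float = NM_PER_OXDNA_UNIT,
) -> None:
    """Write frames as concatenated oxDNA configuration blocks."""
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else trajectory
    inv = 1.0 / nm_per_unit
    with Path(path).open("w") as fh:
        for cfg in frames:
            t_raw = cfg.time / US_PER_OXDNA_TIME
            bx = cfg.box * inv
            fh.write(f"t = {t_raw:.10g}\n")
            fh.write(f"b = {bx[0]:.10g} {bx[1]:.10g} {bx[2]:.10g}\n")
            fh.write("E = 0 0 0\n")
            pos = cfg.positions * inv
            for i in range(cfg.n_nucleotides):
                p, u, v = pos[i], cfg.a1[i], cfg.a3[i]
                fh.write(
                    f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g} "
                    f"{u[0]:.12g} {u[1]:.12g} {u[2]:.12g} "
                    f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g} 0 0 0 0 0 0\n"
                )


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


@dataclass
class ParticleCloud:
    """A bag of labelled point particles (positions in nm)."""

    positions: np.ndarray  # (M, 3) nm
    labels: list[tuple[str, int, str]]  # (chain, residue number, atom name)
    role: str  # 'protein' | 'dna'

    @property
    def n_particles(self) -> int:
        return int(self.positions.shape[0])

    def validate(self) -> None:
        if self.n_particles == 0:
            raise EmptyStructureError("empty particle cloud")
        if not np.isfinite(self.positions).all():
            raise ConsistencyError("non-finite coordinates in particle cloud")


def read_pdb_particles(
    path: str | Path,
    chain_filter: set[str] | None = None,
    include_dna: bool = True,
) -> tuple[ParticleCloud, ParticleCloud]:
    """Split a protein-DNA complex into (protein, dna) heavy-atom clouds.

    Hydrogens are dropped, only the first alternate location is kept, waters
    and unrecognized heteroatoms are excluded, and coordinates are converted
    from angstroms to nm.
    """
    import gemmi

    st = gemmi.read_pdb(str(Path(path)))
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()
    prot_pos: list[list[float]] = []
    prot_lab: list[tuple[str, int, str]] = []
    dna_pos: list[list[float]] = []
    dna_lab: list[tuple[str, int, str]] = []
    unknown: set[str] = set()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            rname = res.name.strip().upper()
            if rname in PROTEIN_RESIDUES:
                dest_pos, dest_lab = prot_pos, prot_lab
            elif rname in DNA_RESIDUES:
                if not include_dna:
                    continue
                dest_pos, dest_lab = dna_pos, dna_lab
            else:
                unknown.add(rname)
                continue
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                dest_pos.append([atom.pos.x / 10.0, atom.pos.y / 10.0, atom.pos.z / 10.0])
                dest_lab.append((chain.name, res.seqid.num, atom.name))
    if unknown:
        warnings.warn(f"excluded unknown residues: {sorted(unknown)}", stacklevel=2)
    if not prot_pos and not dna_pos:
        raise EmptyStructureError(f"{path}: no ATOM records after filtering")
    protein = ParticleCloud(np.array(prot_pos).reshape(-1, 3), prot_lab, "protein")
    dna = ParticleCloud(np.array(dna_pos).reshape(-1, 3), dna_lab, "dna")
    return protein, dna


# ---------------------------------------------------------------------------
# cadnano JSON
# ---------------------------------------------------------------------------


@dataclass
class Staple:
    """One staple: ordered (helix, position) path, 5' -> 3'."""

    path: list[tuple[int, int]]
    omitted: bool = False


@dataclass
class DesignMap:
    """Routing/crossover/sequence annotation of an origami design.

    ``scaffold_path`` is ordered 5' -> 3'; ``scaffold_sequence`` is threaded
    along it.  ``crossovers`` holds (helix, base position, kind) with kind in
    {'scaffold', 'staple'}.  ``scaffold_topology_indices`` optionally maps
    path positions to nucleotide indices of an accompanying Topology.
    """

    scaffold_path: list[tuple[int, int]]
    scaffold_sequence: str
    staples: list[Staple] = field(default_factory=list)
    crossovers: list[tuple[int, int, str]] = field(default_factory=list)
    omitted_staples: set[int] = field(default_factory=set)
    scaffold_topology_indices: np.ndarray | None = None
    #: topology index of the staple nucleotide paired with each scaffold-path
    #: position (-1 = unpaired); the design is the authority on pairing
    staple_topology_indices: np.ndarray | None = None

    @property
    def n_scaffold(self) -> int:
        return len(self.scaffold_path)

    def paired_mask(self) -> np.ndarray:
        """Boolean per scaffold-path position: covered by a non-omitted staple."""
        covered = set()
        for k, stp in enumerate(self.staples):
            if stp.omitted or k in self.omitted_staples:
                continue
            covered.update(stp.path)
        return np.array([pos in covered for pos in self.scaffold_path], dtype=bool)


def _walk_cadnano(vstrands: list[dict], kind: str, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Follow a cadnano linked list from *start* over its 3' pointers."""
    by_num = {v["num"]: v for v in vstrands}
    path = [start]
    seen = {start}
    helix, idx = start
    while True:
        cell = by_num[helix][kind][idx]
        nh, ni = int(cell[2]), int(cell[3])
        if nh == -1:
            break
        nxt = (nh, ni)
        if nxt in seen:
            break  # circular
        path.append(nxt)
        seen.add(nxt)
        helix, idx = nxt
    return path


def read_cadnano_design(path: str | Path, scaffold_sequence: str) -> DesignMap:
    """Recover routing, crossovers and threaded sequence from a cadnano JSON.

    Square-lattice dialect only; honeycomb designs are rejected.  3D
    coordinates are not built here (that is an external converter's job).
    """
    data = json.loads(Path(path).read_text())
    vstrands = data.get("vstrands")
    if not vstrands:
        raise FormatError(f"{path}: no 'vstrands' in cadnano JSON")
    # square lattice check: cadnano2 square files have skip/loop arrays and
    # helices arranged on a square grid; honeycomb rows use col%3 phase. The
    # reliable dialect marker is the per-helix 'row'/'col' parity convention:
    # honeycomb files have (row+col) parity controlling scaffold direction with
    # 21-cell repeats; square files use 32-cell repeats (len % 32 == 0).
    length = len(vstrands[0]["scaf"])
    if length % 32 != 0 and length % 21 == 0:
        raise FormatError(f"{path}: honeycomb-lattice cadnano design not supported")

    by_num = {v["num"]: v for v in vstrands}
    # scaffold 5' ends: cells with no 5' neighbour but a 3' neighbour
    starts = []
    occupied = []
    for v in vstrands:
        for idx, cell in enumerate(v["scaf"]):
            p5 = (int(cell[0]), int(cell[1]))
            p3 = (int(cell[2]), int(cell[3]))
            if p5 == (-1, -1) and p3 != (-1, -1):
                starts.append((v["num"], idx))
            if p5 != (-1, -1) or p3 != (-1, -1):
                occupied.append((v["num"], idx))
    if starts:
        start = starts[0]
    elif occupied:
        start = occupied[0]  # circular scaffold
    else:
        raise FormatError(f"{path}: no scaffold routing found")
    scaffold_path = _walk_cadnano(vstrands, "scaf", start)
    if len(scaffold_path) != len(set(occupied)):
        raise ConsistencyError(
            f"{path}: scaffold path is disconnected "
            f"({len(scaffold_path)} of {len(set(occupied))} cells reached)"
        )
    if len(scaffold_sequence) < len(scaffold_path):
        raise ArgumentError(
            f"scaffold sequence ({len(scaffold_sequence)} nt) shorter than "
            f"routed length ({len(scaffold_path)} nt)"
        )
    seq = scaffold_sequence[: len(scaffold_path)].upper()

    crossovers: list[tuple[int, int, str]] = []
    for (h1, i1), (h2, i2) in zip(scaffold_path[:-1], scaffold_path[1:]):
        if h1 != h2:
            crossovers.append((h1, i1, "scaffold"))
            crossovers.append((h2, i2, "scaffold"))

    staples: list[Staple] = []
    stap_starts = []
    for v in vstrands:
        for idx, cell in enumerate(v["stap"]):
            p5 = (int(cell[0]), int(cell[1]))
            p3 = (int(cell[2]), int(cell[3]))
            if p5 == (-1, -1) and p3 != (-1, -1):
                stap_starts.append((v["num"], idx))
    for s in sorted(stap_starts):
        spath = _walk_cadnano(vstrands, "stap", s)
        staples.append(Staple(path=spath))
        for (h1, i1), (h2, i2) in zip(spath[:-1], spath[1:]):
            if h1 != h2:
                crossovers.append((h1, i1, "staple"))
                crossovers.append((h2, i2, "staple"))

    return DesignMap(
        scaffold_path=scaffold_path,
        scaffold_sequence=seq,
        staples=staples,
        crossovers=crossovers,
    )


# ---------------------------------------------------------------------------
# pairing attachment
# ---------------------------------------------------------------------------


def infer_pairing_geometric(
    topology: Topology, config: "Configuration", threshold: float = 0.15,
    base_site_offset: float = 0.56,
) -> np.ndarray:
    """Geometric pairing fallback: mutually nearest antiparallel base sites.

    oxDNA topology files carry no pairing, so when no design is available
    pairing is inferred from one configuration: nucleotides pair if their
    base interaction sites (position + offset along a1) lie within
    *threshold* nm, their base normals are antiparallel, and their bases are
    complementary.
    """
    from scipy.spatial import cKDTree

    n = topology.n_nucleotides
    sites = config.positions + base_site_offset * config.a1
    tree = cKDTree(sites)
    dist, idx = tree.query(sites, k=2)
    pairing = np.full(n, -1, dtype=np.intp)
    cand_d, cand_j = dist[:, 1], idx[:, 1]
    for i in range(n):
        j = int(cand_j[i])
        if (
            cand_d[i] < threshold
            and int(cand_j[j]) == i
            and config.a3[i] @ config.a3[j] < 0
            and _COMPLEMENT[str(topology.bases[i])] == str(topology.bases[j])
        ):
            pairing[i] = j
    return pairing


def attach_pairing(
    topology: Topology,
    design: DesignMap | None = None,
    config: "Configuration | None" = None,
) -> Topology:
    """Fill ``topology.pairing`` from the design, else geometrically.

    The design mapping covers scaffold-staple duplexes (what the site census
    needs); the geometric route covers arbitrary duplexes but requires a
    configuration.
    """
    if topology.pairing is not None:
        return topology
    if (
        design is not None
        and design.scaffold_topology_indices is not None
        and design.staple_topology_indices is not None
    ):
        pairing = np.full(topology.n_nucleotides, -1, dtype=np.intp)
        scaf = np.asarray(design.scaffold_topology_indices, dtype=np.intp)
        stap = np.asarray(design.staple_topology_indices, dtype=np.intp)
        ok = stap >= 0
        pairing[scaf[ok]] = stap[ok]
        pairing[stap[ok]] = scaf[ok]
        topology.pairing = pairing
        return topology
    if config is not None:
        topology.pairing = infer_pairing_geometric(topology, config)
        return topology
    raise ArgumentError(
        "no pairing available: need a design with topology indices or a "
        "configuration for geometric inference"
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def write_tsv(path: str | Path, df, metadata: dict | None = None) -> None:
    """Write a DataFrame as TSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path):
    """Read a TSV written by :func:`write_tsv` (metadata lines skipped)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
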