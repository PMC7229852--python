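"""Recognition-site census on the origami scaffold.

Finds motif occurrences (e.g. GCGC) along the scaffold sequence, restricts
them to fully base-paired (duplex) regions, builds the 10-bp docking window
(3 bp flank + 4 bp motif + 3 bp flank by default), and flags sites whose
motif lies within one base pair of a scaffold or staple crossover -- such
sites sit on junction geometry and are not enzyme substrates.

Site ids are 1-based and ordered along the scaffold path, matching the
convention used for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConsistencyError
from .io import DesignMap, Topology, complement

WINDOW_BP = 10


@dataclass
class RecognitionSite:
    """One motif occurrence on the scaffold with its docking window."""

    site_id: int  # 1-based along the scaffold
    motif: str
    scaffold_indices: np.ndarray  # topology indices of the motif, 5'->3'
    staple_indices: np.ndarray  # paired partner per motif bp (-1 unpaired)
    window_scaffold_indices: np.ndarray  # 10 bp (or fewer if truncated)
    window_staple_indices: np.ndarray
    path_offsets: np.ndarray  # motif positions along the scaffold path (0-based)
    crossover_overlap: bool = False
    truncated_window: bool = False
    substructure: str | None = None

    def window_pairs(self) -> list[tuple[int, int]]:
        """(scaffold, staple) topology index pairs, scaffold 5'->3'."""
        return [
            (int(s), int(t))
            for s, t in zip(self.window_scaffold_indices, self.window_staple_indices)
        ]


def _scaffold_indices(design: DesignMap, topology: Topology | None) -> np.ndarray | None:
    if design.scaffold_topology_indices is not None:
        return np.asarray(design.scaffold_topology_indices, dtype=np.intp)
    if topology is None:
        return None
    # fall back: the scaffold is the longest strand, path order = 5'->3'
    sizes = np.bincount(topology.strand_ids)
    scaffold_strand = int(np.argmax(sizes))
    order = topology.strand_nucleotides(scaffold_strand)
    if order.size < design.n_scaffold:
        raise ConsistencyError(
            f"longest strand ({order.size} nt) shorter than scaffold path "
            f"({design.n_scaffold} nt)"
        )
    return order[: design.n_scaffold]


def scan_recognition_sites(
    design: DesignMap,
    topology: Topology | None,
    motif: str = "GCGC",
    flank_left: int = 3,
) -> list[RecognitionSite]:
    """All motif occurrences on the scaffold within duplex regions.

    Overlapping occurrences are reported at each offset.  The docking window
    is ``flank_left`` bp upstream + motif + remaining flank downstream, 10 bp
    total; windows that would extend into unpaired scaffold or off the
    scaffold ends are kept but flagged ``truncated_window``.
    """
    motif = motif.upper()
    if len(motif) < 2:
        raise ArgumentError("motif length must be >= 2")
    complement(motif)  # validates alphabet
    seq = design.scaffold_sequence.upper()
    if not seq:
        raise ArgumentError("design has no threaded scaffold sequence")
    paired = design.paired_mask()
    topo_idx = _scaffold_indices(design, topology)
    pairing = topology.pairing if topology is not None else None
    flank_right = WINDOW_BP - len(motif) - flank_left
    if flank_right < 0:
        raise ArgumentError("motif longer than the 10-bp docking window")

    sites: list[RecognitionSite] = []
    start = seq.find(motif)
    while start != -1:
        m_pos = np.arange(start, start + len(motif))
        if paired[m_pos].all():
            w_lo = start - flank_left
            w_hi = start + len(motif) + flank_right
            w_pos = np.arange(max(w_lo, 0), min(w_hi, len(seq)))
            truncated = (w_lo < 0 or w_hi > len(seq)) or not paired[w_pos].all()
            if not truncated:
                pass
            else:
                w_pos = w_pos[paired[w_pos]]
            if topo_idx is not None:
                m_idx = topo_idx[m_pos]
                w_idx = topo_idx[w_pos]
                if pairing is not None:
                    m_st = pairing[m_idx]
                    w_st = pairing[w_idx]
                else:
                    m_st = np.full(m_idx.size, -1, dtype=np.intp)
                    w_st = np.full(w_idx.size, -1, dtype=np.intp)
            else:
                m_idx = np.full(m_pos.size, -1, dtype=np.intp)
                w_idx = np.full(w_pos.size, -1, dtype=np.intp)
                m_st = np.full(m_pos.size, -1, dtype=np.intp)
                w_st = np.full(w_pos.size, -1, dtype=np.intp)
            sites.append(
                RecognitionSite(
                    site_id=len(sites) + 1,
                    motif=motif,
                    scaffold_indices=m_idx,
                    staple_indices=m_st,
                    window_scaffold_indices=w_idx,
                    window_staple_indices=w_st,
                    path_offsets=m_pos,
                    truncated_window=bool(truncated),
                )
            )
        start = seq.find(motif, start + 1)
    for site in sites:
        site.crossover_overlap = flag_crossover_overlap(site, design)
    return sites


def flag_crossover_overlap(
    site: RecognitionSite, design: DesignMap, margin: int = 1
) -> bool:
    """True iff any motif bp lies within *margin* bp of a crossover.

    Both scaffold and staple crossovers count, on either strand of the
    duplex; positions are compared along the helix coordinate of the design.
    """
    if not design.crossovers:
        return False
    motif_cells = [design.scaffold_path[int(p)] for p in site.path_offsets]
    for helix, pos in motif_cells:
        for xh, xp, _kind in design.crossovers:
            if xh == helix and abs(xp - pos) <= margin:
                return True
    return False


def sites_table(sites: list[RecognitionSite]) -> pd.DataFrame:
    """BED-like site table, 1-based inclusive spans along the scaffold."""
    rows = []
    for s in sites:
        rows.append(
            {
                "site_id": s.site_id,
                "motif": s.motif,
                "scaffold_start": int(s.path_offsets[0]) + 1,
                "scaffold_end": int(s.path_offsets[-1]) + 1,
                "window_start": int(s.path_offsets[0]) + 1 - 3,
                "window_end": int(s.path_offsets[-1]) + 1 + 3,
                "crossover_overlap": s.crossover_overlap,
                "truncated_window": s.truncated_window,
                "substructure": s.substructure or "",
            }
        )
    return pd.DataFrame(rows)
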