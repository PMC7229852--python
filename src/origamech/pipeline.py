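"""End-to-end report assembly: sites -> modes -> accessibility -> correlation."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import access, modes, sites as sites_mod
from .errors import ArgumentError, OrigamechError, StageError
from .geometry import build_ideal_helix
from .io import (
    attach_pairing,
    read_cadnano_design,
    read_oxdna_topology,
    read_oxdna_trajectory,
    read_pdb_particles,
    read_tsv,
    write_tsv,
)

log = logging.getLogger("origamech")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    topology: str
    trajectory: str
    design: str | None = None
    scaffold_sequence: str | None = None  # needed for cadnano JSON designs
    pdb: str | None = None
    pdb_chains: list[str] | None = None
    probe_extent: float = 3.0
    probe_particles: int = 4000
    probe_offset: float = 0.0
    motif: str = "GCGC"
    sides: list[str] = field(default_factory=lambda: ["scaffold", "staple"])
    theta_bins: int = access.DEFAULT_THETA_BINS
    flank_left: int = 3
    exclusion_margin_bp: int = access.DEFAULT_EXCLUSION_MARGIN_BP
    n_bins: int = 100
    experiment: str | None = None  # TSV with site_id, fraction columns
    seed: int = 0
    outdir: str = "origamech_out"
    verbosity: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _load_design(cfg: RunConfig):
    from .synth import design_from_json

    if cfg.design is None:
        return None
    path = Path(cfg.design)
    text = path.read_text()
    if '"vstrands"' in text:
        if not cfg.scaffold_sequence:
            raise ArgumentError("cadnano designs require scaffold_sequence")
        return read_cadnano_design(path, cfg.scaffold_sequence)
    return design_from_json(text)


def _scaffold_selection(design, topology) -> np.ndarray:
    if design is not None and design.scaffold_topology_indices is not None:
        return np.asarray(design.scaffold_topology_indices, dtype=np.intp)
    sizes = np.bincount(topology.strand_ids)
    return topology.strand_nucleotides(int(np.argmax(sizes)))


def _build_template(cfg: RunConfig):
    if cfg.pdb is not None:
        protein, dna = read_pdb_particles(
            cfg.pdb, chain_filter=set(cfg.pdb_chains) if cfg.pdb_chains else None
        )
        helix = build_ideal_helix(10, "AAAGCGCAAA")
        return access.build_docking_template(protein, dna, helix)
    return access.probe_template(
        cfg.probe_extent, cfg.probe_particles, offset=cfg.probe_offset, seed=cfg.seed
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns a dict of in-memory results; all output files carry the config
    hash in their metadata header.
    """
    for key in ("topology", "trajectory"):
        p = getattr(cfg, key)
        if p is None or not Path(p).exists():
            raise ArgumentError(f"missing input: {key} = {p!r}")

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    digest = cfg.digest()
    meta = {"config": digest}
    (outdir / "config.json").write_text(json.dumps(asdict(cfg), indent=1))

    try:
        topology = read_oxdna_topology(cfg.topology)
        traj = read_oxdna_trajectory(cfg.trajectory, topology)
        design = _load_design(cfg)
        if topology.pairing is None and (design is not None or len(traj)):
            attach_pairing(topology, design, traj[0] if len(traj) else None)
    except OrigamechError as exc:
        raise StageError("input", str(exc)) from exc
    log.info("read %d frames, %d nucleotides", len(traj), topology.n_nucleotides)

    results: dict = {"config_digest": digest, "n_frames": len(traj)}

    try:
        site_list = (
            sites_mod.scan_recognition_sites(
                design, topology, cfg.motif, flank_left=cfg.flank_left
            )
            if design is not None
            else []
        )
        if site_list:
            write_tsv(outdir / "sites.tsv", sites_mod.sites_table(site_list), meta)
        results["sites"] = site_list
    except OrigamechError as exc:
        raise StageError("sites", str(exc)) from exc

    try:
        selection = _scaffold_selection(design, topology)
        aligned, mean, rmsf = modes.align_and_average(traj, selection)
        spectrum = modes.covariance_modes(aligned, selection)
        write_tsv(
            outdir / "rmsf.tsv",
            pd.DataFrame({"nucleotide": selection, "rmsf_nm": rmsf}),
            {**meta, "selection_size": selection.size},
        )
        write_tsv(
            outdir / "eigenvalues.tsv",
            pd.DataFrame(
                {
                    "mode": np.arange(1, spectrum.eigenvalues.size + 1),
                    "eigenvalue_nm2": spectrum.eigenvalues,
                }
            ),
            {**meta, "total_msf_nm2": spectrum.total_msf},
        )
        series = modes.project_onto_mode(
            aligned, selection, spectrum.eigenvectors[:, 0], spectrum.mean
        )
        write_tsv(
            outdir / "projection_p1.tsv",
            pd.DataFrame({"time_us": series.timestamps, "s_nm": series.values}),
            meta,
        )
        profile = modes.free_energy_profile(series, n_bins=cfg.n_bins)
        write_tsv(
            outdir / "free_energy_p1.tsv",
            pd.DataFrame(
                {
                    "center_nm": profile.centers,
                    "free_energy_kbt": profile.free_energy,
                    "count": profile.counts,
                }
            ),
            meta,
        )
        stats = modes.two_state_stats(series, profile)
        results.update(
            spectrum=spectrum, rmsf=rmsf, projection=series, profile=profile,
            two_state=stats,
        )
        log.info(
            "modes: total MSF %.3f nm^2, %d state(s)", spectrum.total_msf, stats.n_states
        )
    except OrigamechError as exc:
        raise StageError("modes", str(exc)) from exc

    if site_list:
        try:
            template = _build_template(cfg)
            rows = []
            theory: dict[int, float] = {}
            for site in site_list:
                try:
                    res = access.site_accessibility(
                        traj,
                        site,
                        template,
                        sides=tuple(cfg.sides),
                        n_theta=cfg.theta_bins,
                        exclusion_margin_bp=cfg.exclusion_margin_bp,
                    )
                except OrigamechError as exc:
                    log.warning("site %d not scored: %s", site.site_id, exc)
                    continue
                theory[site.site_id] = res.fractions.get(
                    "scaffold", next(iter(res.fractions.values()))
                )
                for side, frac in res.fractions.items():
                    rows.append(
                        {
                            "site_id": site.site_id,
                            "side": side,
                            "frames_used": res.n_frames,
                            "frames_skipped": res.n_skipped,
                            "fraction": frac,
                            "crossover_overlap": site.crossover_overlap,
                        }
                    )
            report = pd.DataFrame(rows)
            write_tsv(outdir / "accessibility.tsv", report, meta)
            results["accessibility"] = report
            results["theory"] = theory
        except OrigamechError as exc:
            raise StageError("accessibility", str(exc)) from exc

        if cfg.experiment is not None:
            try:
                exp = read_tsv(cfg.experiment)
                experiment = dict(
                    zip(exp["site_id"].astype(int), exp["fraction"].astype(float))
                )
                exclude = {s.site_id for s in site_list if s.crossover_overlap}
                r, used = access.correlate_with_experiment(theory, experiment, exclude)
                results["pearson"] = r
                results["pearson_sites"] = used
                (outdir / "correlation.json").write_text(
                    json.dumps({"pearson": r, "sites": used, "config": digest})
                )
                log.info("theory-experiment Pearson r = %.3f over %d sites", r, len(used))
            except OrigamechError as exc:
                raise StageError("correlation", str(exc)) from exc

    log.removeHandler(fh)
    fh.close()
    return results
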