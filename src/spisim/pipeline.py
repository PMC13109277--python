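"""Orchestration: configuration, seed management, and end-to-end commands.

A single master seed is expanded into per-stage seeds by stable hashing of
stage names, so any stage can be re-run in isolation and a full run is
reproducible from the master seed alone.  Every output file embeds the
resolved configuration (JSON) and its SHA-256 hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cdi_forward, cei_dynamics, footprint_analysis, phase_retrieval
from .synthetic_structures import (
    MolecularStructure,
    make_icosahedral_particle,
    make_toy_protein,
    read_pdb,
)
from .xray_optics import (
    AtomicDataTable,
    Composition,
    FELPulse,
    VIRUS_DENSITY_G_CM3,
    absorbed_fraction,
    contrast_ratio,
    photon_energy,
)

__all__ = [
    "RunConfig",
    "stage_seed",
    "cmd_contrast",
    "cmd_cdi",
    "cmd_cei",
    "setup_logging",
]

logger = logging.getLogger("spisim")


def setup_logging(log_file=None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PulseConfig:
    photons: float = 1e11
    wavelength_nm: float = 4.3
    focus_nm: float = 5000.0
    fwhm_fs: float = 12.0

    def to_pulse(self) -> FELPulse:
        return FELPulse(self.photons, self.wavelength_nm, self.focus_nm, self.fwhm_fs)


@dataclass
class MaterialConfig:
    formula: str = "CH1.5O0.5N0.25P0.025"
    density_g_cm3: float = VIRUS_DENSITY_G_CM3
    background_formula: str = "H2O"
    background_density_g_cm3: float = 1.0
    thickness_nm: float = 500.0
    wavelengths_nm: tuple = (4.3, 4.4)

    def sample(self) -> Composition:
        return Composition.from_formula(self.formula, self.density_g_cm3)

    def background(self) -> Composition | None:
        if not self.background_formula:
            return None
        return Composition.from_formula(self.background_formula, self.background_density_g_cm3)


@dataclass
class DetectorConfig:
    n_x: int = 1024
    n_y: int = 1024
    pixel_size_um: float = 75.0
    distance_cm: float = 15.0

    def to_geometry(self) -> cdi_forward.DetectorGeometry:
        return cdi_forward.DetectorGeometry(
            self.n_x, self.n_y, self.pixel_size_um, self.distance_cm
        )


@dataclass
class ParticleConfig:
    diameter_nm: float = 500.0
    voxel_size_nm: float = 5.0
    shape: str = "icosahedron"


@dataclass
class CEIPulseConfig(PulseConfig):
    photons: float = 2.3e10
    wavelength_nm: float = 4.0
    focus_nm: float = 1000.0
    fwhm_fs: float = 12.0


@dataclass
class CEIConfig:
    pulse: CEIPulseConfig = field(default_factory=CEIPulseConfig)
    dt_fs: float = 0.05
    dt_far_fs: float = 0.5
    t_end_fs: float = 300.0
    auger_mode: str = "off"
    bond_cutoff_nm: float = 0.25
    structure_n_residues: tuple = (70, 70)
    structure_seeds: tuple = (101, 202)
    pdb_paths: tuple = ()
    keep_hydrogens: bool = True


@dataclass
class FootprintConfig:
    n_elevation: int = 40
    n_azimuth: int = 80
    min_charge: int = 1
    embed_method: str = "tsne"
    perplexity: float | None = None

    def spec(self) -> footprint_analysis.SphericalDetectorSpec:
        return footprint_analysis.SphericalDetectorSpec(self.n_elevation, self.n_azimuth)


@dataclass
class PhaseConfig:
    n_hio: int = 500
    n_er: int = 100
    beta: float = 0.9
    support_dilation_px: int = 2
    positivity: bool = True  # simulated electron densities are nonnegative


@dataclass
class IOConfig:
    out_dir: str = "spisim_run"


@dataclass
class RunConfig:
    """Resolved configuration for all pipeline stages."""

    pulse: PulseConfig = field(default_factory=PulseConfig)
    material: MaterialConfig = field(default_factory=MaterialConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    particle: ParticleConfig = field(default_factory=ParticleConfig)
    cei: CEIConfig = field(default_factory=CEIConfig)
    footprint: FootprintConfig = field(default_factory=FootprintConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    io: IOConfig = field(default_factory=IOConfig)
    seed: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "pulse", "material", "detector", "particle", "cei", "footprint", "phase", "io",
            ):
                sub_cls = {
                    "pulse": PulseConfig,
                    "material": MaterialConfig,
                    "detector": DetectorConfig,
                    "particle": ParticleConfig,
                    "cei": CEIConfig,
                    "footprint": FootprintConfig,
                    "phase": PhaseConfig,
                    "io": IOConfig,
                }[f.name]
                if f.name == "cei" and isinstance(value, dict):
                    value = dict(value)
                    if "pulse" in value and isinstance(value["pulse"], dict):
                        value["pulse"] = CEIPulseConfig(**value["pulse"])
                kwargs[f.name] = sub_cls(**value) if isinstance(value, dict) else value
            else:
                kwargs[f.name] = value
        config = cls(**kwargs)
        # YAML has no tuples: normalize list-valued fields back to tuples
        for block in dataclasses.fields(config):
            sub = getattr(config, block.name)
            if dataclasses.is_dataclass(sub):
                for f in dataclasses.fields(sub):
                    v = getattr(sub, f.name)
                    if isinstance(v, list):
                        setattr(sub, f.name, tuple(v))
        return config

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _prepare_out(config: RunConfig, out_dir=None) -> Path:
    out = Path(out_dir if out_dir is not None else config.io.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps({"config": config.to_dict(), "hash": config.config_hash()},
                   indent=2, default=str)
    )
    return out


# ---------------------------------------------------------------------------
# commands

def cmd_contrast(config: RunConfig, table: AtomicDataTable | None = None, out_dir=None) -> dict:
    """Absorbed fractions and sample/background contrast at the configured
    wavelengths (defaults: 500 nm slabs at 4.3 and 4.4 nm)."""
    t0 = time.time()
    table = table or AtomicDataTable.bundled()
    out = _prepare_out(config, out_dir)
    sample = config.material.sample()
    background = config.material.background()
    thickness = config.material.thickness_nm

    rows = []
    ratios = {}
    for lam in config.material.wavelengths_nm:
        energy = photon_energy(lam)
        row = {
            "wavelength_nm": lam,
            "energy_ev": energy,
            "sample_absorbed": absorbed_fraction(sample, thickness, energy, table),
        }
        if background is not None:
            row["background_absorbed"] = absorbed_fraction(background, thickness, energy, table)
            row["ratio"] = contrast_ratio(sample, background, thickness, energy, table)
            ratios[lam] = row["ratio"]
        rows.append(row)

    report = {"thickness_nm": thickness, "table": rows}
    if len(ratios) >= 2:
        lams = sorted(ratios)
        report["ratio_quotient"] = ratios[lams[0]] / ratios[lams[-1]]
    (out / "contrast.json").write_text(json.dumps(report, indent=2))
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "contrast.csv", index=False)
    logger.info("contrast: wrote %s (%.2f s)", out / "contrast.csv", time.time() - t0)
    return report


def cmd_cdi(config: RunConfig, out_dir=None, noise: bool = True) -> dict:
    """Particle -> diffraction -> phase retrieval; writes HDF5 + summary."""
    import h5py
    from scipy import ndimage

    t0 = time.time()
    out = _prepare_out(config, out_dir)
    pulse = config.pulse.to_pulse()
    det = config.detector.to_geometry()

    particle = make_icosahedral_particle(
        config.particle.diameter_nm,
        config.material.sample(),
        config.particle.voxel_size_nm,
        shape=config.particle.shape,
    )
    # pad to >= 2x the particle extent for oversampling
    grid = particle.grid
    pad = [(0, max(0, 2 * s - s)) for s in grid.shape]
    grid = np.pad(grid, pad)
    padded = dataclasses.replace(particle, grid=grid)

    seed = stage_seed(config.seed, "diffract")
    pattern = cdi_forward.diffract(padded, pulse, det, seed=seed, noise=noise)

    with h5py.File(out / "pattern.h5", "w") as fh:
        fh.create_dataset("expected", data=pattern.expected)
        fh.create_dataset("counts", data=pattern.counts)
        fh.create_dataset("q_map_nm_inv", data=pattern.q_map)
        fh.create_dataset("mask", data=pattern.mask)
        for key, value in pattern.metadata.items():
            fh.attrs[key] = str(value) if isinstance(value, (tuple, list)) else value
        fh.attrs["config_hash"] = config.config_hash()

    # phase the measured counts on the regular FFT grid of the projection
    projection = padded.grid.sum(axis=2)
    amplitudes = np.abs(np.fft.fft2(projection))
    support = ndimage.binary_dilation(
        projection > 0, iterations=max(1, config.phase.support_dilation_px)
    )
    recon = phase_retrieval.hio_er(
        amplitudes,
        support,
        n_hio=config.phase.n_hio,
        n_er=config.phase.n_er,
        beta=config.phase.beta,
        seed=stage_seed(config.seed, "phase"),
        positivity=config.phase.positivity,
    )
    error = phase_retrieval.align_and_score(recon.density, projection)

    with h5py.File(out / "reconstruction.h5", "w") as fh:
        fh.create_dataset("density", data=recon.density)
        fh.create_dataset("error_series", data=recon.error_series)
        fh.attrs["algorithm"] = recon.algorithm
        fh.attrs["beta"] = recon.beta or 0.0
        fh.attrs["seed"] = recon.seed
        fh.attrs["config_hash"] = config.config_hash()

    summary = {
        "edge_resolution_nm": cdi_forward.edge_resolution(det, pulse.wavelength_nm),
        "resolution_convention": cdi_forward.RESOLUTION_CONVENTION,
        "total_detected_photons": int(pattern.counts.sum()),
        "total_electrons": particle.total_electrons,
        "aligned_reconstruction_error": error,
        "final_fourier_residual": float(recon.error_series[-1]),
        "wall_time_s": time.time() - t0,
    }
    (out / "cdi_summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("cdi: %s", summary)
    return summary


def _cei_structures(config: RunConfig) -> list[MolecularStructure]:
    if config.cei.pdb_paths:
        return [
            read_pdb(p, keep_hydrogens=config.cei.keep_hydrogens)
            for p in config.cei.pdb_paths
        ]
    return [
        make_toy_protein(n, s)
        for n, s in zip(config.cei.structure_n_residues, config.cei.structure_seeds)
    ]


def cmd_cei(config: RunConfig, n_runs: int = 20, out_dir=None,
            table: AtomicDataTable | None = None) -> dict:
    """Seeded explosions per structure, footprints, L2 matrix, embedding,
    and (with >= 2 structures) classification accuracy."""
    import h5py
    import pandas as pd

    t0 = time.time()
    table = table or AtomicDataTable.bundled()
    out = _prepare_out(config, out_dir)
    structures = _cei_structures(config)
    pulse = config.cei.pulse.to_pulse()
    spec = config.footprint.spec()

    footprints = []
    labels = []
    mean_charges = []
    for s_idx, structure in enumerate(structures):
        for run in range(n_runs):
            seed = stage_seed(config.seed, f"cei:{s_idx}:{run}")
            result = cei_dynamics.run_explosion(
                structure, pulse, table,
                dt=config.cei.dt_fs, t_end=config.cei.t_end_fs, seed=seed,
                auger_mode=config.cei.auger_mode, dt_far=config.cei.dt_far_fs,
            )
            fp = footprint_analysis.project(
                result, spec, min_charge=config.footprint.min_charge,
                label=structure.label, seed=seed,
            )
            footprints.append(fp)
            labels.append(s_idx)
            mean_charges.append(float(result.system.charges.mean()))
            logger.info(
                "cei: structure %d run %d seed %d mean charge %.3f e/atom",
                s_idx, run, seed, mean_charges[-1],
            )

    with h5py.File(out / "footprints.h5", "w") as fh:
        fh.attrs["config_hash"] = config.config_hash()
        for idx, fp in enumerate(footprints):
            ds = fh.create_dataset(f"footprint_{idx:04d}", data=fp.counts)
            ds.attrs["label"] = fp.label
            ds.attrs["seed"] = fp.seed
            ds.attrs["structure_index"] = labels[idx]

    summary = {
        "n_structures": len(structures),
        "n_runs": n_runs,
        "mean_charge_per_atom": float(np.mean(mean_charges)) if mean_charges else 0.0,
        "master_seed": config.seed,
    }

    n = len(footprints)
    if n >= 2:
        l2 = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                l2[i, j] = l2[j, i] = footprint_analysis.l2_distance(
                    footprints[i], footprints[j]
                )
        pd.DataFrame(l2).to_csv(out / "l2_matrix.csv", index=False)
        summary["mean_l2"] = float(l2[np.triu_indices(n, 1)].mean())

    if n >= 3 and n_runs >= 2:
        embedding = footprint_analysis.embed(
            footprints,
            method=config.footprint.embed_method,
            seed=stage_seed(config.seed, "embed"),
            perplexity=config.footprint.perplexity,
        )
        pd.DataFrame(
            {"x": embedding.coordinates[:, 0], "y": embedding.coordinates[:, 1],
             "label": labels}
        ).to_csv(out / "embedding.csv", index=False)
        if len(structures) >= 2:
            summary["classification_accuracy"] = footprint_analysis.classify(
                embedding, labels, k=len(structures),
                seed=stage_seed(config.seed, "kmeans"),
            )

    summary["wall_time_s"] = time.time() - t0
    (out / "cei_summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("cei: %s", summary)
    return summary
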