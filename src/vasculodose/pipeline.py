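"""End-to-end experiment orchestration.

One run: generate the vascular phantom, load it with gold clusters in a
chosen compartment, irradiate the bare and loaded phantoms with the same
beam and history count, renormalize the reference to the prescription,
apply the same factor to the loaded grid, and report per-compartment
cDVHs and dose-enhancement ratios.  A master seed deterministically
derives every stage seed; the manifest lists all outputs with checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dosimetry import COMPARTMENTS, cdvh, compartment_mask, der_report, renormalize
from .gnp_placement import GNPPlacementSpec, place
from .io import save_cdvh, save_dose, save_phantom, save_tree, _jsonable
from .materials import EnergySpectrum
from .phantom import LABEL_NAMES, GenerationConfig, generate_tree, voxelize
from .transport import TransportConfig, simulate

log = logging.getLogger("vasculodose")


@dataclass
class RunConfig:
    """Single-file description of a complete experiment."""

    master_seed: int = 1
    phantom: GenerationConfig = field(default_factory=GenerationConfig)
    placement: GNPPlacementSpec = field(default_factory=GNPPlacementSpec)
    spectrum: str = "mono_100kev"
    transport: TransportConfig = field(default_factory=TransportConfig)
    prescription_gy: float = 10.0
    voxel_size_nm: float = 500.0
    output_dir: str = "run_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            kwargs["phantom"] = GenerationConfig(**kwargs["phantom"])
        if "placement" in kwargs:
            kwargs["placement"] = GNPPlacementSpec(**kwargs["placement"])
        if "transport" in kwargs:
            kwargs["transport"] = TransportConfig(**kwargs["transport"])
        return cls(**kwargs)

    def to_yaml(self, path) -> Path:
        data = asdict(self)
        data["placement"]["mode"] = self.placement.mode.value
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
        return Path(path)


def stage_seeds(master_seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage seeds below 2^31 derived from the master."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s % (2**31 - 1)) for s in ss.generate_state(n, dtype=np.uint64)]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: RunConfig) -> dict:
    """Execute generate -> place -> irradiate (x2) -> analyze; returns the
    manifest written to the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.master_seed)
    timings: dict[str, float] = {}
    files: list[Path] = []
    current = {"stage": "setup", "t0": time.time()}

    def _stage(name):
        log.info("stage %s", name)
        current["stage"] = name
        current["t0"] = time.time()

    def _done(name):
        timings[name] = round(time.time() - current["t0"], 3)

    try:
        _stage("generate")
        tree = generate_tree(seeds[0], params=config.phantom)
        phantom = voxelize(tree, voxel_size_nm=config.voxel_size_nm)
        files.append(save_tree(tree, out / "tree.csv"))
        files.append(save_phantom(phantom, out / "phantom.raw"))
        _done("generate")

        _stage("place")
        spec_pl = config.placement
        spec_pl.rng_seed = seeds[1]
        loaded = place(phantom, spec_pl)
        files.append(save_phantom(loaded, out / "phantom_gnp.raw"))
        _done("place")

        _stage("irradiate")
        spectrum = EnergySpectrum.builtin(config.spectrum)
        tcfg = config.transport
        tcfg.rng_seed = seeds[2]
        reference = simulate(phantom, spectrum, tcfg)
        with_gnp = simulate(loaded, spectrum, tcfg)
        _done("irradiate")

        _stage("analyze")
        factor, ref_norm = renormalize(reference, config.prescription_gy)
        gnp_norm = with_gnp.scaled(factor)
        files.append(save_dose(ref_norm, out / "dose_reference.raw"))
        files.append(save_dose(gnp_norm, out / "dose_gnp.raw"))
        report = der_report(gnp_norm, ref_norm, loaded)
        curves = []
        for lab in COMPARTMENTS:
            mask = compartment_mask(loaded, lab)
            if mask.any():
                dmax = float(max(gnp_norm.dose[mask].max(), ref_norm.dose[mask].max()))
                curves.append(cdvh(gnp_norm, mask, dose_max=dmax,
                                   compartment=f"{LABEL_NAMES[lab]}_gnp"))
                curves.append(cdvh(ref_norm, mask, dose_max=dmax,
                                   compartment=f"{LABEL_NAMES[lab]}_reference"))
        files.append(save_cdvh(curves, out / "cdvh.csv"))
        der_path = out / "der_report.json"
        der_path.write_text(json.dumps(_jsonable(report.to_dict()), indent=1))
        files.append(der_path)
        _done("analyze")
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage '{current['stage']}' failed: {err}") from err

    manifest = {
        "master_seed": config.master_seed,
        "stage_seeds": seeds,
        "spectrum": config.spectrum,
        "prescription_gy": config.prescription_gy,
        "normalization_factor": factor,
        "average_der": report.average_der,
        "mean_dose_with_gy": report.mean_dose_with,
        "mean_dose_without_gy": report.mean_dose_without,
        "timings_s": timings,
        "files": {str(p.name): _checksum(p) for p in files},
        "sidecars": {
            f"{p.name}.json": _checksum(Path(str(p) + ".json"))
            for p in files if Path(str(p) + ".json").exists()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
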